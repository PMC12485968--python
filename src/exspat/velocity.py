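"""Spatial RNA velocity from nuclear/cytoplasmic compartment counts.

The nuclear count of a gene serves as the unspliced proxy u and the
cytoplasmic count as the spliced proxy s. The steady-state ratio γ is fit
per gene by least squares through the origin (γ = Σus / Σs²), velocity is
v = u − γs, and the predicted future state is s* = max(s + v·Δt, 0). Current
and future states are projected into a shared 2D PCA basis fitted on the
pooled (both-condition) normalized current states, giving per-cell
displacement vectors whose magnitudes are compared by Mann–Whitney U and
whose phases by a circular-mean permutation test, optionally stratified by
cell type and region. Δt is 1 in arbitrary units, so magnitudes are only
comparable within a shared basis/scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from ._utils import child_seed
from .dataio import UNASSIGNED
from .spatial import bh_adjust

DEFAULT_MIN_CELLS_GAMMA = 30
DEFAULT_MIN_CELLS_STRATUM = 10


@dataclass
class CompartmentCounts:
    """Per-cell nuclear (u) and cytoplasmic (s) count matrices plus cell
    metadata, aligned on cell_id."""

    u: pd.DataFrame  # cells × genes
    s: pd.DataFrame  # cells × genes
    meta: pd.DataFrame  # indexed by cell_id: cell_type, region, sample_id, condition


def compartment_counts(
    spots: pd.DataFrame, cells: pd.DataFrame, panel: list[str] | None = None
) -> CompartmentCounts:
    """Tally nuclear and cytoplasmic spots per (cell, gene); unassigned
    spots are ignored and u + s conserves the assigned spot count."""
    assigned = spots[(spots["cell_id"] != UNASSIGNED) & (spots["compartment"] != UNASSIGNED)]
    piv = (
        assigned.groupby(["cell_id", "gene", "compartment"]).size()
        .unstack("compartment", fill_value=0)
    )
    for comp in ("nuclear", "cytoplasmic"):
        if comp not in piv.columns:
            piv[comp] = 0
    u = piv["nuclear"].unstack("gene", fill_value=0)
    s = piv["cytoplasmic"].unstack("gene", fill_value=0)
    if panel is not None:
        u = u.reindex(columns=panel, fill_value=0)
        s = s.reindex(columns=panel, fill_value=0)
    cell_ids = u.index.union(s.index)
    u = u.reindex(index=cell_ids, fill_value=0)
    s = s.reindex(index=cell_ids, fill_value=0)
    meta = (
        cells.set_index("cell_id")[["cell_type", "region", "sample_id", "condition", "fov_id"]]
        .reindex(cell_ids)
    )
    return CompartmentCounts(u, s, meta)


def fit_gamma(
    counts: CompartmentCounts,
    min_cells: int = DEFAULT_MIN_CELLS_GAMMA,
    cell_mask: np.ndarray | None = None,
) -> pd.Series:
    """Per-gene steady-state ratio γ = Σ u·s / Σ s² (least squares through
    the origin) over the cells in scope. Genes with fewer than ``min_cells``
    cells having s > 0 are NaN (skip records); all-zero u gives γ = 0."""
    u = counts.u.to_numpy(dtype=float)
    s = counts.s.to_numpy(dtype=float)
    if cell_mask is not None:
        u, s = u[cell_mask], s[cell_mask]
    n_pos = (s > 0).sum(axis=0)
    ss = (s * s).sum(axis=0)
    us = (u * s).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = np.where(ss > 0, us / np.where(ss > 0, ss, 1.0), 0.0)
    gamma = np.where(n_pos >= min_cells, gamma, np.nan)
    # a gene never seen in the nucleus has γ = 0 exactly
    gamma = np.where((n_pos >= min_cells) & (u.sum(axis=0) == 0), 0.0, gamma)
    return pd.Series(gamma, index=counts.u.columns, name="gamma")


def cell_velocity(
    counts: CompartmentCounts, gamma: pd.Series, dt: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell, per-gene velocity v = u − γs and future state
    s* = max(s + v·Δt, 0). Genes without a γ fit are dropped."""
    genes = gamma.dropna().index
    u = counts.u[genes].to_numpy(dtype=float)
    s = counts.s[genes].to_numpy(dtype=float)
    v = u - gamma[genes].to_numpy() * s
    future = np.clip(s + v * dt, 0.0, None)
    idx = counts.u.index
    return (
        pd.DataFrame(v, index=idx, columns=genes),
        pd.DataFrame(future, index=idx, columns=genes),
    )


def _normalize_states(current: np.ndarray, future: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Depth-normalize to the median current total (the same per-cell factor
    applied to both states so displacement reflects state change, not
    depth), then log1p."""
    totals = current.sum(axis=1)
    med = np.median(totals[totals > 0]) if (totals > 0).any() else 1.0
    scale = np.where(totals > 0, med / np.where(totals > 0, totals, 1.0), 1.0)
    return np.log1p(current * scale[:, None]), np.log1p(future * scale[:, None])


def pca_displacement(
    current: pd.DataFrame,
    future: pd.DataFrame,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Project current and future states into a shared 2D PCA basis and
    return per-cell displacement vectors with magnitude and phase.

    The basis is fitted on pooled normalized current states (conditions
    together), so it is invariant to condition labels; component signs are
    fixed by making the first nonzero loading in panel order non-negative.
    Zero displacement has phase 0 by convention.
    """
    if len(current) < 2:
        raise ValueError("need at least 2 cells for a PCA displacement")
    cur, fut = _normalize_states(
        current.to_numpy(dtype=float), future.to_numpy(dtype=float)
    )
    n_comp = min(2, cur.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    pca.fit(cur)
    # transform() both states through the same code path so identical
    # current/future inputs give exactly zero displacement
    proj_cur = pca.transform(cur)
    signs = np.ones(n_comp)
    for j in range(n_comp):
        nz = np.flatnonzero(np.abs(pca.components_[j]) > 1e-12)
        if len(nz) and pca.components_[j, nz[0]] < 0:
            signs[j] = -1.0
    proj_cur = proj_cur * signs
    proj_fut = (pca.transform(fut)) * signs
    d = proj_fut - proj_cur
    if n_comp < 2:
        d = np.column_stack([d, np.zeros(len(d))])
    magnitude = np.linalg.norm(d, axis=1)
    phase = np.where(magnitude > 0, np.arctan2(d[:, 1], d[:, 0]), 0.0)
    out = pd.DataFrame(
        {"d1": d[:, 0], "d2": d[:, 1], "magnitude": magnitude, "phase": phase},
        index=current.index,
    )
    if meta is not None:
        out = out.join(meta[["cell_type", "region", "sample_id", "condition"]])
    return out


def compare_magnitudes(
    magnitudes_a: np.ndarray,
    magnitudes_b: np.ndarray,
    min_n: int = DEFAULT_MIN_CELLS_STRATUM,
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U (tie-corrected) on displacement magnitudes;
    returns (U, p) or (NaN, NaN) for undersized groups."""
    a, b = np.asarray(magnitudes_a, float), np.asarray(magnitudes_b, float)
    if len(a) < min_n or len(b) < min_n:
        return float("nan"), float("nan")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def circular_mean(phases: np.ndarray) -> tuple[float, float]:
    """Angle and resultant length of the mean direction."""
    z = np.exp(1j * np.asarray(phases, float)).mean()
    return float(np.angle(z)), float(np.abs(z))


def _angular_distance(a: float, b: float) -> float:
    d = abs(a - b) % (2 * np.pi)
    return min(d, 2 * np.pi - d)


def compare_phases(
    phases_a: np.ndarray,
    phases_b: np.ndarray,
    n_perm: int = 999,
    rng: np.random.Generator | int = 0,
    min_n: int = DEFAULT_MIN_CELLS_STRATUM,
) -> tuple[float, float]:
    """Permutation test on the angular distance between group circular
    means (statistic in [0, π]); null permutes condition labels; add-one p.

    The caller excludes zero-magnitude cells. Returns (NaN, NaN) for
    undersized groups or when a group's resultant length vanishes (the mean
    direction is then undefined and the record is skipped).
    """
    a, b = np.asarray(phases_a, float), np.asarray(phases_b, float)
    if len(a) < min_n or len(b) < min_n:
        return float("nan"), float("nan")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    ang_a, r_a = circular_mean(a)
    ang_b, r_b = circular_mean(b)
    if r_a < 1e-12 or r_b < 1e-12:
        return float("nan"), float("nan")
    t_obs = _angular_distance(ang_a, ang_b)
    pooled = np.concatenate([a, b])
    n_a = len(a)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        pa, pb = pooled[perm[:n_a]], pooled[perm[n_a:]]
        t = _angular_distance(circular_mean(pa)[0], circular_mean(pb)[0])
        if t >= t_obs - 1e-12:
            count += 1
    return float(t_obs), (1.0 + count) / (n_perm + 1.0)


def phase_kde_distance(
    phases_a: np.ndarray, phases_b: np.ndarray, n_grid: int = 360, bw: float = 0.3
) -> float:
    """Alternative phase statistic: integrated squared difference of
    wrapped (von Mises kernel) circular KDEs."""
    grid = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)

    def kde(ph):
        kappa = 1.0 / bw**2
        w = np.exp(kappa * np.cos(grid[:, None] - ph[None, :]))
        dens = w.sum(axis=1)
        return dens / (dens.sum() * (2 * np.pi / n_grid))

    diff = kde(np.asarray(phases_a, float)) - kde(np.asarray(phases_b, float))
    return float((diff**2).sum() * (2 * np.pi / n_grid))


def gene_velocity_difftest(
    v_a: pd.DataFrame,
    v_b: pd.DataFrame,
    min_n: int = DEFAULT_MIN_CELLS_STRATUM,
) -> pd.DataFrame:
    """Per-gene two-sided MWU on per-cell velocities between conditions,
    BH-adjusted across the genes tested in this scope."""
    genes = [g for g in v_a.columns if g in v_b.columns]
    rows = []
    for g in genes:
        a, b = v_a[g].to_numpy(dtype=float), v_b[g].to_numpy(dtype=float)
        if len(a) < min_n or len(b) < min_n or (np.ptp(np.concatenate([a, b])) == 0):
            rows.append({"gene": g, "statistic": np.nan, "p": np.nan, "skipped": True})
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {"gene": g, "statistic": float(res.statistic), "p": float(res.pvalue), "skipped": False}
        )
    out = pd.DataFrame(rows)
    q = np.full(len(out), np.nan)
    tested = out["p"].notna().to_numpy()
    if tested.any():
        q[tested] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["q"] = q
    return out


def velocity_analysis(
    spots: pd.DataFrame,
    cells: pd.DataFrame,
    panel: list[str],
    dt: float = 1.0,
    min_cells_gamma: int = DEFAULT_MIN_CELLS_GAMMA,
) -> tuple[CompartmentCounts, pd.Series, pd.DataFrame, pd.DataFrame]:
    """Convenience chain: counts → γ → velocity/future states."""
    counts = compartment_counts(spots, cells, panel)
    gamma = fit_gamma(counts, min_cells=min_cells_gamma)
    v, future = cell_velocity(counts, gamma, dt=dt)
    return counts, gamma, v, future


def stratify(
    counts: CompartmentCounts,
    gamma: pd.Series,
    v: pd.DataFrame,
    future: pd.DataFrame,
    by_region: bool = True,
    cell_types: list[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
    min_cells: int = DEFAULT_MIN_CELLS_STRATUM,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[tuple, pd.DataFrame]]:
    """Run magnitude, phase and gene-level velocity comparisons per stratum
    (cell type × region plus cell type × pooled regions).

    PCA displacements are fitted per stratum on pooled conditions, so
    magnitudes are never compared across strata. Empty or undersized strata
    yield skip records rather than exceptions. Returns (stratum test table,
    all displacement vectors, per-stratum gene test tables).
    """
    meta = counts.meta
    conditions = sorted(meta["condition"].dropna().unique())
    if len(conditions) != 2:
        raise ValueError("stratified comparison needs exactly 2 conditions")
    cond_a, cond_b = conditions
    if cell_types is None:
        cell_types = sorted(meta["cell_type"].dropna().unique())
    region_scopes: list[str | None] = [None]
    if by_region:
        region_scopes += sorted(meta["region"].dropna().unique())

    genes = gamma.dropna().index
    current = counts.s[genes]

    rows, disp_frames, gene_tables = [], [], {}
    for ct in cell_types:
        for region in region_scopes:
            sel = (meta["cell_type"] == ct).to_numpy()
            if region is not None:
                sel &= (meta["region"] == region).to_numpy()
            label = {"cell_type": ct, "region": region if region is not None else "all"}
            n_sel = int(sel.sum())
            is_a = (meta["condition"] == cond_a).to_numpy()
            n_a, n_b = int((sel & is_a).sum()), int((sel & ~is_a).sum())
            rec = {**label, "n_a": n_a, "n_b": n_b,
                   "condition_a": cond_a, "condition_b": cond_b}
            if n_a < min_cells or n_b < min_cells or n_sel < 2:
                rec.update(
                    magnitude_p=np.nan, magnitude_delta=np.nan,
                    phase_delta=np.nan, phase_p=np.nan, skipped=True,
                )
                rows.append(rec)
                continue
            disp = pca_displacement(current[sel], future[genes][sel], meta[sel])
            disp["scope_region"] = label["region"]
            disp_frames.append(disp)
            mag_a = disp.loc[disp["condition"] == cond_a, "magnitude"].to_numpy()
            mag_b = disp.loc[disp["condition"] == cond_b, "magnitude"].to_numpy()
            _, mag_p = compare_magnitudes(mag_a, mag_b, min_n=min_cells)
            nz = disp["magnitude"] > 0
            rng = np.random.default_rng(child_seed(seed, "phase", ct, label["region"]))
            ph_delta, ph_p = compare_phases(
                disp.loc[nz & (disp["condition"] == cond_a), "phase"].to_numpy(),
                disp.loc[nz & (disp["condition"] == cond_b), "phase"].to_numpy(),
                n_perm=n_perm, rng=rng, min_n=min_cells,
            )
            gt = gene_velocity_difftest(v[sel & is_a], v[sel & ~is_a], min_n=min_cells)
            gene_tables[(ct, label["region"])] = gt
            rec.update(
                magnitude_p=mag_p,
                magnitude_delta=float(np.median(mag_a) - np.median(mag_b)),
                phase_delta=ph_delta, phase_p=ph_p, skipped=False,
            )
            rows.append(rec)
    disp_all = pd.concat(disp_frames) if disp_frames else pd.DataFrame()
    return pd.DataFrame(rows), disp_all, gene_tables
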