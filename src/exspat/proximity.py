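"""Cell–cell proximity and its relation to cell-state change.

Boundary distances use the sphere proxy: for cells i (source) and j
(target) the distance is max(0, ‖c_i − c_j‖ − r_i − r_j), exactly 0 for
overlapping spheres, minimized over the target cells of the same FOV only
(no stitched geometry). Cells whose FOV contains no target cell get a
missing distance and are excluded from stratification but counted. The
proximal stratum is distance ≤ threshold (default 1 μm, inclusive).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import mannwhitneyu

from ._utils import child_seed
from .spatial import bh_adjust
from .velocity import compare_phases

DEFAULT_THRESHOLD = 1.0  # μm, inclusive
DEFAULT_MIN_CELLS = 10


def boundary_distances(
    cells: pd.DataFrame,
    source_type: str,
    target_type: str,
    fovs: list[str] | None = None,
    distance_column: str | None = None,
) -> pd.DataFrame:
    """Minimum boundary distance of each source-type cell to the target
    type within its FOV (NaN when the FOV holds no target cell).

    ``distance_column`` lets callers override the sphere proxy with
    precomputed surface-to-surface distances from real segmentation masks.
    """
    src = cells[cells["cell_type"] == source_type]
    if fovs is not None:
        src = src[src["fov_id"].isin(fovs)]
    if distance_column is not None:
        return src[["cell_id", "fov_id", distance_column]].rename(
            columns={distance_column: "min_boundary_distance"}
        )
    out = []
    for fov, group in src.groupby("fov_id"):
        targets = cells[(cells["fov_id"] == fov) & (cells["cell_type"] == target_type)]
        if targets.empty:
            dist = np.full(len(group), np.nan)
        else:
            centre_d = cdist(
                group[["cx", "cy", "cz"]].to_numpy(dtype=float),
                targets[["cx", "cy", "cz"]].to_numpy(dtype=float),
            )
            boundary = centre_d - group["radius"].to_numpy()[:, None] - targets[
                "radius"
            ].to_numpy()[None, :]
            # a cell can be both source and target type only if types equal;
            # mask self-distances in that case
            if source_type == target_type:
                same = group["cell_id"].to_numpy()[:, None] == targets["cell_id"].to_numpy()[None, :]
                boundary = np.where(same, np.inf, boundary)
            dist = np.clip(boundary.min(axis=1), 0.0, None)
            dist = np.where(np.isfinite(dist), dist, np.nan)
        out.append(pd.DataFrame({"cell_id": group["cell_id"], "fov_id": fov,
                                 "min_boundary_distance": dist}))
    if not out:
        return pd.DataFrame(columns=["cell_id", "fov_id", "min_boundary_distance"])
    return pd.concat(out, ignore_index=True)


def proximity_records(
    cells: pd.DataFrame,
    source_type: str,
    target_type: str,
    threshold: float = DEFAULT_THRESHOLD,
    distance_column: str | None = None,
) -> pd.DataFrame:
    rec = boundary_distances(cells, source_type, target_type, distance_column=distance_column)
    rec["target_type"] = target_type
    rec["proximal"] = pd.array(rec["min_boundary_distance"] <= threshold, dtype="boolean")
    rec.loc[rec["min_boundary_distance"].isna(), "proximal"] = pd.NA
    return rec


def proximity_stratified_tests(
    displacements: pd.DataFrame,
    records: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> pd.DataFrame:
    """Magnitude (MWU) and phase (circular permutation) comparisons between
    conditions, run separately within the proximal and non-proximal strata.

    ``displacements`` must be indexed by cell_id with columns magnitude,
    phase, condition (from :func:`exspat.velocity.pca_displacement`);
    ``records`` comes from :func:`proximity_records`. Emits one row per
    stratum with the direction of effect (sign of the median difference);
    undersized strata are skip records.
    """
    rec = records.dropna(subset=["min_boundary_distance"]).set_index("cell_id")
    joined = displacements.join(rec[["proximal"]], how="inner")
    conditions = sorted(joined["condition"].unique())
    if len(conditions) != 2:
        raise ValueError("proximity stratification needs exactly 2 conditions")
    cond_a, cond_b = conditions
    rows = []
    for stratum, flag in (("proximal", True), ("non_proximal", False)):
        sub = joined[joined["proximal"] == flag]
        a = sub[sub["condition"] == cond_a]
        b = sub[sub["condition"] == cond_b]
        rec_row = {
            "stratum": stratum, "condition_a": cond_a, "condition_b": cond_b,
            "n_a": len(a), "n_b": len(b),
        }
        if len(a) < min_cells or len(b) < min_cells:
            rec_row.update(
                magnitude_p=np.nan, magnitude_delta=np.nan, direction="",
                phase_delta=np.nan, phase_p=np.nan, skipped=True,
            )
            rows.append(rec_row)
            continue
        res = mannwhitneyu(a["magnitude"], b["magnitude"], alternative="two-sided")
        delta = float(a["magnitude"].median() - b["magnitude"].median())
        nz_a = a.loc[a["magnitude"] > 0, "phase"].to_numpy()
        nz_b = b.loc[b["magnitude"] > 0, "phase"].to_numpy()
        rng = np.random.default_rng(child_seed(seed, "proximity-phase", stratum))
        ph_delta, ph_p = compare_phases(nz_a, nz_b, n_perm=n_perm, rng=rng, min_n=min_cells)
        rec_row.update(
            magnitude_p=float(res.pvalue), magnitude_delta=delta,
            direction=f"{cond_a}>{cond_b}" if delta > 0 else f"{cond_b}>{cond_a}",
            phase_delta=ph_delta, phase_p=ph_p, skipped=False,
        )
        rows.append(rec_row)
    return pd.DataFrame(rows)


def gene_velocity_distance_correlation(
    v: pd.DataFrame,
    records: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> pd.DataFrame:
    """Per-gene Pearson correlation between per-cell velocity and boundary
    distance, with a permutation p (distances permuted across cells) and BH
    adjustment across genes. Genes with zero velocity variance are skipped.
    """
    rec = records.dropna(subset=["min_boundary_distance"]).set_index("cell_id")
    common = v.index.intersection(rec.index)
    if len(common) < min_cells:
        return pd.DataFrame(columns=["gene", "r", "p", "q", "skipped"])
    d = rec.loc[common, "min_boundary_distance"].to_numpy(dtype=float)
    vv = v.loc[common]
    if np.std(d) == 0:
        raise ValueError("distance has zero variance; correlation undefined")
    rng = np.random.default_rng(child_seed(seed, "gene-distance"))
    d_c = d - d.mean()
    d_sd = np.sqrt((d_c**2).sum())
    perms = np.stack([rng.permutation(len(d)) for _ in range(n_perm)])
    d_perm = d_c[perms]  # (n_perm, n)
    rows = []
    for g in vv.columns:
        x = vv[g].to_numpy(dtype=float)
        if np.std(x) == 0:
            rows.append({"gene": g, "r": np.nan, "p": np.nan, "skipped": True})
            continue
        x_c = x - x.mean()
        x_sd = np.sqrt((x_c**2).sum())
        r_obs = float((x_c @ d_c) / (x_sd * d_sd))
        r_perm = (d_perm @ x_c) / (x_sd * d_sd)
        p = (1.0 + np.count_nonzero(np.abs(r_perm) >= abs(r_obs) - 1e-12)) / (n_perm + 1.0)
        rows.append({"gene": g, "r": r_obs, "p": p, "skipped": False})
    out = pd.DataFrame(rows)
    q = np.full(len(out), np.nan)
    tested = out["p"].notna().to_numpy()
    if tested.any():
        q[tested] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["q"] = q
    return out
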