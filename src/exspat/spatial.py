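"""Grid-based differential spatial statistics.

The core screen voxelizes each gene's molecules per FOV onto a fixed
10 × 10 × 10 μm lattice, computes global Moran's I with binary face-adjacent
(6-neighbor) weights over all lattice voxels (empty voxels included, so the
weight graph is identical across FOVs), and compares conditions by a
permutation test on per-FOV values with FOVs as the replicate unit. The same
permutation machinery is applied to depth-normalized per-FOV expression.
P values are Benjamini–Hochberg adjusted per region, separately for the
expression and the spatial family, and each gene is categorized as
expression-only, spatial-only, both, or neither.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_VOXEL_SIZE = 10.0
DEFAULT_MIN_SPOTS = 10


class OutOfBoundsError(ValueError):
    """A spot falls outside the declared voxelization bounds."""


@dataclass
class VoxelGrid:
    counts: np.ndarray  # (nx, ny, nz) non-negative ints
    origin: tuple[float, float, float]
    voxel_size: float
    gene: str = ""
    fov_id: str = ""

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.counts.shape


@dataclass
class MoranStat:
    gene: str
    fov_id: str
    I: float  # NaN when invalid
    n_voxels: int
    weight_sum: float
    n_spots: int
    valid: bool


def voxelize(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    voxel_size: float = DEFAULT_VOXEL_SIZE,
    bounds: tuple[float, float, float] = (100.0, 100.0, 30.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    gene: str = "",
    fov_id: str = "",
    spot_ids: np.ndarray | None = None,
) -> VoxelGrid:
    """Bin spots onto a half-open lattice: voxel i spans
    [origin + i·s, origin + (i+1)·s). Counts conserve the spot number and
    empty voxels inside the bounds are retained as zeros."""
    if voxel_size <= 0:
        raise ValueError("voxel_size must be > 0")
    coords = np.column_stack([x, y, z]).astype(float)
    origin_a = np.asarray(origin, dtype=float)
    extent = np.asarray(bounds, dtype=float)
    dims = np.ceil(extent / voxel_size - 1e-9).astype(int)
    dims = np.maximum(dims, 1)
    idx = np.floor((coords - origin_a) / voxel_size).astype(int)
    bad = np.any((idx < 0) | (idx >= dims), axis=1)
    if bad.any():
        which = np.flatnonzero(bad)[0]
        sid = spot_ids[which] if spot_ids is not None else f"row {which}"
        raise OutOfBoundsError(f"spot {sid} lies outside the voxelization bounds")
    counts = np.zeros(tuple(dims), dtype=np.int64)
    np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1)
    return VoxelGrid(counts, tuple(origin_a), float(voxel_size), gene, fov_id)


def morans_i(grid: VoxelGrid, min_spots: int = DEFAULT_MIN_SPOTS) -> MoranStat:
    """Global Moran's I over the full lattice with binary 6-neighbor weights:

        I = (N / W) · Σ_ij w_ij (x_i − x̄)(x_j − x̄) / Σ_i (x_i − x̄)²

    Degenerate fields (constant counts or fewer than ``min_spots`` molecules)
    yield ``valid=False`` with a NaN statistic rather than an exception.
    """
    counts = grid.counts.astype(float)
    n_spots = int(counts.sum())
    n_voxels = counts.size
    # directed weight sum: each face-adjacent pair counted twice
    nx, ny, nz = counts.shape
    weight_sum = 2.0 * ((nx - 1) * ny * nz + nx * (ny - 1) * nz + nx * ny * (nz - 1))
    dev = counts - counts.mean()
    denom = float((dev**2).sum())
    if n_spots < min_spots or denom == 0.0 or weight_sum == 0.0:
        return MoranStat(grid.gene, grid.fov_id, float("nan"), n_voxels, weight_sum, n_spots, False)
    num = 0.0
    for axis in range(3):
        lead = np.take(dev, range(1, counts.shape[axis]), axis=axis)
        lag = np.take(dev, range(0, counts.shape[axis] - 1), axis=axis)
        num += 2.0 * float((lead * lag).sum())
    value = (n_voxels / weight_sum) * num / denom
    return MoranStat(grid.gene, grid.fov_id, value, n_voxels, weight_sum, n_spots, True)


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q values (q monotone in p-rank,
    q ≤ 1, q ≥ p)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def permutation_diff_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int,
    rng: np.random.Generator | int,
) -> tuple[float, float]:
    """Two-sided permutation test on T = mean(A) − mean(B) under random
    relabelings of the group labels, with the add-one convention
    p = (1 + #{|T_perm| ≥ |T_obs|}) / (n_perm + 1)."""
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    pooled = np.concatenate([a, b])
    n_a, n = len(a), len(pooled)
    t_obs = a.mean() - b.mean()
    perms = rng.permuted(np.broadcast_to(pooled, (n_perm, n)).copy(), axis=1)
    t_perm = perms[:, :n_a].mean(axis=1) - perms[:, n_a:].mean(axis=1)
    p = (1.0 + np.count_nonzero(np.abs(t_perm) >= abs(t_obs) - 1e-12)) / (n_perm + 1.0)
    return float(t_obs), float(p)


def fov_depth_factors(spots: pd.DataFrame) -> pd.Series:
    """Per-FOV depth scale factors by median-of-ratios (DESeq-style) size
    factors: for each FOV the median, over genes, of its count relative to
    the gene's geometric mean across FOVs, rescaled to unit median.

    Unlike total-count scaling this is robust to a minority of genuinely
    shifted genes, which would otherwise bias every other gene's
    depth-normalized value in the shifted condition.
    """
    counts = spots.groupby(["gene", "fov_id"]).size().unstack(fill_value=0)
    log_counts = np.log(counts.where(counts > 0))
    log_ratios = log_counts.sub(log_counts.mean(axis=1), axis=0)
    size = np.exp(log_ratios.median(axis=0))
    size = size.fillna(1.0)
    size = size / size.median()
    return 1.0 / size


def _categorize(de_sig: bool, sp_sig: bool) -> str:
    if de_sig and sp_sig:
        return "both"
    if de_sig:
        return "expression_only"
    if sp_sig:
        return "spatial_only"
    return "neither"


def region_screen(
    spots: pd.DataFrame,
    cells: pd.DataFrame,
    region: str,
    panel: list[str] | None = None,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    voxel_size: float = DEFAULT_VOXEL_SIZE,
    fov_size: tuple[float, float, float] = (100.0, 100.0, 30.0),
    min_spots: int = DEFAULT_MIN_SPOTS,
    min_fovs: int = 2,
    permute_by: str = "fov",
) -> pd.DataFrame:
    """Per-gene differential screen within one hippocampal region.

    For every panel gene, runs the permutation test on (a) depth-normalized
    per-FOV expression and (b) per-FOV grid Moran's I, BH-adjusts each
    family separately within the region, and categorizes each gene by
    (de_q < α, moran_q < α). FOVs with an invalid Moran's I for a gene are
    dropped pairwise before permutation; genes with fewer than ``min_fovs``
    valid FOVs in either condition are emitted as skip records
    (``skipped=True`` with NaN statistics).

    ``permute_by="sample"`` relabels whole samples instead of FOVs — the
    conservative variant acknowledging technical-replicate pseudoreplication.
    """
    from ._utils import child_seed

    regions_present = set(cells["region"])
    if region not in regions_present:
        raise KeyError(f"region {region!r} absent from cell table")
    fov_meta = (
        cells[cells["region"] == region][["fov_id", "condition", "sample_id"]]
        .drop_duplicates()
        .set_index("fov_id")
    )
    fov_ids = fov_meta.index.to_numpy()
    conditions = sorted(fov_meta["condition"].unique())
    if len(conditions) != 2:
        raise ValueError(f"region {region!r} needs exactly 2 conditions, found {conditions}")
    cond_a, cond_b = conditions
    rspots = spots[spots["fov_id"].isin(fov_ids)]
    if panel is None:
        panel = sorted(rspots["gene"].unique())

    depth = fov_depth_factors(rspots)
    counts = (
        rspots.groupby(["gene", "fov_id"]).size().unstack(fill_value=0)
        .reindex(index=panel, columns=fov_ids, fill_value=0)
    )
    expr = counts.mul(depth.reindex(fov_ids), axis=1)

    # per-(gene, FOV) Moran's I on the fixed lattice
    moran = pd.DataFrame(np.nan, index=panel, columns=fov_ids)
    for fov, fspots in rspots.groupby("fov_id"):
        for gene, gspots in fspots.groupby("gene"):
            if gene not in moran.index:
                continue
            grid = voxelize(
                gspots["x"].to_numpy(), gspots["y"].to_numpy(), gspots["z"].to_numpy(),
                voxel_size=voxel_size, bounds=fov_size, gene=gene, fov_id=fov,
            )
            stat = morans_i(grid, min_spots=min_spots)
            if stat.valid:
                moran.loc[gene, fov] = stat.I

    is_a = (fov_meta["condition"] == cond_a).to_numpy()
    sample_of = fov_meta["sample_id"].to_numpy()

    rows = []
    for gene in panel:
        grec: dict = {"gene": gene, "region": region, "condition_a": cond_a, "condition_b": cond_b}
        gene_rng = np.random.default_rng(child_seed(seed, "screen", region, gene))
        for family, values in (("de", expr.loc[gene]), ("moran", moran.loc[gene])):
            vals = values.to_numpy(dtype=float)
            ok = np.isfinite(vals)
            a, b = vals[ok & is_a], vals[ok & ~is_a]
            if len(a) < min_fovs or len(b) < min_fovs:
                grec[f"{family}_stat"], grec[f"{family}_p"] = np.nan, np.nan
                grec[f"{family}_skipped"] = True
                continue
            if permute_by == "sample":
                stat, p = _sample_permutation_test(
                    vals[ok], is_a[ok], sample_of[ok], n_perm, gene_rng
                )
            else:
                stat, p = permutation_diff_test(a, b, n_perm, gene_rng)
            grec[f"{family}_stat"], grec[f"{family}_p"] = stat, p
            grec[f"{family}_skipped"] = False
        rows.append(grec)
    out = pd.DataFrame(rows)

    for family in ("de", "moran"):
        q = np.full(len(out), np.nan)
        tested = out[f"{family}_p"].notna().to_numpy()
        if tested.any():
            q[tested] = bh_adjust(out.loc[tested, f"{family}_p"].to_numpy())
        out[f"{family}_q"] = q
    out["category"] = [
        _categorize(bool(dq < alpha), bool(mq < alpha)) if np.isfinite(dq) or np.isfinite(mq)
        else "neither"
        for dq, mq in zip(out["de_q"].fillna(np.inf), out["moran_q"].fillna(np.inf))
    ]
    out["skipped"] = out["de_skipped"] & out["moran_skipped"]
    return out


def _sample_permutation_test(values, is_a, sample_of, n_perm, rng):
    """Permute condition labels at the sample level (conservative variant)."""
    samples = np.unique(sample_of)
    sample_is_a = np.array([is_a[sample_of == s][0] for s in samples])
    t_obs = values[is_a].mean() - values[~is_a].mean()
    n_a = int(sample_is_a.sum())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(samples))
        lab = np.isin(sample_of, samples[perm[:n_a]])
        if lab.all() or not lab.any():
            continue
        t = values[lab].mean() - values[~lab].mean()
        if abs(t) >= abs(t_obs) - 1e-12:
            count += 1
    return float(t_obs), (1.0 + count) / (n_perm + 1.0)


def venn_summary(results: pd.DataFrame) -> dict[str, int]:
    """Counts of the four differential categories (the Venn view)."""
    counts = results["category"].value_counts().to_dict()
    return {k: int(counts.get(k, 0)) for k in ("expression_only", "spatial_only", "both", "neither")}


@dataclass
class AxisDensityResult:
    gene: str
    axis_origin: np.ndarray
    axis_direction: np.ndarray
    grid: np.ndarray
    density_a: np.ndarray
    density_b: np.ndarray
    bandwidth_a: float
    bandwidth_b: float
    ks_statistic: float
    ks_p: float
    n_a: int
    n_b: int
    skipped: bool = False


def axis_density_compare(
    spots_a: pd.DataFrame,
    spots_b: pd.DataFrame,
    gene: str,
    axis: tuple[np.ndarray, np.ndarray] | None = None,
    min_spots: int = 20,
    grid_points: int = 256,
    bandwidth: float | str = "scott",
) -> AxisDensityResult:
    """Compare a gene's 1D density profiles along a tissue axis.

    Spot coordinates are projected onto the axis (default: the first
    principal axis of the pooled cloud), a Gaussian KDE is evaluated per
    condition for display, and a two-sample Kolmogorov–Smirnov test is run
    on the raw projections so the test is bandwidth-free.
    """
    pa = spots_a[spots_a["gene"] == gene][["x", "y", "z"]].to_numpy(dtype=float)
    pb = spots_b[spots_b["gene"] == gene][["x", "y", "z"]].to_numpy(dtype=float)
    if len(pa) < min_spots or len(pb) < min_spots:
        return AxisDensityResult(
            gene, np.zeros(3), np.zeros(3), np.array([]), np.array([]), np.array([]),
            np.nan, np.nan, np.nan, np.nan, len(pa), len(pb), skipped=True,
        )
    if axis is None:
        pooled = np.vstack([pa, pb])
        origin = pooled.mean(axis=0)
        _, _, vt = np.linalg.svd(pooled - origin, full_matrices=False)
        direction = vt[0]
        if direction[np.argmax(np.abs(direction))] < 0:
            direction = -direction  # deterministic orientation
    else:
        origin, direction = np.asarray(axis[0], float), np.asarray(axis[1], float)
        direction = direction / np.linalg.norm(direction)
    proj_a = (pa - origin) @ direction
    proj_b = (pb - origin) @ direction
    ks = stats.ks_2samp(proj_a, proj_b)
    lo = min(proj_a.min(), proj_b.min())
    hi = max(proj_a.max(), proj_b.max())
    pad = 0.05 * (hi - lo or 1.0)
    grid = np.linspace(lo - pad, hi + pad, grid_points)
    kde_a = stats.gaussian_kde(proj_a, bw_method=bandwidth)
    kde_b = stats.gaussian_kde(proj_b, bw_method=bandwidth)
    return AxisDensityResult(
        gene, origin, direction, grid, kde_a(grid), kde_b(grid),
        float(kde_a.factor), float(kde_b.factor),
        float(ks.statistic), float(ks.pvalue), len(pa), len(pb),
    )


def moran_stat_frame(stats_list: list[MoranStat]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in stats_list])
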