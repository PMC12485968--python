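"""Technical-validation computations: FOV expression profiles, Spearman
correlation matrix, PCA + k-means clustering of FOVs, and
reference-correlation cell typing."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .dataio import SchemaError


def fov_expression_matrix(spots: pd.DataFrame, panel: list[str] | None = None) -> pd.DataFrame:
    """Genes × FOVs molecule-count matrix; entry (g, f) is the number of
    spots of gene g in FOV f, so the matrix total equals the spot count."""
    if spots.empty:
        raise ValueError("spot table is empty")
    mat = spots.groupby(["gene", "fov_id"]).size().unstack(fill_value=0)
    if panel is not None:
        mat = mat.reindex(index=panel, fill_value=0)
    return mat


def normalize_profiles(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each FOV's counts to the median FOV total, then log1p.

    Sequencing depth varies severalfold across samples, so depth must be
    removed before comparing FOV profiles.
    """
    totals = matrix.sum(axis=0)
    scale = totals.median() / totals.replace(0, np.nan)
    return np.log1p(matrix.mul(scale.fillna(0.0), axis=1))


def fov_spearman_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation matrix of FOV expression profiles
    (symmetric, unit diagonal)."""
    if matrix.shape[1] == 1:
        return pd.DataFrame([[1.0]], index=matrix.columns, columns=matrix.columns)
    rho = stats.spearmanr(matrix.to_numpy(), axis=0).statistic
    rho = np.atleast_2d(rho)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=matrix.columns, columns=matrix.columns)


def fov_pca_kmeans(
    matrix: pd.DataFrame, k: int, seed: int, n_init: int = 10
) -> tuple[pd.Series, pd.DataFrame]:
    """PCA (2 components) of normalized, log1p FOV profiles followed by
    k-means; returns per-FOV cluster labels in 0..k−1 and 2D coordinates.
    Deterministic given ``seed`` (multi-start k-means, best inertia kept)."""
    n_fovs = matrix.shape[1]
    if not 2 <= k <= n_fovs:
        raise ValueError(f"k must satisfy 2 <= k <= number of FOVs ({n_fovs})")
    profiles = normalize_profiles(matrix).T.to_numpy()
    n_comp = min(2, n_fovs, matrix.shape[0])
    coords = PCA(n_components=n_comp, random_state=seed, svd_solver="full").fit_transform(profiles)
    labels = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit_predict(coords)
    coord_df = pd.DataFrame(coords, index=matrix.columns, columns=[f"PC{i+1}" for i in range(n_comp)])
    return pd.Series(labels, index=matrix.columns, name="cluster"), coord_df


def assign_cell_types(
    counts: pd.DataFrame,
    reference: pd.DataFrame,
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Assign each cell the reference type with maximal Spearman correlation
    of its count profile against the reference signatures.

    ``counts`` is cells × genes, ``reference`` is types × genes over the same
    panel. Ties break by reference row order; cells whose best correlation is
    below ``threshold`` (including degenerate all-zero cells) are labeled
    ``"unknown"`` rather than force-assigned.
    """
    if set(counts.columns) != set(reference.columns):
        raise SchemaError("reference signatures cover a different gene set than the counts")
    if (reference.to_numpy() < 0).any():
        raise ValueError("reference profiles must be non-negative")
    ref = reference[counts.columns].to_numpy(dtype=float)
    x = counts.to_numpy(dtype=float)
    # rank-transform once, then correlate via Pearson on ranks
    xr = stats.rankdata(x, axis=1)
    rr = stats.rankdata(ref, axis=1)
    xr_c = xr - xr.mean(axis=1, keepdims=True)
    rr_c = rr - rr.mean(axis=1, keepdims=True)
    x_sd = np.sqrt((xr_c**2).sum(axis=1))
    r_sd = np.sqrt((rr_c**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (xr_c @ rr_c.T) / np.outer(x_sd, r_sd)
    corr = np.nan_to_num(corr, nan=-np.inf)  # zero-variance cells -> unknown
    best = corr.argmax(axis=1)
    best_corr = corr[np.arange(len(x)), best]
    labels = np.asarray(reference.index, dtype=object)[best]
    labels = np.where(best_corr >= threshold, labels, "unknown")
    return pd.DataFrame(
        {"cell_type": labels, "correlation": np.where(np.isfinite(best_corr), best_corr, np.nan)},
        index=counts.index,
    )


def cell_by_gene_counts(spots: pd.DataFrame, panel: list[str] | None = None) -> pd.DataFrame:
    """Cells × genes count matrix from cell-assigned spots."""
    assigned = spots[spots["cell_id"] != "NA"]
    mat = assigned.groupby(["cell_id", "gene"]).size().unstack(fill_value=0)
    if panel is not None:
        mat = mat.reindex(columns=panel, fill_value=0)
    return mat
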