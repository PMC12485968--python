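"""Single-cell neighborhood analysis.

Per cell type and sample, genes whose per-cell expression fraction is
spatially autocorrelated beyond the cell-type expectation are detected with
a kNN-graph Moran's I permutation test (a documented stand-in with the same
input/output contract as dedicated spatially-variable-gene detectors).
Detected genes are clustered by shared per-cell expression (average-linkage
hierarchical clustering on 1 − Spearman distance), clusters are intersected
across the samples of each condition by greedy Jaccard matching, and
clusters recurrent in one condition but unmatched in the other are reported
as condition-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.neighbors import NearestNeighbors

from ._utils import child_seed
from .dataio import UNASSIGNED
from .spatial import bh_adjust

DEFAULT_MIN_CELLS = 30
DEFAULT_MIN_COUNTS = 5  # cells below this total are excluded
DEFAULT_K = 6
DEFAULT_CLUSTER_THRESHOLD = 0.7
DEFAULT_JACCARD_MIN = 0.5


@dataclass
class GeneCluster:
    cell_type: str
    sample_id: str
    members: frozenset[str]


@dataclass
class RecurrentCluster:
    cell_type: str
    condition: str
    consensus: frozenset[str]
    jaccard_by_sample: dict[str, float] = field(default_factory=dict)


def knn_moran(
    fractions: np.ndarray,
    coords: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    k: int = DEFAULT_K,
) -> tuple[np.ndarray, np.ndarray]:
    """Moran's I of each column of ``fractions`` over a binary k-nearest-
    neighbor graph of ``coords``, with a permutation null (cells shuffled
    jointly across columns). Returns (I values, add-one p values)."""
    n_cells, n_genes = fractions.shape
    k = min(k, n_cells - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, nbr = nn.kneighbors(coords)
    src = np.repeat(np.arange(n_cells), k)
    dst = nbr[:, 1:].ravel()  # drop self
    w_sum = float(len(src))

    dev = fractions - fractions.mean(axis=0)
    denom = (dev**2).sum(axis=0)
    ok = denom > 0

    def moran(d: np.ndarray) -> np.ndarray:
        num = (d[src] * d[dst]).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            return (n_cells / w_sum) * num / denom

    i_obs = moran(dev)
    count = np.zeros(n_genes)
    for _ in range(n_perm):
        perm = rng.permutation(n_cells)
        count += moran(dev[perm]) >= i_obs - 1e-12
    p = (1.0 + count) / (n_perm + 1.0)
    i_obs[~ok] = np.nan
    p[~ok] = np.nan
    return i_obs, p


def cell_fractions(
    spots: pd.DataFrame,
    cells: pd.DataFrame,
    panel: list[str],
    min_counts: int = DEFAULT_MIN_COUNTS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell gene fractions (count / cell total) and matching cell
    metadata; cells with fewer than ``min_counts`` total molecules are
    excluded so fractions are not dominated by shot noise."""
    assigned = spots[spots["cell_id"] != UNASSIGNED]
    counts = (
        assigned.groupby(["cell_id", "gene"]).size().unstack(fill_value=0)
        .reindex(columns=panel, fill_value=0)
    )
    totals = counts.sum(axis=1)
    counts = counts[totals >= min_counts]
    fractions = counts.div(counts.sum(axis=1), axis=0)
    meta = cells.set_index("cell_id").loc[fractions.index.intersection(cells["cell_id"])]
    fractions = fractions.loc[meta.index]
    return fractions, meta


def detect_svg(
    fractions: pd.DataFrame,
    centroids: np.ndarray,
    cell_type: str,
    sample_id: str,
    n_perm: int = 999,
    seed: int = 0,
    k: int = DEFAULT_K,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> pd.DataFrame:
    """Spatially-variable-gene records for one (cell type, sample) stratum.

    The statistic per gene is Moran's I of the per-cell fraction over the
    kNN graph of cell centroids; the null permutes fractions across cells;
    q values are BH-adjusted within the stratum. Returns an empty frame when
    the stratum has fewer than ``min_cells`` cells (the skip record is the
    caller's to log).
    """
    if len(fractions) < min_cells:
        return pd.DataFrame(
            columns=["gene", "cell_type", "sample_id", "statistic", "p", "q"]
        )
    rng = np.random.default_rng(child_seed(seed, "svg", cell_type, sample_id))
    i_vals, p_vals = knn_moran(fractions.to_numpy(dtype=float), centroids, n_perm, rng, k=k)
    out = pd.DataFrame(
        {
            "gene": fractions.columns,
            "cell_type": cell_type,
            "sample_id": sample_id,
            "statistic": i_vals,
            "p": p_vals,
        }
    )
    q = np.full(len(out), np.nan)
    tested = out["p"].notna().to_numpy()
    if tested.any():
        q[tested] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["q"] = q
    return out


def cluster_detected_genes(
    fractions: pd.DataFrame,
    detected: list[str],
    threshold: float = DEFAULT_CLUSTER_THRESHOLD,
) -> list[frozenset[str]]:
    """Average-linkage hierarchical clustering of detected genes at distance
    1 − Spearman correlation of per-cell fractions; tree cut at
    ``threshold``; singletons discarded."""
    detected = sorted(detected)
    if len(detected) < 2:
        return []
    sub = fractions[detected].to_numpy(dtype=float)
    rho = spearmanr(sub, axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho = np.atleast_2d(np.nan_to_num(rho, nan=0.0))
    dist = np.clip(1.0 - rho, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=threshold, criterion="distance")
    clusters = []
    for lab in np.unique(labels):
        members = frozenset(np.asarray(detected, dtype=object)[labels == lab])
        if len(members) >= 2:
            clusters.append(members)
    return sorted(clusters, key=lambda m: (-len(m), sorted(m)))


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def intersect_clusters(
    clusters_by_sample: dict[str, list[frozenset[str]]],
    cell_type: str,
    condition: str,
    jaccard_min: float = DEFAULT_JACCARD_MIN,
) -> list[RecurrentCluster]:
    """Greedy Jaccard matching of clusters across the samples of one
    condition. A cluster of the reference sample (first in sorted order) is
    recurrent iff every other sample contains a match with Jaccard ≥
    ``jaccard_min``; the consensus is the intersection of matched member
    sets. Matching ties break by larger cluster, then lexicographic order."""
    samples = sorted(clusters_by_sample)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples per condition")
    reference = clusters_by_sample[samples[0]]
    recurrent = []
    for anchor in sorted(reference, key=lambda m: (-len(m), sorted(m))):
        consensus = anchor
        jaccards = {samples[0]: 1.0}
        ok = True
        for s in samples[1:]:
            candidates = sorted(
                clusters_by_sample[s],
                key=lambda m: (-_jaccard(anchor, m), -len(m), sorted(m)),
            )
            if not candidates or _jaccard(anchor, candidates[0]) < jaccard_min:
                ok = False
                break
            jaccards[s] = _jaccard(anchor, candidates[0])
            consensus = consensus & candidates[0]
        if ok and consensus:
            recurrent.append(RecurrentCluster(cell_type, condition, frozenset(consensus), jaccards))
    return recurrent


def condition_specific_clusters(
    recurrent_a: list[RecurrentCluster],
    recurrent_b: list[RecurrentCluster],
    jaccard_min: float = DEFAULT_JACCARD_MIN,
) -> tuple[list[RecurrentCluster], list[RecurrentCluster]]:
    """A recurrent cluster is condition-specific iff no recurrent cluster of
    the other condition matches it at Jaccard ≥ ``jaccard_min``."""

    def specific(own, other):
        return [
            c for c in own
            if all(_jaccard(c.consensus, o.consensus) < jaccard_min for o in other)
        ]

    return specific(recurrent_a, recurrent_b), specific(recurrent_b, recurrent_a)


def neighborhood_analysis(
    spots: pd.DataFrame,
    cells: pd.DataFrame,
    panel: list[str],
    fov_offsets: pd.DataFrame | None = None,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    jaccard_min: float = DEFAULT_JACCARD_MIN,
    cluster_threshold: float = DEFAULT_CLUSTER_THRESHOLD,
    min_cells: int = DEFAULT_MIN_CELLS,
    cell_types: list[str] | None = None,
) -> dict:
    """Full neighborhood workflow: SVG detection per (cell type, sample),
    gene clustering, per-condition intersection, condition-specific report.

    When ``fov_offsets`` is given, cell centroids are mapped into sample
    space so the kNN graph spans FOVs; otherwise FOV-local coordinates are
    used (neighbors then still form within FOVs, since tiles are disjoint).
    """
    fractions, meta = cell_fractions(spots, cells, panel)
    coords = meta[["cx", "cy", "cz"]].to_numpy(dtype=float).copy()
    if fov_offsets is not None:
        off = fov_offsets.set_index("fov_id")
        coords[:, 0] += off.loc[meta["fov_id"], "x_offset"].to_numpy()
        coords[:, 1] += off.loc[meta["fov_id"], "y_offset"].to_numpy()
        coords[:, 2] += off.loc[meta["fov_id"], "z_offset"].to_numpy()

    if cell_types is None:
        cell_types = sorted(meta["cell_type"].unique())
    sample_condition = dict(zip(cells["sample_id"], cells["condition"]))

    svg_frames, skips = [], []
    clusters: dict[tuple[str, str], list[frozenset[str]]] = {}
    for ct in cell_types:
        for sample in sorted(meta["sample_id"].unique()):
            sel = (meta["cell_type"] == ct) & (meta["sample_id"] == sample)
            if sel.sum() < min_cells:
                skips.append({"cell_type": ct, "sample_id": sample, "n_cells": int(sel.sum())})
                clusters[(ct, sample)] = []
                continue
            frac_ct = fractions[sel.to_numpy()]
            rec = detect_svg(
                frac_ct, coords[sel.to_numpy()], ct, sample,
                n_perm=n_perm, seed=seed, min_cells=min_cells,
            )
            svg_frames.append(rec)
            detected = rec.loc[rec["q"] < alpha, "gene"].tolist()
            clusters[(ct, sample)] = cluster_detected_genes(
                frac_ct, detected, threshold=cluster_threshold
            )

    svg = (
        pd.concat(svg_frames, ignore_index=True)
        if svg_frames
        else pd.DataFrame(columns=["gene", "cell_type", "sample_id", "statistic", "p", "q"])
    )

    conditions = sorted(set(sample_condition.values()))
    recurrent: dict[str, list[RecurrentCluster]] = {c: [] for c in conditions}
    for ct in cell_types:
        for cond in conditions:
            by_sample = {
                s: clusters[(ct, s)]
                for s in sorted({s for (t, s) in clusters if t == ct})
                if sample_condition.get(s) == cond
            }
            if len(by_sample) >= 2:
                recurrent[cond].extend(intersect_clusters(by_sample, ct, cond, jaccard_min))

    specific: dict[str, list[RecurrentCluster]] = {c: [] for c in conditions}
    if len(conditions) == 2:
        a, b = conditions
        for ct in cell_types:
            rec_a = [c for c in recurrent[a] if c.cell_type == ct]
            rec_b = [c for c in recurrent[b] if c.cell_type == ct]
            spec_a, spec_b = condition_specific_clusters(rec_a, rec_b, jaccard_min)
            specific[a].extend(spec_a)
            specific[b].extend(spec_b)

    return {
        "svg_records": svg,
        "clusters": clusters,
        "recurrent": recurrent,
        "condition_specific": specific,
        "skips": skips,
    }
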