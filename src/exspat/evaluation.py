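"""Property-based evaluation runs: independent oracles, null calibrations
and planted-effect recovery studies.

Every function here regenerates its inputs from scratch through the
synthetic generator (or direct simulation of a test's null) and measures
the pipeline's behavior against ground truth. The brute-force references
(:func:`morans_i_reference`, :func:`boundary_distances_reference`) are
deliberately naive double loops kept independent of the vectorized
implementations they check.

Problem sizes are scaled study conditions: effect parameters follow the
planted-effect definitions (cluster concentration 20 with 20 FOVs per
condition, nuclear:cytoplasmic ratio ×3 with 200 cells per side, proximity
boost ×2 with ~300 cells, a 3-gene module in every sample of one
condition), while panel size and molecule counts per FOV are reduced
proportionally so per-gene depth matches the full-scale design.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import neighborhood, pipeline, proximity, spatial, synthetic, velocity
from ._utils import child_seed
from .synthetic import CellTypeSpec, PlantedEffect, SimulationConfig
from .velocity import CompartmentCounts

ALPHA = 0.05


# ---------------------------------------------------------------------------
# independent oracles


def morans_i_reference(counts: np.ndarray) -> float:
    """O(N²) double-loop Moran's I with binary 6-neighbor weights over the
    full lattice. Returns NaN for constant fields."""
    x = counts.astype(float).ravel()
    shape = counts.shape
    coords = [np.unravel_index(i, shape) for i in range(x.size)]
    dev = x - x.mean()
    denom = (dev**2).sum()
    if denom == 0:
        return float("nan")
    num = 0.0
    w_sum = 0.0
    for i in range(x.size):
        for j in range(x.size):
            if i == j:
                continue
            diff = sum(abs(a - b) for a, b in zip(coords[i], coords[j]))
            if diff == 1:  # face-adjacent
                num += dev[i] * dev[j]
                w_sum += 1.0
    return (x.size / w_sum) * num / denom


def boundary_distances_reference(
    cells: pd.DataFrame, source_type: str, target_type: str
) -> pd.Series:
    """All-pairs within-FOV minimum boundary distance (sphere proxy)."""
    out = {}
    for _, src in cells[cells["cell_type"] == source_type].iterrows():
        best = np.nan
        for _, tgt in cells.iterrows():
            if tgt["fov_id"] != src["fov_id"] or tgt["cell_type"] != target_type:
                continue
            if tgt["cell_id"] == src["cell_id"]:
                continue
            d = np.sqrt(
                (src["cx"] - tgt["cx"]) ** 2
                + (src["cy"] - tgt["cy"]) ** 2
                + (src["cz"] - tgt["cz"]) ** 2
            )
            d = max(0.0, d - src["radius"] - tgt["radius"])
            if np.isnan(best) or d < best:
                best = d
        out[src["cell_id"]] = best
    return pd.Series(out)


# ---------------------------------------------------------------------------
# criterion runs


def moran_oracle_check(n_grids: int = 200, seed: int = 0) -> dict:
    """Vectorized Moran's I vs the double-loop reference on random grids up
    to 6×6×3, plus the closed-form 1D and checkerboard examples."""
    rng = np.random.default_rng(child_seed(seed, "moran-oracle"))
    max_diff = 0.0
    for _ in range(n_grids):
        dims = (rng.integers(1, 7), rng.integers(1, 7), rng.integers(1, 4))
        if np.prod(dims) < 2:
            dims = (2, 2, 1)
        counts = rng.poisson(rng.uniform(0.3, 4.0), size=dims)
        if counts.max() == counts.min():
            counts.flat[0] += 1
        grid = spatial.VoxelGrid(counts, (0, 0, 0), 10.0)
        ours = spatial.morans_i(grid, min_spots=0).I
        ref = morans_i_reference(counts)
        max_diff = max(max_diff, abs(ours - ref))
    line = spatial.VoxelGrid(np.array([1, 1, 0, 0]).reshape(1, 4, 1), (0, 0, 0), 10.0)
    checker = spatial.VoxelGrid(np.array([[1, 0], [0, 1]]).reshape(2, 2, 1), (0, 0, 0), 10.0)
    return {
        "max_abs_diff": float(max_diff),
        "line_value": float(spatial.morans_i(line, min_spots=0).I),
        "checkerboard_value": float(spatial.morans_i(checker, min_spots=0).I),
        "n_grids": n_grids,
    }


def _null_config(seed: int, n_genes: int = 100) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        n_samples_per_condition=2,
        fovs_per_region_per_sample=5,
        mean_molecules_per_fov=8000.0,
        cells_per_fov=30.0,
        regions=("DG-CA1",),
    )


def permutation_calibration(
    seed: int = 0, n_datasets: int = 10, n_genes: int = 100, n_perm: int = 499
) -> dict:
    """Null rejection rates of the per-region permutation tests (expression
    and Moran families) and of the per-gene velocity MWU, over
    ``n_datasets × n_genes`` replicates generated without planted effects."""
    expr_p, moran_p, mwu_p = [], [], []
    for i in range(n_datasets):
        ds = synthetic.generate_dataset(_null_config(child_seed(seed, "calib", i), n_genes))
        res = spatial.region_screen(
            ds.spots, ds.cells, "DG-CA1", panel=ds.panel,
            n_perm=n_perm, seed=child_seed(seed, "calib-screen", i),
        )
        expr_p.extend(res["de_p"].dropna().tolist())
        moran_p.extend(res["moran_p"].dropna().tolist())

        counts, gamma, v, _ = velocity.velocity_analysis(ds.spots, ds.cells, ds.panel)
        is_a = (counts.meta["condition"] == ds.config.conditions[0]).to_numpy()
        gt = velocity.gene_velocity_difftest(v[is_a], v[~is_a])
        mwu_p.extend(gt["p"].dropna().tolist())
    return {
        "expression_rejection_rate": float(np.mean(np.asarray(expr_p) < ALPHA)),
        "moran_rejection_rate": float(np.mean(np.asarray(moran_p) < ALPHA)),
        "velocity_mwu_rejection_rate": float(np.mean(np.asarray(mwu_p) < ALPHA)),
        "n_expression": len(expr_p),
        "n_moran": len(moran_p),
        "n_velocity_mwu": len(mwu_p),
    }


def phase_calibration(
    seed: int = 0, n_reps: int = 1000, n: int = 50, kappa: float = 2.0, n_perm: int = 199
) -> dict:
    """Type-I error of the circular-mean permutation test: both groups drawn
    from the same von Mises distribution."""
    rng = np.random.default_rng(child_seed(seed, "phase-calib"))
    rejections = 0
    for _ in range(n_reps):
        mu = rng.uniform(-np.pi, np.pi)
        a = rng.vonmises(mu, kappa, n)
        b = rng.vonmises(mu, kappa, n)
        _, p = velocity.compare_phases(a, b, n_perm=n_perm, rng=rng)
        rejections += p < ALPHA
    return {"phase_rejection_rate": rejections / n_reps, "n_reps": n_reps}


def spatial_only_recovery(seed: int = 0, n_seeds: int = 20, n_perm: int = 999) -> dict:
    """Recovery of the spatial-only phenomenon: a planted spatial shift
    (cluster concentration 20, 20 FOVs per condition) must be categorized
    spatial_only while its per-FOV expression stays unchanged by
    construction."""
    gene = "G005"
    hits, de_sig, expr_ratio = 0, 0, []
    for i in range(n_seeds):
        cfg = SimulationConfig(
            seed=child_seed(seed, "sponly", i),
            n_genes=30,
            n_samples_per_condition=2,
            fovs_per_region_per_sample=10,  # 20 FOVs per condition
            mean_molecules_per_fov=2400.0,
            cells_per_fov=30.0,
            regions=("DG-CA1",),
            planted_effects=(
                PlantedEffect(kind="spatial_shift", gene=gene, condition="5xFAD",
                              magnitude=20.0),
            ),
        )
        ds = synthetic.generate_dataset(cfg)
        res = spatial.region_screen(
            ds.spots, ds.cells, "DG-CA1", panel=ds.panel,
            n_perm=n_perm, seed=child_seed(seed, "sponly-screen", i),
        )
        row = res.set_index("gene").loc[gene]
        hits += row["category"] == "spatial_only"
        de_sig += row["de_p"] < ALPHA
        counts = ds.spots[ds.spots["gene"] == gene].groupby(
            ["fov_id"]).size().to_frame("n")
        cond = ds.cells[["fov_id", "condition"]].drop_duplicates().set_index("fov_id")
        counts = counts.join(cond)
        means = counts.groupby("condition")["n"].mean()
        expr_ratio.append(means["5xFAD"] / means["WT"])
    return {
        "spatial_only_sensitivity": hits / n_seeds,
        "expression_false_positive_rate": de_sig / n_seeds,
        "mean_expression_ratio": float(np.mean(expr_ratio)),
        "n_seeds": n_seeds,
    }


def gamma_recovery(seed: int = 0, n_reps: int = 20, n_cells: int = 500,
                   gamma_true: float = 0.5) -> dict:
    """γ estimation on steady-state data: s ~ Poisson(20), u ~ Poisson(γs)."""
    rng = np.random.default_rng(child_seed(seed, "gamma"))
    errors = []
    for _ in range(n_reps):
        s = rng.poisson(20.0, n_cells)
        u = rng.poisson(gamma_true * s)
        counts = CompartmentCounts(
            u=pd.DataFrame({"G1": u}),
            s=pd.DataFrame({"G1": s}),
            meta=pd.DataFrame(index=pd.RangeIndex(n_cells)),
        )
        fit = velocity.fit_gamma(counts)["G1"]
        errors.append(abs(fit - gamma_true) / gamma_true)
    errors = np.asarray(errors)
    return {
        "gamma_max_relative_error": float(errors.max()),
        "gamma_within_10pct_rate": float(np.mean(errors <= 0.10)),
        "n_reps": n_reps,
    }


def _velocity_config(seed: int, effects: tuple[PlantedEffect, ...],
                     fovs_per_sample: int = 5) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        n_genes=5,
        n_samples_per_condition=2,
        fovs_per_region_per_sample=fovs_per_sample,
        mean_molecules_per_fov=8000.0,
        cells_per_fov=40.0,
        regions=("DG-CA1",),
        gene_abundance_sd=0.2,
        cell_types=(
            CellTypeSpec("excitatory", 0.5, 6.0),
            CellTypeSpec("inhibitory", 0.3, 5.0),
            CellTypeSpec("endothelial", 0.2, 4.0),
        ),
        planted_effects=effects,
    )


def velocity_shift_recovery(seed: int = 0, n_seeds: int = 10) -> dict:
    """A nuclear:cytoplasmic ratio ×3 planted in excitatory neurons of one
    condition (~200 cells per side) must reach gene-level BH q < 0.05 and a
    stratum magnitude MWU p < 0.05."""
    gene = "G003"
    gene_hits, mag_hits, both = 0, 0, 0
    for i in range(n_seeds):
        eff = PlantedEffect(kind="velocity_shift", gene=gene, condition="5xFAD",
                            magnitude=3.0, cell_type="excitatory")
        ds = synthetic.generate_dataset(_velocity_config(child_seed(seed, "vel", i), (eff,)))
        counts, gamma, v, future = velocity.velocity_analysis(ds.spots, ds.cells, ds.panel)
        strata, _, gene_tables = velocity.stratify(
            counts, gamma, v, future, by_region=False, cell_types=["excitatory"],
            n_perm=199, seed=child_seed(seed, "vel-strat", i),
        )
        gt = gene_tables[("excitatory", "all")].set_index("gene")
        g_ok = bool(gt.loc[gene, "q"] < ALPHA)
        m_ok = bool(strata.iloc[0]["magnitude_p"] < ALPHA)
        gene_hits += g_ok
        mag_hits += m_ok
        both += g_ok and m_ok
    return {
        "velocity_gene_recovery_rate": gene_hits / n_seeds,
        "velocity_magnitude_recovery_rate": mag_hits / n_seeds,
        "velocity_joint_recovery_rate": both / n_seeds,
        "n_seeds": n_seeds,
    }


def proximity_recovery(seed: int = 0, n_seeds: int = 10) -> dict:
    """A ×2 nuclear:cytoplasmic boost at zero boundary distance, decaying
    with distance to excitatory neurons, planted in inhibitory neurons of
    one condition (~300 cells per side): the proximal (≤1 μm) stratum must
    show a significant magnitude increase in the affected condition while
    the non-proximal stratum stays non-significant. Also checks the
    vectorized distance computation against the all-pairs reference."""
    hits_prox, hits_dir, hits_nonprox_null, joint = 0, 0, 0, 0
    max_dist_diff = 0.0
    for i in range(n_seeds):
        eff = PlantedEffect(
            kind="proximity_velocity", gene="all", condition="5xFAD", magnitude=2.0,
            cell_type="inhibitory", target_type="excitatory", decay_scale=0.3,
        )
        ds = synthetic.generate_dataset(
            _velocity_config(child_seed(seed, "prox", i), (eff,), fovs_per_sample=13)
        )
        counts, gamma, v, future = velocity.velocity_analysis(ds.spots, ds.cells, ds.panel)
        records = proximity.proximity_records(ds.cells, "inhibitory", "excitatory")
        if i == 0:  # oracle equivalence once per run (the reference is slow)
            sub_cells = ds.cells[ds.cells["fov_id"].isin(ds.cells["fov_id"].unique()[:6])]
            ref = boundary_distances_reference(sub_cells, "inhibitory", "excitatory")
            got = proximity.boundary_distances(sub_cells, "inhibitory", "excitatory")
            got = got.set_index("cell_id")["min_boundary_distance"].reindex(ref.index)
            diff = np.abs(got.to_numpy() - ref.to_numpy())
            diff = diff[~np.isnan(diff)]
            max_dist_diff = max(max_dist_diff, float(diff.max()) if len(diff) else 0.0)
        sel = (counts.meta["cell_type"] == "inhibitory").to_numpy()
        genes = gamma.dropna().index
        disp = velocity.pca_displacement(counts.s[genes][sel], future[genes][sel],
                                         counts.meta[sel])
        strata = proximity.proximity_stratified_tests(
            disp, records, n_perm=199, seed=child_seed(seed, "prox-strat", i)
        ).set_index("stratum")
        p_ok = bool(strata.loc["proximal", "magnitude_p"] < ALPHA)
        d_ok = strata.loc["proximal", "direction"] == "5xFAD>WT"
        n_ok = not bool(strata.loc["non_proximal", "magnitude_p"] < ALPHA)
        hits_prox += p_ok
        hits_dir += p_ok and d_ok
        hits_nonprox_null += n_ok
        joint += p_ok and d_ok and n_ok
    return {
        "proximal_detection_rate": hits_prox / n_seeds,
        "proximal_correct_direction_rate": hits_dir / n_seeds,
        "nonproximal_null_rate": hits_nonprox_null / n_seeds,
        "proximity_joint_recovery_rate": joint / n_seeds,
        "distance_oracle_max_diff": max_dist_diff,
        "n_seeds": n_seeds,
    }


def neighborhood_recovery(seed: int = 0, n_seeds: int = 10) -> dict:
    """A 3-gene module planted (shared spatial gradient in excitatory
    neurons) in every sample of one condition must be reported as a
    condition-specific recurrent cluster with exactly the planted
    membership."""
    module = ("G010", "G011", "G012")
    exact, detected_any = 0, 0
    for i in range(n_seeds):
        cfg = SimulationConfig(
            seed=child_seed(seed, "nbhd", i),
            n_genes=30,
            n_samples_per_condition=3,
            fovs_per_region_per_sample=8,
            mean_molecules_per_fov=4000.0,
            cells_per_fov=40.0,
            regions=("DG-CA1",),
            gene_abundance_sd=0.2,
            region_profile_sd=0.1,
            cell_types=(
                CellTypeSpec("excitatory", 0.5, 6.0),
                CellTypeSpec("inhibitory", 0.3, 5.0),
                CellTypeSpec("endothelial", 0.2, 4.0),
            ),
            planted_effects=(
                PlantedEffect(kind="module_shift", gene=module, condition="5xFAD",
                              magnitude=2.5, cell_type="excitatory"),
            ),
        )
        ds = synthetic.generate_dataset(cfg)
        res = neighborhood.neighborhood_analysis(
            ds.spots, ds.cells, ds.panel, fov_offsets=ds.fov_offsets,
            n_perm=1999, seed=child_seed(seed, "nbhd-run", i),
            cell_types=["excitatory"],
        )
        specific = res["condition_specific"].get("5xFAD", [])
        members = [c.consensus for c in specific]
        exact += frozenset(module) in members
        detected_any += any(set(module) <= set(m) for m in members)
    return {
        "module_exact_recovery_rate": exact / n_seeds,
        "module_superset_recovery_rate": detected_any / n_seeds,
        "n_seeds": n_seeds,
    }


def determinism_check(seed: int = 0, out_root: str | Path | None = None) -> dict:
    """Two full pipeline runs with the same config and seed must produce
    hash-identical stage outputs."""
    config = {
        "seed": int(seed),
        "simulate": {
            "n_genes": 20,
            "n_samples_per_condition": 2,
            "fovs_per_region_per_sample": 5,
            "mean_molecules_per_fov": 1500.0,
            "cells_per_fov": 25.0,
            "regions": ["CA1", "DG-CA1"],
        },
        "qc": {"k": 2},
        "spatialdiff": {"n_perm": 199},
        "neighborhood": {"n_perm": 199},
        "velocity": {"n_perm": 199},
        "proximity": {"n_perm": 199, "source_type": "inhibitory",
                      "target_type": "excitatory"},
    }
    ctx = tempfile.TemporaryDirectory() if out_root is None else None
    root = Path(ctx.name) if ctx else Path(out_root)
    try:
        m1 = pipeline.run_pipeline(config, root / "run1")
        m2 = pipeline.run_pipeline(config, root / "run2")
        h1, h2 = pipeline.result_hashes(m1), pipeline.result_hashes(m2)
        mismatches = [k for k in h1 if h1[k] != h2.get(k)]
        return {
            "identical": float(h1 == h2),
            "n_outputs": len(h1),
            "mismatched_outputs": mismatches,
        }
    finally:
        if ctx:
            ctx.cleanup()
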