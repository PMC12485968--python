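import numpy as np
import pandas as pd
import pytest

from exspat import velocity
from exspat.dataio import UNASSIGNED
from exspat.velocity import CompartmentCounts


@pytest.fixture()
def tiny_counts():
    spots = pd.DataFrame({
        "spot_id": [f"s{i}" for i in range(7)],
        "gene": ["G1"] * 5 + ["G2"] * 2,
        "x": 0.0, "y": 0.0, "z": 0.0,
        "fov_id": "f1", "sample_id": "WT_s1",
        "cell_id": ["c1"] * 5 + ["c1", UNASSIGNED],
        "compartment": ["nuclear"] * 3 + ["cytoplasmic"] * 2 + ["cytoplasmic", UNASSIGNED],
    })
    cells = pd.DataFrame({
        "cell_id": ["c1"], "sample_id": ["WT_s1"], "fov_id": ["f1"],
        "cx": [0.0], "cy": [0.0], "cz": [0.0], "radius": [5.0],
        "cell_type": ["excitatory"], "region": ["CA1"], "condition": ["WT"],
    })
    return spots, cells


class TestCompartmentCounts:
    def test_tallies_match_labels(self, tiny_counts):
        spots, cells = tiny_counts
        counts = velocity.compartment_counts(spots, cells, panel=["G1", "G2"])
        assert counts.u.loc["c1", "G1"] == 3
        assert counts.s.loc["c1", "G1"] == 2
        assert counts.u.loc["c1", "G2"] == 0
        assert counts.s.loc["c1", "G2"] == 1

    def test_unassigned_ignored_and_totals_conserved(self, tiny_counts):
        spots, cells = tiny_counts
        counts = velocity.compartment_counts(spots, cells)
        assigned = (spots["cell_id"] != UNASSIGNED).sum()
        assert counts.u.to_numpy().sum() + counts.s.to_numpy().sum() == assigned

    def test_generator_nuclear_fraction_recovered(self, small_dataset):
        counts = velocity.compartment_counts(
            small_dataset.spots, small_dataset.cells, panel=small_dataset.panel)
        u_tot = counts.u.to_numpy().sum()
        s_tot = counts.s.to_numpy().sum()
        frac = u_tot / (u_tot + s_tot)
        lo, hi = small_dataset.config.nuclear_fraction_range
        assert lo - 0.05 < frac < hi + 0.05


class TestFitGamma:
    def _counts(self, u, s):
        n = len(u)
        return CompartmentCounts(
            u=pd.DataFrame({"G1": u}), s=pd.DataFrame({"G1": s}),
            meta=pd.DataFrame(index=pd.RangeIndex(n)),
        )

    def test_exact_line_recovers_slope(self):
        s = np.arange(1, 41)
        fit = velocity.fit_gamma(self._counts(2 * s, s), min_cells=10)
        assert fit["G1"] == pytest.approx(2.0)

    def test_all_zero_nuclear_gives_zero(self):
        s = np.arange(1, 41)
        fit = velocity.fit_gamma(self._counts(np.zeros_like(s), s), min_cells=10)
        assert fit["G1"] == 0.0

    def test_insufficient_cells_gives_nan(self):
        fit = velocity.fit_gamma(self._counts([1, 2], [1, 2]), min_cells=30)
        assert np.isnan(fit["G1"])

    def test_noisy_recovery_within_ten_percent(self):
        rng = np.random.default_rng(0)
        within = 0
        for _ in range(20):
            s = rng.poisson(20, 500)
            u = rng.poisson(0.5 * s)
            fit = velocity.fit_gamma(self._counts(u, s))
            within += abs(fit["G1"] - 0.5) / 0.5 <= 0.10
        assert within >= 19


class TestCellVelocity:
    def test_steady_state_has_zero_velocity_and_displacement(self):
        rng = np.random.default_rng(1)
        s = pd.DataFrame(rng.poisson(10, size=(50, 3)).astype(float),
                         columns=["G1", "G2", "G3"])
        gamma = pd.Series([0.5, 1.0, 2.0], index=s.columns)
        u = s * gamma
        counts = CompartmentCounts(u=u, s=s, meta=pd.DataFrame(index=s.index))
        v, future = velocity.cell_velocity(counts, gamma)
        np.testing.assert_allclose(v.to_numpy(), 0.0, atol=1e-12)
        np.testing.assert_allclose(future.to_numpy(), s.to_numpy(), atol=1e-12)
        disp = velocity.pca_displacement(s, future)
        np.testing.assert_allclose(disp["magnitude"], 0.0, atol=1e-9)
        np.testing.assert_allclose(disp["phase"], 0.0, atol=1e-12)

    def test_zero_dt_keeps_current_state(self):
        s = pd.DataFrame({"G1": [5.0, 10.0]})
        u = pd.DataFrame({"G1": [9.0, 1.0]})
        counts = CompartmentCounts(u=u, s=s, meta=pd.DataFrame(index=s.index))
        gamma = pd.Series([1.0], index=["G1"])
        _, future = velocity.cell_velocity(counts, gamma, dt=0.0)
        pd.testing.assert_frame_equal(future, s)

    def test_future_state_floored_at_zero(self):
        s = pd.DataFrame({"G1": [1.0]})
        u = pd.DataFrame({"G1": [0.0]})
        counts = CompartmentCounts(u=u, s=s, meta=pd.DataFrame(index=s.index))
        gamma = pd.Series([5.0], index=["G1"])
        _, future = velocity.cell_velocity(counts, gamma, dt=1.0)
        assert (future.to_numpy() >= 0).all()


class TestPcaDisplacement:
    def test_basis_invariant_to_condition_permutation(self):
        rng = np.random.default_rng(2)
        s = pd.DataFrame(rng.poisson(20, size=(60, 4)).astype(float))
        fut = s + rng.normal(0, 1, s.shape)
        meta = pd.DataFrame({
            "cell_type": "t", "region": "CA1", "sample_id": "a",
            "condition": rng.choice(["WT", "5xFAD"], 60),
        }, index=s.index)
        d1 = velocity.pca_displacement(s, fut, meta)
        meta2 = meta.assign(condition=rng.permutation(meta["condition"].to_numpy()))
        d2 = velocity.pca_displacement(s, fut, meta2)
        np.testing.assert_allclose(d1[["d1", "d2"]], d2[["d1", "d2"]])

    def test_single_cell_rejected(self):
        s = pd.DataFrame({"G1": [1.0], "G2": [2.0]})
        with pytest.raises(ValueError):
            velocity.pca_displacement(s, s)


class TestCompareMagnitudes:
    def test_identical_groups_near_one(self):
        vals = np.arange(20.0)
        _, p = velocity.compare_magnitudes(vals, vals.copy())
        assert p > 0.9

    def test_exact_small_sample_value(self):
        u, p = velocity.compare_magnitudes(
            [10.0, 11.0, 12.0], [0.0, 1.0, 2.0], min_n=3)
        assert u == 9.0
        assert p == pytest.approx(0.1)

    def test_undersized_groups_skip(self):
        u, p = velocity.compare_magnitudes([1.0] * 5, [2.0] * 20)
        assert np.isnan(u) and np.isnan(p)


class TestComparePhases:
    def test_identical_multisets_give_p_one(self):
        ph = np.linspace(-1, 1, 30)
        _, p = velocity.compare_phases(ph, ph.copy(), n_perm=199, rng=0)
        assert p == 1.0

    def test_opposite_concentrations_hit_floor(self):
        rng = np.random.default_rng(3)
        a = rng.vonmises(0.0, 10.0, 100)
        b = rng.vonmises(np.pi, 10.0, 100)
        delta, p = velocity.compare_phases(a, b, n_perm=999, rng=1)
        assert delta == pytest.approx(np.pi, abs=0.2)
        # near the permutation floor: balanced relabelings have near-zero
        # resultants whose angles occasionally land ~pi apart by chance
        assert p <= 0.01

    def test_statistic_in_zero_pi(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(-np.pi, np.pi, 40)
        b = rng.uniform(-np.pi, np.pi, 40)
        delta, _ = velocity.compare_phases(a, b, n_perm=199, rng=2)
        assert 0 <= delta <= np.pi

    def test_zero_resultant_skips(self):
        # four perfectly opposed phases: resultant length 0
        a = np.array([0.0, np.pi, np.pi / 2, -np.pi / 2] * 5)
        b = np.linspace(0, 1, 20)
        delta, p = velocity.compare_phases(a, b, n_perm=199, rng=0)
        assert np.isnan(delta) and np.isnan(p)


class TestGeneVelocityDifftest:
    def test_single_gene_q_equals_p(self):
        rng = np.random.default_rng(5)
        va = pd.DataFrame({"G1": rng.normal(0, 1, 30)})
        vb = pd.DataFrame({"G1": rng.normal(1, 1, 30)})
        res = velocity.gene_velocity_difftest(va, vb)
        assert res["q"].iloc[0] == pytest.approx(res["p"].iloc[0])

    def test_identical_conditions_stay_null(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(10):
            v = rng.normal(size=(40, 20))
            res = velocity.gene_velocity_difftest(
                pd.DataFrame(v[:20]), pd.DataFrame(v[20:]))
            hits += (res["q"] < 0.05).any()
        assert hits <= 1

    def test_undersized_gene_skipped(self):
        va = pd.DataFrame({"G1": [1.0, 2.0]})
        vb = pd.DataFrame({"G1": [1.0, 2.0]})
        res = velocity.gene_velocity_difftest(va, vb)
        assert bool(res["skipped"].iloc[0])


class TestStratify:
    def test_empty_stratum_yields_skip_record(self, small_dataset):
        counts, gamma, v, future = velocity.velocity_analysis(
            small_dataset.spots, small_dataset.cells, small_dataset.panel,
            min_cells_gamma=5)
        strata, _, _ = velocity.stratify(
            counts, gamma, v, future, by_region=False,
            cell_types=["excitatory", "not_a_type"], n_perm=199, seed=0)
        rec = strata.set_index("cell_type").loc["not_a_type"]
        assert bool(rec["skipped"])

    def test_region_effect_detected_in_stratum_not_elsewhere(self):
        from exspat import synthetic
        from exspat.synthetic import CellTypeSpec, PlantedEffect, SimulationConfig

        cfg = SimulationConfig(
            seed=41, n_genes=5, n_samples_per_condition=2,
            fovs_per_region_per_sample=5, mean_molecules_per_fov=8000.0,
            cells_per_fov=40.0, regions=("DG-CA1", "CA3"), gene_abundance_sd=0.2,
            cell_types=(
                CellTypeSpec("inhibitory", 0.5, 5.0),
                CellTypeSpec("excitatory", 0.5, 6.0),
            ),
            planted_effects=(
                PlantedEffect(kind="velocity_shift", gene="G002", condition="5xFAD",
                              magnitude=3.0, cell_type="inhibitory",
                              regions=("DG-CA1",)),
            ),
        )
        ds = synthetic.generate_dataset(cfg)
        counts, gamma, v, future = velocity.velocity_analysis(ds.spots, ds.cells, ds.panel)
        strata, _, _ = velocity.stratify(
            counts, gamma, v, future, cell_types=["inhibitory"], n_perm=199, seed=0)
        strata = strata.set_index("region")
        # the affected stratum is overwhelmingly significant; the unaffected
        # region only shows the mild FOV-clustering noise of a cell-level MWU
        assert strata.loc["DG-CA1", "magnitude_p"] < 1e-6
        assert strata.loc["CA3", "magnitude_p"] > 1e-3
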