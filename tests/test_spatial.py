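import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exspat import spatial
from exspat.evaluation import morans_i_reference
from exspat.spatial import OutOfBoundsError, VoxelGrid


class TestVoxelize:
    def test_single_spot_lands_in_origin_voxel(self):
        grid = spatial.voxelize(
            np.array([5.0]), np.array([5.0]), np.array([5.0]),
            voxel_size=10.0, bounds=(100.0, 100.0, 30.0))
        assert grid.dims == (10, 10, 3)
        assert grid.counts.sum() == 1
        assert grid.counts[0, 0, 0] == 1

    def test_boundary_value_falls_in_next_voxel(self):
        # half-open convention: x = 10.0 belongs to voxel index 1
        grid = spatial.voxelize(
            np.array([10.0]), np.array([0.0]), np.array([0.0]),
            voxel_size=10.0, bounds=(100.0, 100.0, 30.0))
        assert grid.counts[1, 0, 0] == 1

    def test_out_of_bounds_names_spot(self):
        with pytest.raises(OutOfBoundsError, match="s7"):
            spatial.voxelize(
                np.array([150.0]), np.array([0.0]), np.array([0.0]),
                spot_ids=np.array(["s7"]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(1, 500), st.integers(0, 2**31 - 1))
    def test_counts_conserved_for_random_spot_sets(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 100, n)
        y = rng.uniform(0, 100, n)
        z = rng.uniform(0, 30, n)
        grid = spatial.voxelize(x, y, z)
        assert grid.counts.sum() == n
        assert (grid.counts >= 0).all()


class TestMoransI:
    def test_constant_grid_is_invalid(self):
        grid = VoxelGrid(np.full((3, 3, 2), 5), (0, 0, 0), 10.0)
        stat = spatial.morans_i(grid, min_spots=0)
        assert not stat.valid
        assert np.isnan(stat.I)

    def test_line_half_and_half(self):
        # [1,1,0,0] on a 1x4 lattice: N=4, W=6, I = 1/3 by direct double loop
        grid = VoxelGrid(np.array([1, 1, 0, 0]).reshape(1, 4, 1), (0, 0, 0), 10.0)
        assert spatial.morans_i(grid, min_spots=0).I == pytest.approx(1 / 3)

    def test_checkerboard_is_minus_one(self):
        grid = VoxelGrid(np.array([[1, 0], [0, 1]]).reshape(2, 2, 1), (0, 0, 0), 10.0)
        assert spatial.morans_i(grid, min_spots=0).I == pytest.approx(-1.0)

    def test_min_spots_gate(self):
        counts = np.zeros((2, 2, 1), dtype=int)
        counts[0, 0, 0] = 3
        grid = VoxelGrid(counts, (0, 0, 0), 10.0)
        assert not spatial.morans_i(grid, min_spots=10).valid
        assert spatial.morans_i(grid, min_spots=1).valid

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_reference_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        dims = (int(rng.integers(1, 7)), int(rng.integers(1, 7)), int(rng.integers(1, 4)))
        counts = rng.poisson(1.5, size=dims)
        if counts.max() == counts.min():
            counts.flat[0] += 1
        if np.prod(dims) == 1:
            counts = np.array([1, 0]).reshape(2, 1, 1)
        grid = VoxelGrid(counts, (0, 0, 0), 10.0)
        assert spatial.morans_i(grid, min_spots=0).I == pytest.approx(
            morans_i_reference(counts), abs=1e-12)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert spatial.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        # m=4: q_i = min over j>=i of p_(j)*m/j, all equal to 0.04 here
        np.testing.assert_allclose(
            spatial.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(spatial.bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            spatial.bh_adjust([0.5, 1.5])

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = spatial.bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestPermutationDiffTest:
    def test_identical_groups_give_p_one(self):
        vals = np.array([1.0, 2.0, 3.0])
        _, p = spatial.permutation_diff_test(vals, vals.copy(), 199, 0)
        assert p == 1.0

    def test_matches_exhaustive_enumeration(self):
        a = np.array([10.0, 11.0, 12.0])
        b = np.array([0.0, 1.0, 2.0])
        pooled = np.concatenate([a, b])
        t_obs = a.mean() - b.mean()
        count = total = 0
        for combo in itertools.combinations(range(6), 3):
            rest = [i for i in range(6) if i not in combo]
            t = pooled[list(combo)].mean() - pooled[rest].mean()
            count += abs(t) >= abs(t_obs) - 1e-12
            total += 1
        exact = count / total  # 2/20
        assert exact == pytest.approx(0.1)
        _, p = spatial.permutation_diff_test(a, b, 4999, 1)
        assert p == pytest.approx(exact, abs=0.02)

    def test_requires_enough_permutations_and_values(self):
        with pytest.raises(ValueError):
            spatial.permutation_diff_test([1, 2], [3, 4], 10, 0)
        with pytest.raises(ValueError):
            spatial.permutation_diff_test([1.0], [2.0, 3.0], 199, 0)

    def test_deterministic_given_seed(self):
        a, b = np.arange(5.0), np.arange(5.0) + 0.5
        assert spatial.permutation_diff_test(a, b, 199, 42) == \
            spatial.permutation_diff_test(a, b, 199, 42)


class TestRegionScreen:
    def test_planted_expression_and_spatial_effects_categorized(self):
        from exspat import synthetic
        from exspat.synthetic import PlantedEffect, SimulationConfig

        cfg = SimulationConfig(
            seed=21, n_genes=12, n_samples_per_condition=2,
            fovs_per_region_per_sample=10, mean_molecules_per_fov=1500.0,
            regions=("DG-CA1",),
            planted_effects=(
                PlantedEffect(kind="expression_shift", gene="G001",
                              condition="5xFAD", magnitude=2.0),
                PlantedEffect(kind="spatial_shift", gene="G002",
                              condition="5xFAD", magnitude=20.0),
            ),
        )
        ds = synthetic.generate_dataset(cfg)
        res = spatial.region_screen(
            ds.spots, ds.cells, "DG-CA1", panel=ds.panel, n_perm=999, seed=7,
        ).set_index("gene")
        assert res.loc["G001", "category"] == "expression_only"
        assert res.loc["G002", "category"] == "spatial_only"

    def test_same_seed_reproduces_table(self, small_dataset):
        kw = dict(panel=small_dataset.panel, n_perm=199, seed=5)
        a = spatial.region_screen(small_dataset.spots, small_dataset.cells, "CA1", **kw)
        b = spatial.region_screen(small_dataset.spots, small_dataset.cells, "CA1", **kw)
        assert a.equals(b)

    def test_absent_region_raises(self, small_dataset):
        with pytest.raises(KeyError):
            spatial.region_screen(small_dataset.spots, small_dataset.cells, "SLM")


class TestAxisDensity:
    def test_identical_samples_have_zero_distance(self, small_dataset):
        gene = small_dataset.panel[0]
        res = spatial.axis_density_compare(
            small_dataset.spots, small_dataset.spots, gene, min_spots=5)
        assert res.ks_statistic == 0.0
        assert res.ks_p == pytest.approx(1.0)

    def test_disjoint_projections_have_d_one(self):
        import pandas as pd

        def frame(xs):
            return pd.DataFrame({
                "gene": "G1", "x": xs, "y": 0.0, "z": 0.0,
            })

        res = spatial.axis_density_compare(
            frame([1.0, 2.0, 3.0]), frame([4.0, 5.0, 6.0]), "G1",
            axis=(np.zeros(3), np.array([1.0, 0, 0])), min_spots=3)
        assert res.ks_statistic == 1.0

    def test_kde_integrates_to_one(self, small_dataset):
        gene = small_dataset.panel[0]
        half = small_dataset.spots.iloc[::2]
        other = small_dataset.spots.iloc[1::2]
        res = spatial.axis_density_compare(half, other, gene, min_spots=5)
        area = np.trapezoid(res.density_a, res.grid)
        assert area == pytest.approx(1.0, abs=0.05)

    def test_too_few_spots_yields_skip_record(self, small_dataset):
        res = spatial.axis_density_compare(
            small_dataset.spots.iloc[:2], small_dataset.spots, small_dataset.panel[0],
            min_spots=50)
        assert res.skipped
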