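import dataclasses

import numpy as np
import pandas as pd
import pytest

from exspat import spatial, synthetic
from exspat._utils import file_sha256
from exspat.synthetic import (
    CellTypeSpec,
    ConfigError,
    PlantedEffect,
    SimulationConfig,
)


def _hash_dir(d):
    return {p.name: file_sha256(p) for p in sorted(d.iterdir())}


def test_identical_config_and_seed_give_byte_identical_outputs(small_config, tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    synthetic.write_dataset(synthetic.generate_dataset(small_config), a)
    synthetic.write_dataset(synthetic.generate_dataset(small_config), b)
    assert _hash_dir(a) == _hash_dir(b)


def test_different_seeds_differ(small_config):
    other = dataclasses.replace(small_config, seed=12)
    a = synthetic.generate_dataset(small_config)
    b = synthetic.generate_dataset(other)
    assert not a.spots["x"].equals(b.spots["x"])


@pytest.mark.parametrize(
    "field,value,message",
    [
        ("n_genes", 0, "n_genes"),
        ("fov_size", (0.0, 100.0, 30.0), "fov_size"),
        ("unassigned_fraction", 1.2, "unassigned_fraction"),
        ("regions", ("Mars",), "regions"),
    ],
)
def test_invalid_config_names_offending_field(small_config, field, value, message):
    cfg = dataclasses.replace(small_config, **{field: value})
    with pytest.raises(ConfigError, match=message):
        cfg.validate()


def test_cell_type_frequencies_must_sum_to_one(small_config):
    cfg = dataclasses.replace(
        small_config,
        cell_types=(CellTypeSpec("a", 0.5, 5.0), CellTypeSpec("b", 0.4, 5.0)),
    )
    with pytest.raises(ConfigError, match="cell_types"):
        cfg.validate()


def test_expression_shift_doubles_mean_count_in_affected_condition():
    cfg = SimulationConfig(
        seed=3,
        n_genes=10,
        n_samples_per_condition=2,
        fovs_per_region_per_sample=10,  # 20 FOVs per condition
        mean_molecules_per_fov=2000.0,
        regions=("CA1",),
        planted_effects=(
            PlantedEffect(kind="expression_shift", gene="G001", condition="5xFAD",
                          magnitude=2.0),
        ),
    )
    ds = synthetic.generate_dataset(cfg)
    counts = ds.spots[ds.spots["gene"] == "G001"].groupby("fov_id").size()
    cond = ds.cells[["fov_id", "condition"]].drop_duplicates().set_index("fov_id")["condition"]
    means = counts.groupby(cond).mean()
    ratio = means["5xFAD"] / means["WT"]
    # Poisson error plus per-FOV cell-density variation at 20 FOVs per side
    assert 1.5 < ratio < 2.5


@pytest.fixture(scope="module")
def shift_baseline():
    cfg = SimulationConfig(
        seed=5, n_genes=4, n_samples_per_condition=1,
        fovs_per_region_per_sample=4, mean_molecules_per_fov=2000.0,
        regions=("CA1",),
    )
    return synthetic.generate_dataset(cfg)


@pytest.fixture(scope="module")
def velocity_baseline():
    cfg = SimulationConfig(
        seed=6, n_genes=4, n_samples_per_condition=1,
        fovs_per_region_per_sample=4, mean_molecules_per_fov=3000.0,
        cells_per_fov=25.0, regions=("CA1",),
    )
    return synthetic.generate_dataset(cfg)


class TestSpatialShift:
    def test_spot_counts_per_fov_conserved(self, shift_baseline):
        rng = np.random.default_rng(0)
        shifted = synthetic.plant_spatial_shift(
            shift_baseline.spots, "G001", 20.0, rng, fov_size=(100.0, 100.0, 30.0))
        before = shift_baseline.spots.groupby(["fov_id", "gene"]).size()
        after = shifted.groupby(["fov_id", "gene"]).size()
        pd.testing.assert_series_equal(before, after)

    def test_non_coordinate_columns_untouched(self, shift_baseline):
        rng = np.random.default_rng(0)
        shifted = synthetic.plant_spatial_shift(
            shift_baseline.spots, "G001", 20.0, rng, fov_size=(100.0, 100.0, 30.0))
        for col in ("spot_id", "gene", "fov_id", "cell_id", "compartment"):
            assert shifted[col].equals(shift_baseline.spots[col])

    def test_zero_concentration_is_identity_in_distribution(self, shift_baseline):
        # c = 0 keeps every spot on the uniform branch of the mixture
        rng = np.random.default_rng(0)
        shifted = synthetic.plant_spatial_shift(
            shift_baseline.spots, "G001", 0.0, rng, fov_size=(100.0, 100.0, 30.0))
        sel = shifted["gene"] == "G001"
        from scipy.stats import kstest
        # uniform marginal on x over [0, 100)
        p = kstest(shifted.loc[sel, "x"] / 100.0, "uniform").pvalue
        assert p > 0.01

    def test_large_concentration_raises_morans_i(self, shift_baseline):
        rng = np.random.default_rng(1)
        shifted = synthetic.plant_spatial_shift(
            shift_baseline.spots, "G002", 50.0, rng, fov_size=(100.0, 100.0, 30.0))
        higher = 0
        fovs = shift_baseline.spots["fov_id"].unique()
        for fov in fovs:
            def morans(df):
                sub = df[(df["fov_id"] == fov) & (df["gene"] == "G002")]
                grid = spatial.voxelize(
                    sub["x"].to_numpy(), sub["y"].to_numpy(), sub["z"].to_numpy())
                return spatial.morans_i(grid).I
            higher += morans(shifted) > morans(shift_baseline.spots)
        assert higher == len(fovs)

    def test_unknown_gene_raises(self, shift_baseline):
        with pytest.raises(KeyError):
            synthetic.plant_spatial_shift(
                shift_baseline.spots, "NOPE", 1.0, np.random.default_rng(0),
                fov_size=(100.0, 100.0, 30.0))


class TestVelocityShift:
    def test_per_cell_totals_conserved(self, velocity_baseline):
        shifted = synthetic.plant_velocity_shift(
            velocity_baseline.spots, velocity_baseline.cells, "G001", "excitatory", 3.0,
            np.random.default_rng(0))
        before = velocity_baseline.spots.groupby(["cell_id", "gene"]).size()
        after = shifted.groupby(["cell_id", "gene"]).size()
        pd.testing.assert_series_equal(before, after)

    def test_multiplier_raises_nuclear_fraction(self, velocity_baseline):
        shifted = synthetic.plant_velocity_shift(
            velocity_baseline.spots, velocity_baseline.cells, "G001", "excitatory", 3.0,
            np.random.default_rng(0))
        exc = set(velocity_baseline.cells.loc[velocity_baseline.cells["cell_type"] == "excitatory", "cell_id"])

        def nuc_frac(df):
            sel = df[(df["gene"] == "G001") & df["cell_id"].isin(exc)]
            return (sel["compartment"] == "nuclear").mean()

        assert nuc_frac(shifted) > nuc_frac(velocity_baseline.spots) + 0.1

    def test_multiplier_one_keeps_fraction(self, velocity_baseline):
        shifted = synthetic.plant_velocity_shift(
            velocity_baseline.spots, velocity_baseline.cells, "G001", "excitatory", 1.0,
            np.random.default_rng(0))
        f0 = (velocity_baseline.spots["compartment"] == "nuclear").mean()
        f1 = (shifted["compartment"] == "nuclear").mean()
        assert abs(f0 - f1) < 0.05

    def test_unknown_cell_type_raises(self, velocity_baseline):
        with pytest.raises(KeyError):
            synthetic.plant_velocity_shift(
                velocity_baseline.spots, velocity_baseline.cells, "G001", "purkinje", 2.0,
                np.random.default_rng(0))


def test_ground_truth_records_all_effects_and_roundtrips(tmp_path):
    effects = (
        PlantedEffect(kind="expression_shift", gene="G001", condition="WT", magnitude=1.5),
        PlantedEffect(kind="module_shift", gene=("G002", "G003"), condition="5xFAD",
                      magnitude=2.0, cell_type="excitatory"),
    )
    cfg = SimulationConfig(
        seed=8, n_genes=4, n_samples_per_condition=1, fovs_per_region_per_sample=1,
        mean_molecules_per_fov=300.0, regions=("CA1",), planted_effects=effects,
    )
    ds = synthetic.generate_dataset(cfg)
    assert len(ds.truth.effects) == 2
    synthetic.write_dataset(ds, tmp_path)
    back = synthetic.read_dataset(tmp_path)
    assert back.truth.effects == ds.truth.effects


def test_geometric_compartments_respect_cell_radius(small_dataset):
    spots = small_dataset.spots
    cells = small_dataset.cells.set_index("cell_id")
    assigned = spots[spots["cell_id"] != "NA"].sample(500, random_state=0)
    geo = cells.loc[assigned["cell_id"]]
    d = np.sqrt(
        (assigned["x"].to_numpy() - geo["cx"].to_numpy()) ** 2
        + (assigned["y"].to_numpy() - geo["cy"].to_numpy()) ** 2
        + (assigned["z"].to_numpy() - geo["cz"].to_numpy()) ** 2
    )
    r = geo["radius"].to_numpy()
    nuclear = assigned["compartment"].to_numpy() == "nuclear"
    assert (d <= r + 1e-9).all()
    assert (d[nuclear] <= synthetic.NUCLEAR_INNER_FRACTION * r[nuclear] + 1e-9).all()
    assert (d[~nuclear] >= synthetic.NUCLEAR_INNER_FRACTION * r[~nuclear] - 1e-9).all()
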