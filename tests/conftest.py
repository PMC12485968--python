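import pytest

from exspat import synthetic
from exspat.synthetic import SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        n_genes=8,
        n_samples_per_condition=2,
        fovs_per_region_per_sample=2,
        mean_molecules_per_fov=800.0,
        cells_per_fov=15.0,
        regions=("CA1", "DG"),
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """A small effect-free dataset shared by read-only tests."""
    return synthetic.generate_dataset(small_config)
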