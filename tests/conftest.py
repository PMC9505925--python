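import pytest
from hypothesis import HealthCheck, settings

from tinyintron.synthetic_data import SimulationConfig, generate_genome

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_sim():
    """One full-size simulation under the default study conditions."""
    return generate_genome(SimulationConfig(n_genes=2000, seed=42))


@pytest.fixture(scope="session")
def small_sim():
    """A smaller simulation for cheap structural round-trip checks."""
    return generate_genome(SimulationConfig(n_genes=300, seed=42))


@pytest.fixture(scope="session")
def small_sim_paths(small_sim, tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    return small_sim.write(out)
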