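import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")

from epireprog import SimulationConfig, simulate_experiment  # noqa: E402


@pytest.fixture(scope="session")
def small_cfg():
    """Scaled-down study: 200 genes, otherwise the default design."""
    return SimulationConfig(
        n_genes=200,
        n_peaks_per_mark=300,
        n_probes=1200,
        genome_length=4_000_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment(small_cfg):
    return simulate_experiment(small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
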