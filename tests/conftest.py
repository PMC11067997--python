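import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from zsd import SimConfig, generate_founder_alleles, simulate_population

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240503)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_females=150, n_males=150, k=10, generations=25, seed=11)


@pytest.fixture(scope="session")
def small_state(small_config):
    return simulate_population(small_config)


@pytest.fixture(scope="session")
def founder_haplotypes():
    cfg = SimConfig(k=11, seed=5)
    return generate_founder_alleles(11, cfg, np.random.default_rng(5))
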