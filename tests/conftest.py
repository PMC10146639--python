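import numpy as np
import pytest

from breathprint import SimulationConfig, simulate_breathprints


@pytest.fixture(scope="session")
def small_cohort():
    """A well-separated 6+5 cohort, the size of a small training model."""
    cfg = SimulationConfig(n_asthma=6, n_control=5, delta=6.0, seed=11)
    prints, gt = simulate_breathprints(cfg)
    return prints, gt


@pytest.fixture(scope="session")
def medium_cohort():
    """100 + 100 samples at delta = 2 for distributional checks."""
    cfg = SimulationConfig(n_asthma=100, n_control=100, delta=2.0, seed=29)
    prints, gt = simulate_breathprints(cfg)
    return prints, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
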