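import numpy as np
import pytest
from hypothesis import settings

from bisque.simulate import SimulationConfig, simulate_run

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_sim():
    """One stochastic simulated plate shared by read-only tests."""
    cfg = SimulationConfig(seed=7)
    run, truth = simulate_run(cfg)
    return cfg, run, truth


@pytest.fixture(scope="session")
def noiseless_sim():
    """Exact zero-noise plate: estimates must equal the closed forms."""
    cfg = SimulationConfig(seed=7, ct_noise_sd=0.0, stochastic_copies=False)
    run, truth = simulate_run(cfg)
    return cfg, run, truth
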