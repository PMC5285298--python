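import numpy as np
import pytest

from gpmobility.synthetic_panel import DGPConfig, generate_population, simulate_panel


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """A fast, small census configuration used across tests."""
    return DGPConfig(n_practices=120, doctors_per_practice=4.0, seed=777)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_panel(small_config, generate_population(small_config))
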