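import numpy as np
import pytest

from cernax.synthetic_data import SimulationParams, simulate


@pytest.fixture(scope="session")
def sim_data():
    """One default-condition synthetic dataset shared across tests."""
    return simulate(SimulationParams(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
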