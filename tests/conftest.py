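import numpy as np
import pytest

from branchnet.core import SimParams
from branchnet.simulate import simulate_sequential, simulate_single_step


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def published_params():
    """Kinetic parameters at the published values."""
    return SimParams(seed=0)


@pytest.fixture(scope="session")
def small_sequential_network():
    """One sequential-model network, capped at 15 MTs."""
    return simulate_sequential(SimParams(seed=7, t_max=2400, max_mts=15))


@pytest.fixture(scope="session")
def small_single_step_network():
    return simulate_single_step(SimParams(seed=7, t_max=2400, max_mts=15))
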