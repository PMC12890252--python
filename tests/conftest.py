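import numpy as np
import pytest

from stpkit.pool import PoolParams, StimTrain


@pytest.fixture
def baseline_pool() -> PoolParams:
    """Resting-state pool of the reference synapse: six sites, docking
    6.9/s, undocking 16.1/s (occupancy 0.3), fusion probability 1."""
    return PoolParams(n_sites=6, k1_base=6.9, b1=16.1, p_v=1.0)


@pytest.fixture
def paired_stim() -> StimTrain:
    """Two APs separated by 20 ms."""
    return StimTrain((0.0, 0.02))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
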