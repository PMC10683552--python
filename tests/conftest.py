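import numpy as np
import pytest

from mcellnet.params import NetworkConfig, dominant_preset, subordinate_preset


@pytest.fixture(scope="session")
def dom_cfg() -> NetworkConfig:
    return dominant_preset()

@pytest.fixture(scope="session")
def sub_cfg() -> NetworkConfig:
    return subordinate_preset()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20231127)


def random_state_vector(rng: np.random.Generator) -> np.ndarray:
    """A random valid state: v in [-90, 40] mV, gates in [0,1], Ca in [0,10],
    gI in [0, 2]."""
    y = np.empty(16)
    y[0:4] = rng.uniform(-90.0, 40.0, 4)
    y[4:8] = rng.uniform(0.0, 1.0, 4)
    y[8:12] = rng.uniform(0.0, 10.0, 4)
    y[12:15] = rng.uniform(0.0, 1.0, 3)
    y[15] = rng.uniform(0.0, 2.0)
    return y
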