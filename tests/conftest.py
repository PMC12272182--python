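import numpy as np
import pytest

from riftkit.dipole import HeadModel
from riftkit.synthmeg import make_sensor_array


@pytest.fixture(scope="session")
def array64():
    return make_sensor_array(64, seed=0)


@pytest.fixture(scope="session")
def array32():
    return make_sensor_array(32, seed=0)


@pytest.fixture(scope="session")
def head64(array64):
    return HeadModel(array=array64)


def circdist_mod_pi(a: float, b: float) -> float:
    """Circular distance between two angles identified modulo pi."""
    d = (a - b) % np.pi
    return float(min(d, np.pi - d))
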