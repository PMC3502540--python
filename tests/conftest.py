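import numpy as np
import pytest

from fcshpa.fcs_core import ConfocalVolume
from fcshpa.fcs_synth import AssayProtocol, make_lag_grid


@pytest.fixture(scope="session")
def volume():
    return ConfocalVolume()


@pytest.fixture(scope="session")
def protocol():
    return AssayProtocol()


@pytest.fixture(scope="session")
def lag_grid():
    return make_lag_grid()


@pytest.fixture(scope="session")
def t_obs_table2():
    """Observation grid of the time-course arms (minutes)."""
    return np.array([0.0, 1.0, 5.0, 15.0, 30.0, 60.0, 120.0, 1320.0])
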