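import numpy as np
import pytest

from icbkit.arenas import checking_platform, open_field
from icbkit.checking import build_zone_grid
from icbkit.trajectory import Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid():
    return build_zone_grid()


def make_traj(x, y, dt=0.2, arena=None):
    x = np.asarray(x, float)
    t = dt * np.arange(x.size)
    return Trajectory(t, x, np.asarray(y, float), arena or open_field())


@pytest.fixture
def make_trajectory():
    return make_traj


@pytest.fixture
def platform_traj_factory():
    def _make(x, y, dt=0.2):
        return make_traj(x, y, dt=dt, arena=checking_platform())

    return _make
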