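import numpy as np
import pandas as pd
import pytest

from wintertrack import MovementModel, make_environment
from wintertrack.simulate import TrueTrack


@pytest.fixture(scope="session")
def habitat():
    """Coarse (1 degree) habitat stack shared across tests."""
    return make_environment(resolution=1.0, seed=11)


@pytest.fixture(scope="session")
def habitat_half():
    """Half-degree stack for tests needing finer masks."""
    return make_environment(resolution=0.5, seed=11)


@pytest.fixture
def movement():
    return MovementModel()


def make_stationary_track(lon, lat, start="2011-06-01", n_days=15,
                          bird_id="b0", colony="BRP"):
    times = pd.date_range(start, periods=2 * n_days, freq="12h")
    return TrueTrack(bird_id, colony, "M", times,
                     np.full(len(times), float(lon)),
                     np.full(len(times), float(lat)),
                     times[0], times[-1])


@pytest.fixture
def stationary_track():
    return make_stationary_track(-59.21, -54.0)
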