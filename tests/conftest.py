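import numpy as np
import pytest

import floralcam as fc
from floralcam.synthetic import UV_GRID


@pytest.fixture(scope="session")
def d65():
    return fc.cie_daylight_spd(6500.0)


@pytest.fixture(scope="session")
def d65_uv():
    return fc.cie_daylight_spd(6500.0, UV_GRID)


@pytest.fixture(scope="session")
def visible_profile():
    return fc.synthetic_visible_profile()


@pytest.fixture(scope="session")
def uv_profile():
    return fc.synthetic_uv_profile()


@pytest.fixture()
def rng():
    return np.random.default_rng(20140514)


def uniform_calibrated(value=0.4, shape=(64, 64), n_channels=1):
    """A constant linear image with clean flags, for sampling tests."""
    channels = np.full(shape + (n_channels,), value, dtype=float)
    false = np.zeros_like(channels, dtype=bool)
    return fc.CalibratedImage(channels, "linear", false.copy(), false.copy())
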