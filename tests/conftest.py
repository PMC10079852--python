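import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from resire.phantom import PhantomSpec, make_vesicle_phantom, simulate_tilt_series


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230406)


@pytest.fixture(scope="session")
def smooth_volume(rng):
    """Band-limited random 32^3 volume with interior support."""
    v = np.zeros((32, 32, 32))
    v[6:26, 6:26, 6:26] = rng.random((20, 20, 20))
    return gaussian_filter(v, 2.0)


@pytest.fixture(scope="session")
def small_phantom():
    """Vesicle phantom scaled to a 32^3 grid (fast unit tests)."""
    return make_vesicle_phantom(PhantomSpec().scaled(32))


@pytest.fixture(scope="session")
def small_stack(small_phantom):
    """Noiseless 21-projection single-axis series of the small phantom."""
    return simulate_tilt_series(small_phantom, (-70, 70), 7.0)


@pytest.fixture(scope="session")
def vesicle_phantom():
    """Full-size 64^3 vesicle phantom (shared by the slow tests)."""
    return make_vesicle_phantom()


@pytest.fixture(scope="session")
def vesicle_stack(vesicle_phantom):
    """The noiseless 41-projection +-70 deg / 3.5 deg series."""
    return simulate_tilt_series(vesicle_phantom)
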