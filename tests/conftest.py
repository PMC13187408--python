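import numpy as np
import pytest

from metascope.metaoptic import surrogate_library
from metascope.optics import make_pupil


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_grid():
    """64-px pupil grid with a 20-sample aperture radius."""
    return make_pupil(64, 1.0, 40.0)


@pytest.fixture(scope="session")
def toy_library():
    return surrogate_library(wavelengths_nm=(521.0, 681.0))


@pytest.fixture(scope="session")
def full_library():
    return surrogate_library()


def finite_difference_grad(f, x0, h=1e-6):
    """Central finite differences of a scalar function of an array."""
    x0 = np.asarray(x0, dtype=np.float64)
    g = np.zeros_like(x0)
    it = np.nditer(x0, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp, xm = x0.copy(), x0.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2 * h)
    return g
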