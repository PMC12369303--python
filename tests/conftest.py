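import numpy as np
import pytest
from scipy import ndimage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def textured_frame(rng):
    """Smooth random texture suitable for dense optical flow."""
    return ndimage.gaussian_filter(rng.random((120, 160)), 1.5)


def warp_frame(frame, dx, dy):
    """Translate a frame by (dx, dy) px with cubic interpolation."""
    yy, xx = np.mgrid[0 : frame.shape[0], 0 : frame.shape[1]].astype(float)
    return ndimage.map_coordinates(frame, [yy - dy, xx - dx], order=3, mode="reflect")
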