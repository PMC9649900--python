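import numpy as np
import pytest

from scintiseg.scan_io import CountMatrix, PolygonLabel, View


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_uint16(rng):
    def make(h=32, w=32, high=65535):
        return rng.integers(0, high + 1, size=(h, w), dtype=np.uint16)
    return make


@pytest.fixture
def square_polygon():
    """Axis-aligned square whose interior covers pixel centers (2..5, 2..5)."""
    return PolygonLabel(points=[[1.5, 1.5], [5.5, 1.5], [5.5, 5.5], [1.5, 5.5]],
                        lesion_id="sq")


@pytest.fixture
def torso_scan(rng):
    """A whole-body-like count matrix with a connected nonzero body region."""
    img = np.zeros((1024, 256), dtype=np.uint16)
    img[60:960, 40:216] = rng.integers(20, 200, size=(900, 176))
    return CountMatrix(img, view=View.ANTERIOR)
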