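import numpy as np
import pytest

from pallorscan.synth import SyntheticSpec, render_eye_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synth_spec():
    return SyntheticSpec()


@pytest.fixture(scope="session")
def eye_images(synth_spec):
    """One rendered (image, ground-truth mask) pair per class, fixed seeds."""
    return {
        cls: render_eye_image(cls, synth_spec, seed=97 + i)
        for i, cls in enumerate(("anemic", "moderate", "normal"))
    }


def make_red_rect_image(h=64, w=64, row0=10, row1=20, col0=30, col1=50):
    """Gray image with a saturated red rectangle covering rows [row0, row1]
    and cols [col0, col1] inclusive — the ROI-detector fixture."""
    img = np.full((h, w, 3), 128, dtype=np.uint8)
    img[row0 : row1 + 1, col0 : col1 + 1] = (200, 40, 40)
    return img
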