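import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from droughtfeat import SegmentationConfig
from droughtfeat.synthetic_plants import BLUE_BACKGROUND

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def cfg() -> SegmentationConfig:
    return SegmentationConfig()


@pytest.fixture
def green_square_image() -> np.ndarray:
    """A 10x10 pure-green square on a blue background, 30x30 canvas."""
    img = np.empty((30, 30, 3), dtype=np.uint8)
    img[:, :] = BLUE_BACKGROUND
    img[10:20, 10:20] = (0, 255, 0)
    return img


def solid_color_image(rgb, shape=(4, 4)) -> np.ndarray:
    img = np.empty((*shape, 3), dtype=np.uint8)
    img[:, :] = rgb
    return img
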