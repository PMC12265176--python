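import numpy as np
import pytest
from scipy import ndimage

S4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
S8 = np.ones((3, 3), dtype=int)


def flood_fill_components(mask: np.ndarray) -> int:
    """Independent oracle: 4-connected component count of a binary mask."""
    if not mask.any():
        return 0
    return ndimage.label(mask, structure=S4)[1]


def flood_fill_holes(mask: np.ndarray) -> int:
    """Independent oracle: bounded complementary regions of a binary mask,
    counted by 8-connected flood fill of the padded complement (the one
    component touching the padded border is the unbounded outside)."""
    comp = np.pad(~mask, 1, constant_values=True)
    return ndimage.label(comp, structure=S8)[1] - 1


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_record(rng):
    from aftgnet.io import ImageRecord

    return ImageRecord("rand", rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8).astype(np.uint8))
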