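import numpy as np
import pytest

from overlaptrack.mask_io import LabeledMask, MaskSequence


def mask_from(array, frame_index=1):
    """Build a LabeledMask from a nested-list literal."""
    return LabeledMask(
        pixels=np.asarray(array, dtype=np.int64), frame_index=frame_index
    )


def block_mask(shape, blocks, frame_index=1):
    """Mask with rectangular cells: blocks = [(label, r0, r1, c0, c1), ...]."""
    pixels = np.zeros(shape, dtype=np.int64)
    for label, r0, r1, c0, c1 in blocks:
        pixels[r0:r1, c0:c1] = label
    return LabeledMask(pixels=pixels, frame_index=frame_index)


@pytest.fixture
def two_distant_cells_sequence():
    """3 frames, two stationary 5x5 cells in opposite corners, labels
    swapped in frame 2 to tempt a cross-link."""
    shape = (200, 300)
    a = (2, 7, 2, 7)       # top-left cell geometry
    b = (190, 195, 290, 295)  # bottom-right cell geometry
    frames = [
        block_mask(shape, [(1, *a), (2, *b)], frame_index=1),
        block_mask(shape, [(2, *a), (1, *b)], frame_index=2),
        block_mask(shape, [(1, *a), (2, *b)], frame_index=3),
    ]
    return MaskSequence(frames=frames)
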