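"""Per-cell feature extraction and pixel-overlap counting.

A cell is exactly the set of equal-valued positive pixels in one frame's
label mask. Features are the pixel count (size), the centroid (unweighted
mean of member pixel coordinates), and the pixel set itself. Overlaps
between cells of two consecutive frames are counted at identical pixel
coordinates, with no registration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractViolationError
from .mask_io import LabeledMask


@dataclass(frozen=True)
class CellRegion:
    """Features of one segmented cell in one frame.

    Coordinates are 0-based ``(row, col)``; ``centroid_x`` / ``centroid_y``
    expose the conventional image axes (x = column, y = row).
    """

    label: int
    frame_index: int
    size: int
    centroid: tuple[float, float]  # (row, col)
    pixel_set: frozenset[tuple[int, int]] = field(repr=False)

    def __post_init__(self) -> None:
        if self.size < 1 or self.size != len(self.pixel_set):
            raise ContractViolationError(
                f"region size {self.size} inconsistent with "
                f"{len(self.pixel_set)} member pixels"
            )

    @property
    def centroid_x(self) -> float:
        return self.centroid[1]

    @property
    def centroid_y(self) -> float:
        return self.centroid[0]


@dataclass(frozen=True)
class OverlapTable:
    """Sparse map ``(source_label, target_label) -> shared pixel count``.

    Pairs with zero overlap are absent. Lookup through :meth:`get`
    returns 0 for absent pairs.
    """

    counts: dict[tuple[int, int], int]

    def get(self, source_label: int, target_label: int) -> int:
        return self.counts.get((source_label, target_label), 0)

    def __len__(self) -> int:
        return len(self.counts)


def extract_regions(mask: LabeledMask) -> list[CellRegion]:
    """Extract one :class:`CellRegion` per positive label, ordered by label.

    Sizes and centroids are exact; an all-background mask yields an
    empty list. Pixels of one label need not be connected — connectivity
    is the segmenter's concern, not the tracker's.
    """
    rows, cols = np.nonzero(mask.pixels)
    if rows.size == 0:
        return []
    labels = mask.pixels[rows, cols]
    order = np.argsort(labels, kind="stable")
    rows, cols, labels = rows[order], cols[order], labels[order]
    # boundaries of each label's run in the sorted pixel list
    unique_labels, starts = np.unique(labels, return_index=True)
    stops = np.append(starts[1:], labels.size)
    regions = []
    for label, lo, hi in zip(unique_labels, starts, stops):
        r, c = rows[lo:hi], cols[lo:hi]
        regions.append(
            CellRegion(
                label=int(label),
                frame_index=mask.frame_index,
                size=int(hi - lo),
                centroid=(float(r.mean()), float(c.mean())),
                pixel_set=frozenset(zip(r.tolist(), c.tolist())),
            )
        )
    return regions


def count_overlaps(source: LabeledMask, target: LabeledMask) -> OverlapTable:
    """Count shared pixels for every (source cell, target cell) pair.

    ``counts[(i, j)]`` is the number of pixel positions where the source
    mask holds label ``i`` and the target mask holds label ``j`` (both
    positive). Zero-count pairs are omitted.
    """
    if source.pixels.shape != target.pixels.shape:
        raise ContractViolationError(
            f"mask dimensions differ: {source.pixels.shape} vs {target.pixels.shape}"
        )
    both = (source.pixels > 0) & (target.pixels > 0)
    if not both.any():
        return OverlapTable(counts={})
    pairs = np.stack([source.pixels[both], target.pixels[both]], axis=1)
    unique_pairs, counts = np.unique(pairs, axis=0, return_counts=True)
    return OverlapTable(
        counts={
            (int(i), int(j)): int(n)
            for (i, j), n in zip(unique_pairs, counts)
        }
    )
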