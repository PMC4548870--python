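"""The mapping cost: three normalized metrics and their weighted sum.

The cost of mapping a source cell (frame k) onto a target cell
(frame k+1) is

    d = w_o * O + w_c * delta_c + w_s * delta_s

where each term lies in [0, 1]:

* ``O`` — overlap metric: 1 minus the shared pixel count averaged over
  the reciprocal sizes of the two cells; 0 when the cells coincide
  pixel-for-pixel, 1 when they share no pixels.
* ``delta_c`` — centroid offset: Euclidean centroid distance divided by
  the image diagonal.
* ``delta_s`` — size change: absolute size difference over the larger
  size.

A pair with no shared pixels whose raw centroid distance (in pixels)
exceeds a user threshold is pathological — cells do not jump across the
field of view between consecutive frames — and is assigned the sentinel
``MAX_COST``, which marks the mapping invalid.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ContractViolationError
from .regions import CellRegion, OverlapTable

#: Default metric weights: overlap dominates, centroid offset refines,
#: size change tie-breaks.
DEFAULT_WEIGHT_OVERLAP = 2.0
DEFAULT_WEIGHT_CENTROID = 1.0
DEFAULT_WEIGHT_SIZE = 0.5
DEFAULT_MAX_CENTROID_DISTANCE = 50.0
DEFAULT_MAX_COST = 1e9


@dataclass(frozen=True)
class TrackerConfig:
    """Weights and thresholds of the cost function.

    Parameters
    ----------
    weight_overlap, weight_centroid, weight_size
        Non-negative weights of the three metrics. Raise the overlap
        weight for high acquisition rates (large frame-to-frame
        overlap); raise the size weight for cells of stable area.
    max_centroid_distance
        Pixel threshold of the pathological filter: a zero-overlap pair
        whose centroids are farther apart than this is invalid.
    max_cost
        Sentinel cost of an invalid mapping; must exceed the largest
        attainable finite cost (the sum of the weights).
    """

    weight_overlap: float = DEFAULT_WEIGHT_OVERLAP
    weight_centroid: float = DEFAULT_WEIGHT_CENTROID
    weight_size: float = DEFAULT_WEIGHT_SIZE
    max_centroid_distance: float = DEFAULT_MAX_CENTROID_DISTANCE
    max_cost: float = DEFAULT_MAX_COST

    def __post_init__(self) -> None:
        for name in ("weight_overlap", "weight_centroid", "weight_size"):
            if getattr(self, name) < 0:
                raise ContractViolationError(f"{name} must be >= 0")
        if self.max_centroid_distance <= 0:
            raise ContractViolationError("max_centroid_distance must be > 0")
        if self.max_cost <= self.weight_sum:
            raise ContractViolationError(
                "max_cost must exceed the sum of the weights "
                f"({self.max_cost} <= {self.weight_sum})"
            )

    @property
    def weight_sum(self) -> float:
        """Upper bound of any finite (valid) cost."""
        return self.weight_overlap + self.weight_centroid + self.weight_size

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "TrackerConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ContractViolationError(
                f"unknown config key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**data)

    @classmethod
    def from_json(cls, path: str | Path) -> "TrackerConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class CostMatrix:
    """All pairwise mapping costs between two consecutive frames."""

    frame_pair: tuple[int, int]
    source_labels: tuple[int, ...]
    target_labels: tuple[int, ...]
    values: np.ndarray  # shape (len(source_labels), len(target_labels))

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.source_labels), len(self.target_labels)):
            raise ContractViolationError(
                f"cost matrix shape {values.shape} does not match "
                f"{len(self.source_labels)} sources x {len(self.target_labels)} targets"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "source_labels", tuple(self.source_labels))
        object.__setattr__(self, "target_labels", tuple(self.target_labels))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def overlap_metric(source_size: int, target_size: int, n_overlap: int) -> float:
    """Overlap metric ``1 - (n_o/2)(1/s_source + 1/s_target)``.

    0 only for a pixel-perfect match (overlap equals both sizes),
    1 when the cells share no pixels.
    """
    if source_size < 1 or target_size < 1:
        raise ContractViolationError("cell sizes must be >= 1 pixel")
    if not 0 <= n_overlap <= min(source_size, target_size):
        raise ContractViolationError(
            f"overlap {n_overlap} outside [0, min({source_size}, {target_size})]"
        )
    return 1.0 - (n_overlap / 2.0) * (1.0 / source_size + 1.0 / target_size)


def centroid_metric(
    source_centroid: tuple[float, float],
    target_centroid: tuple[float, float],
    height: int,
    width: int,
) -> float:
    """Euclidean centroid distance normalized by the image diagonal.

    Centroids are ``(row, col)`` pairs; the diagonal normalization makes
    the metric 1 exactly for a corner-to-corner displacement.
    """
    if height < 1 or width < 1:
        raise ContractViolationError("image dimensions must be >= 1")
    return centroid_distance(source_centroid, target_centroid) / math.hypot(
        height, width
    )


def centroid_distance(
    source_centroid: tuple[float, float], target_centroid: tuple[float, float]
) -> float:
    """Raw Euclidean distance between two centroids, in pixels."""
    return math.hypot(
        source_centroid[0] - target_centroid[0],
        source_centroid[1] - target_centroid[1],
    )


def size_metric(source_size: int, target_size: int) -> float:
    """Relative size change ``|s_source - s_target| / max(sizes)``.

    0 for equal sizes; always strictly below 1 since sizes are >= 1.
    """
    if source_size < 1 or target_size < 1:
        raise ContractViolationError("cell sizes must be >= 1 pixel")
    return abs(source_size - target_size) / max(source_size, target_size)


def pair_cost(
    source: CellRegion,
    target: CellRegion,
    n_overlap: int,
    config: TrackerConfig,
    height: int,
    width: int,
) -> float:
    """Weighted mapping cost of one source/target pair.

    Returns ``max_cost`` when the pathological filter fires (zero
    overlap and raw centroid distance above the threshold), otherwise
    the weighted sum of the three metrics.
    """
    if n_overlap == 0:
        if centroid_distance(source.centroid, target.centroid) > config.max_centroid_distance:
            return config.max_cost
    return (
        config.weight_overlap * overlap_metric(source.size, target.size, n_overlap)
        + config.weight_centroid
        * centroid_metric(source.centroid, target.centroid, height, width)
        + config.weight_size * size_metric(source.size, target.size)
    )


def build_cost_matrix(
    source_regions: list[CellRegion],
    target_regions: list[CellRegion],
    overlaps: OverlapTable,
    config: TrackerConfig,
    height: int,
    width: int,
    frame_pair: tuple[int, int] | None = None,
) -> CostMatrix:
    """Dense cost matrix over every source/target cell combination.

    Pairs absent from the overlap table use an overlap of 0. Frames with
    no cells produce a matrix with zero rows or columns.
    """
    if frame_pair is None:
        frame_pair = (
            source_regions[0].frame_index if source_regions else 0,
            target_regions[0].frame_index if target_regions else 0,
        )
    values = np.empty((len(source_regions), len(target_regions)), dtype=float)
    for i, src in enumerate(source_regions):
        for j, tgt in enumerate(target_regions):
            values[i, j] = pair_cost(
                src, tgt, overlaps.get(src.label, tgt.label), config, height, width
            )
    return CostMatrix(
        frame_pair=frame_pair,
        source_labels=tuple(r.label for r in source_regions),
        target_labels=tuple(r.label for r in target_regions),
        values=values,
    )


def write_cost_matrix_csv(matrix: CostMatrix, path: str | Path) -> None:
    """Dump one frame pair's cost matrix as CSV for auditing."""
    import pandas as pd

    frame = pd.DataFrame(
        matrix.values,
        index=list(matrix.source_labels),
        columns=list(matrix.target_labels),
    )
    frame.index.name = "source_label"
    frame.to_csv(path)
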