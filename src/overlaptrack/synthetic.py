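"""Synthetic label-mask sequences with known ground-truth identities.

The generator emulates what a segmenter would hand the tracker for a
sparse culture of motile cells imaged at a high acquisition rate:
non-touching elliptical blobs whose centers random-walk with a bounded
per-frame step (so consecutive instances of a cell share pixels), with
mild area fluctuation and optional appearance / disappearance events.
Per-frame labels are randomly permuted, mimicking the arbitrary
numbering independent segmentations produce, so nothing downstream can
lean on label continuity. Ground truth maps every per-frame label to a
persistent cell identity, enabling exact link-level scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from skimage.draw import ellipse as draw_ellipse

from .errors import ConsistencyError, ContractViolationError
from .mask_io import LabeledMask, MaskSequence
from .tracking import TrackTable


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic sequence generator.

    Defaults describe a sparse fibroblast-like culture in a
    520x696 px field imaged often enough that a cell moves well under
    its own radius per frame.
    """

    n_frames: int = 25
    height: int = 520
    width: int = 696
    n_cells: int = 10
    cell_radius_range: tuple[float, float] = (8.0, 14.0)
    max_step: float = 4.0
    size_jitter: float = 0.05
    appear_prob: float = 0.0
    disappear_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cell_radius_range
        if self.n_frames < 2:
            raise ContractViolationError("n_frames must be >= 2")
        if self.n_cells < 0:
            raise ContractViolationError("n_cells must be >= 0")
        if lo < 1 or hi < lo:
            raise ContractViolationError(
                f"invalid cell_radius_range {self.cell_radius_range}"
            )
        if self.max_step < 0:
            raise ContractViolationError("max_step must be >= 0")
        if not 0 <= self.size_jitter < 1:
            raise ContractViolationError("size_jitter must lie in [0, 1)")
        for name in ("appear_prob", "disappear_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ContractViolationError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Per frame, the map from mask label to persistent cell identity."""

    frames: tuple[dict[int, int], ...]

    def identity(self, frame_index: int, label: int) -> int:
        return self.frames[frame_index - 1][label]

    def __len__(self) -> int:
        return len(self.frames)


class PlacementError(ContractViolationError):
    """The requested cells could not be placed without touching."""


# aspect range of the elliptical blobs; kept mild so the smallest
# semi-axis stays above max_step * sqrt(2) under the default config
_ASPECT_RANGE = (0.85, 1.18)
_MAX_PLACEMENT_TRIES = 1000
_MAX_STEP_TRIES = 25


@dataclass
class _Cell:
    identity: int
    center: np.ndarray  # (row, col), float
    radius: float
    aspect: float
    rotation: float
    alive: bool = True

    def axes(self, area_scale: float) -> tuple[float, float]:
        s = float(np.sqrt(area_scale))
        return self.radius * self.aspect * s, self.radius / self.aspect * s


def _footprint(
    cell: _Cell, center: np.ndarray, area_scale: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    a, b = cell.axes(area_scale)
    return draw_ellipse(
        center[0], center[1], a, b, shape=shape, rotation=cell.rotation
    )


def _touches(occupied_dilated: np.ndarray, rr: np.ndarray, cc: np.ndarray) -> bool:
    return bool(occupied_dilated[rr, cc].any())


def _dilated_window(
    rr: np.ndarray, cc: np.ndarray, shape: tuple[int, int]
) -> tuple[int, int, np.ndarray]:
    """3x3-dilated footprint restricted to its bounding window."""
    r0 = max(int(rr.min()) - 2, 0)
    r1 = min(int(rr.max()) + 3, shape[0])
    c0 = max(int(cc.min()) - 2, 0)
    c1 = min(int(cc.max()) + 3, shape[1])
    window = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    window[rr - r0, cc - c0] = True
    return r0, c0, binary_dilation(window, structure=np.ones((3, 3), dtype=bool))


def _window_touches(
    win: tuple[int, int, np.ndarray], rr: np.ndarray, cc: np.ndarray
) -> bool:
    r0, c0, w = win
    sel = (rr >= r0) & (rr < r0 + w.shape[0]) & (cc >= c0) & (cc < c0 + w.shape[1])
    if not sel.any():
        return False
    return bool(w[rr[sel] - r0, cc[sel] - c0].any())


def simulate_sequence(config: SimulationConfig) -> tuple[MaskSequence, GroundTruth]:
    """Generate a mask sequence plus its ground-truth identity maps.

    Deterministic for a fixed config (including the seed). Cells never
    touch (at least a 1-pixel 8-connected gap); centers reflect at the
    image borders.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.height, config.width)
    lo, hi = config.cell_radius_range

    cells: list[_Cell] = []
    next_identity = 1

    def margin(cell: _Cell) -> float:
        return cell.radius * max(_ASPECT_RANGE[1], 1.0 / _ASPECT_RANGE[0]) + 1.0

    def new_cell() -> _Cell:
        nonlocal next_identity
        cell = _Cell(
            identity=next_identity,
            center=np.zeros(2),
            radius=float(rng.uniform(lo, hi)),
            aspect=float(rng.uniform(*_ASPECT_RANGE)),
            rotation=float(rng.uniform(0, np.pi)),
        )
        next_identity += 1
        return cell

    def reflect(value: float, low: float, high: float) -> float:
        # reflect into [low, high]; one bounce suffices for bounded steps
        if value < low:
            value = 2 * low - value
        if value > high:
            value = 2 * high - value
        return float(np.clip(value, low, high))

    def random_center(cell: _Cell) -> np.ndarray:
        m = margin(cell)
        if 2 * m >= min(config.height - 1, config.width - 1):
            raise PlacementError(
                f"frame {config.height}x{config.width} too small for a cell "
                f"of radius {cell.radius:.1f}"
            )
        return np.array(
            [
                rng.uniform(m, config.height - 1 - m),
                rng.uniform(m, config.width - 1 - m),
            ]
        )

    frames: list[LabeledMask] = []
    truth_frames: list[dict[int, int]] = []
    # previous-frame footprint and dilated window of each placed cell
    prev_footprint: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    prev_window: dict[int, tuple[int, int, np.ndarray]] = {}

    for frame_pos in range(config.n_frames):
        k = frame_pos + 1
        if frame_pos == 0:
            for _ in range(config.n_cells):
                cells.append(new_cell())
        else:
            for cell in cells:
                if cell.alive and rng.random() < config.disappear_prob:
                    cell.alive = False
            if rng.random() < config.appear_prob:
                cells.append(new_cell())

        dilated = np.zeros(shape, dtype=bool)
        rendered: list[tuple[_Cell, np.ndarray, np.ndarray]] = []
        alive_cells = [c for c in cells if c.alive]
        # identities still waiting to be rendered this frame; a move may
        # not touch their previous footprints, which guarantees every
        # cell can always fall back to staying put
        pending = {c.identity for c in alive_cells if c.identity in prev_window}

        def blocked(cell: _Cell, rr: np.ndarray, cc: np.ndarray) -> bool:
            if _touches(dilated, rr, cc):
                return True
            return any(
                _window_touches(prev_window[i], rr, cc)
                for i in pending
                if i != cell.identity
            )

        for cell in alive_cells:
            scale = 1.0 + float(
                rng.uniform(-config.size_jitter, config.size_jitter)
            )
            if cell.identity not in prev_window:  # fresh cell, never placed
                for _ in range(_MAX_PLACEMENT_TRIES):
                    center = random_center(cell)
                    rr, cc = _footprint(cell, center, 1.0, shape)
                    if rr.size and not blocked(cell, rr, cc):
                        cell.center = center
                        break
                else:
                    raise PlacementError(
                        f"could not place cell {cell.identity} in frame {k}; "
                        "use fewer or smaller cells"
                    )
            else:
                m = margin(cell)
                for _ in range(_MAX_STEP_TRIES):
                    step = rng.uniform(-config.max_step, config.max_step, size=2)
                    center = np.array(
                        [
                            reflect(cell.center[0] + step[0], m, config.height - 1 - m),
                            reflect(cell.center[1] + step[1], m, config.width - 1 - m),
                        ]
                    )
                    rr, cc = _footprint(cell, center, scale, shape)
                    if rr.size and not blocked(cell, rr, cc):
                        cell.center = center
                        break
                else:
                    # stay put: the previous footprint is collision-free
                    # by construction (everyone else kept a gap to it)
                    rr, cc = prev_footprint[cell.identity]
            pending.discard(cell.identity)
            win = _dilated_window(rr, cc, shape)
            r0, c0, w = win
            dilated[r0 : r0 + w.shape[0], c0 : c0 + w.shape[1]] |= w
            prev_footprint[cell.identity] = (rr, cc)
            prev_window[cell.identity] = win
            rendered.append((cell, rr, cc))

        # arbitrary per-frame numbering, as independent segmentations give
        labels = rng.permutation(len(rendered)) + 1
        pixels = np.zeros(shape, dtype=np.uint16)
        truth: dict[int, int] = {}
        for (cell, rr, cc), label in zip(rendered, labels):
            pixels[rr, cc] = label
            truth[int(label)] = cell.identity
        frames.append(LabeledMask(pixels=pixels, frame_index=k))
        truth_frames.append(truth)

    return MaskSequence(frames=frames), GroundTruth(frames=tuple(truth_frames))


def score_tracking(result: TrackTable, truth: GroundTruth) -> float:
    """Fraction of true persisting consecutive-frame pairs linked correctly.

    A link (label a in frame k) -> (label b in frame k+1) is correct iff
    both labels map to the same true identity. The denominator is the
    number of identities present in both frames of each consecutive
    pair; with no persisting pairs the score is vacuously 1.0.
    """
    n_frames = len(truth)
    result_links: dict[tuple[int, int], int] = {}
    for points in result.tracks.values():
        for p0, p1 in zip(points, points[1:]):
            if p0.frame_index < 1 or p1.frame_index > n_frames:
                raise ConsistencyError(
                    f"track frame {p1.frame_index} outside the {n_frames}-frame truth"
                )
            result_links[(p0.frame_index, p0.label)] = p1.label

    total = 0
    correct = 0
    for k in range(1, n_frames):
        src_truth = truth.frames[k - 1]
        tgt_truth = truth.frames[k]
        tgt_by_identity = {ident: label for label, ident in tgt_truth.items()}
        for src_label, ident in src_truth.items():
            if ident not in tgt_by_identity:
                continue
            total += 1
            if result_links.get((k, src_label)) == tgt_by_identity[ident]:
                correct += 1
    if total == 0:
        return 1.0
    return correct / total


def write_ground_truth_csv(truth: GroundTruth, path: str | Path) -> None:
    rows = [
        {"frame": k, "label": label, "true_id": ident}
        for k, frame in enumerate(truth.frames, start=1)
        for label, ident in sorted(frame.items())
    ]
    pd.DataFrame(rows, columns=["frame", "label", "true_id"]).to_csv(
        path, index=False
    )


def read_ground_truth_csv(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path)
    n_frames = int(df["frame"].max()) if len(df) else 0
    frames: list[dict[int, int]] = [{} for _ in range(n_frames)]
    for row in df.itertuples(index=False):
        frames[int(row.frame) - 1][int(row.label)] = int(row.true_id)
    return GroundTruth(frames=tuple(frames))
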