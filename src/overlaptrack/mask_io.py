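"""Reading, writing and validation of segmented label masks.

A label mask is a 2-D integer image in which 0 marks background and each
positive value marks the pixels of one segmented cell in that frame.
Masks arrive as externally produced segmentation output (8/16-bit
grayscale TIFF or PNG); this module loads them, checks the data model,
and canonicalizes per-frame cell numbers to ``1..M_k``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import LabelRangeError, MaskFormatError, MaskIOError, SequenceError

_TIFF_SUFFIXES = {".tif", ".tiff"}
_SUPPORTED_SUFFIXES = _TIFF_SUFFIXES | {".png"}


@dataclass(frozen=True)
class LabeledMask:
    """One frame's integer label image.

    Parameters
    ----------
    pixels
        2-D array of non-negative integers, shape ``(height, width)``.
        0 is background; positive values are per-frame cell numbers.
    frame_index
        1-based position of the frame in its sequence.
    """

    pixels: np.ndarray
    frame_index: int = 1

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise MaskFormatError(
                f"label mask must be a single-channel 2-D image, got shape {arr.shape}"
            )
        if arr.size == 0:
            raise MaskFormatError("label mask must have height >= 1 and width >= 1")
        if not np.issubdtype(arr.dtype, np.integer):
            raise MaskFormatError(
                f"label mask must hold integers, got dtype {arr.dtype}"
            )
        if arr.size and arr.min() < 0:
            raise MaskFormatError("label mask contains negative pixel values")
        if self.frame_index < 1:
            raise MaskFormatError("frame_index must be >= 1")
        object.__setattr__(self, "pixels", arr)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def labels(self) -> np.ndarray:
        """Sorted array of positive labels present in the mask."""
        values = np.unique(self.pixels)
        return values[values > 0]

    @property
    def n_cells(self) -> int:
        """Number of distinct cells ``M_k`` in the frame."""
        return int(self.labels.size)

    def is_canonical(self) -> bool:
        """True when the positive labels are exactly ``1..M_k``."""
        labels = self.labels
        return bool(np.array_equal(labels, np.arange(1, labels.size + 1)))

    def with_pixels(self, pixels: np.ndarray) -> "LabeledMask":
        return LabeledMask(pixels=pixels, frame_index=self.frame_index)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabeledMask):
            return NotImplemented
        return self.frame_index == other.frame_index and np.array_equal(
            self.pixels, other.pixels
        )


@dataclass(frozen=True)
class MaskSequence:
    """A time-ordered series of equally sized label masks."""

    frames: Sequence[LabeledMask]
    paths: Sequence[Path] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if len(frames) < 2:
            raise SequenceError(
                f"a mask sequence needs >= 2 frames, got {len(frames)}"
            )
        first = frames[0]
        for frame in frames[1:]:
            if (frame.height, frame.width) != (first.height, first.width):
                raise MaskFormatError(
                    "all frames must share one image size: "
                    f"frame {first.frame_index} is {first.height}x{first.width} "
                    f"but frame {frame.frame_index} is {frame.height}x{frame.width}"
                )
        indices = [f.frame_index for f in frames]
        if indices != list(range(indices[0], indices[0] + len(frames))):
            raise SequenceError(
                f"frame indices must be consecutive and increasing, got {indices}"
            )
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "paths", tuple(self.paths))

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[LabeledMask]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> LabeledMask:
        return self.frames[i]

    @property
    def height(self) -> int:
        return self.frames[0].height

    @property
    def width(self) -> int:
        return self.frames[0].width


def read_mask(path: str | Path, frame_index: int = 1) -> LabeledMask:
    """Read one label mask from a grayscale TIFF or PNG file.

    Pixel values are returned exactly as stored; no renumbering happens
    here (see :func:`canonicalize_labels`).
    """
    path = Path(path)
    try:
        if path.suffix.lower() in _TIFF_SUFFIXES:
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except FileNotFoundError:
        raise MaskIOError(f"mask file not found: {path}") from None
    except Exception as exc:  # noqa: BLE001 - surface decoder failures uniformly
        raise MaskIOError(f"could not read mask file {path}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise MaskFormatError(
            f"{path}: expected a single-channel image, got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise MaskFormatError(
            f"{path}: expected integer pixel values, got dtype {arr.dtype}"
        )
    if arr.size and int(arr.min()) < 0:
        raise MaskFormatError(f"{path}: mask contains negative pixel values")
    return LabeledMask(pixels=arr, frame_index=frame_index)


def canonicalize_labels(mask: LabeledMask) -> LabeledMask:
    """Renumber positive labels to ``1..M_k`` in raster first-encounter order.

    Cells are numbered in the order in which they are first met scanning
    the image row-major (top-left to bottom-right), so the label set
    becomes exactly ``{1, ..., M_k}``. The background and the partition
    of foreground pixels into regions are unchanged. Idempotent.
    """
    flat = mask.pixels.ravel()
    values, first_idx = np.unique(flat, return_index=True)
    fg = values > 0
    values, first_idx = values[fg], first_idx[fg]
    if values.size == 0:
        return mask.with_pixels(mask.pixels.astype(np.uint16, copy=True))
    order = np.argsort(first_idx, kind="stable")
    # LUT over the dense range [0, max_label]; fine for 16-bit-scale labels
    lut = np.zeros(int(values.max()) + 1, dtype=np.int64)
    lut[values[order]] = np.arange(1, values.size + 1)
    out = lut[mask.pixels]
    dtype = np.uint16 if values.size <= np.iinfo(np.uint16).max else np.int64
    return mask.with_pixels(out.astype(dtype))


_NATURAL_RE = re.compile(r"(\d+)")


def _natural_key(path: Path) -> tuple:
    """Sort key treating digit runs numerically, e.g. t2 < t10."""
    return tuple(
        int(part) if part.isdigit() else part
        for part in _NATURAL_RE.split(path.name)
    )


def read_sequence(
    directory: str | Path, pattern: str = "*.tif", canonicalize: bool = True
) -> MaskSequence:
    """Read a directory of per-frame mask files into a :class:`MaskSequence`.

    Files matching ``pattern`` are ordered by natural (numeric-aware)
    filename sort, assigned frame indices ``1..N``, canonicalized, and
    checked for identical dimensions.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise MaskIOError(f"not a directory: {directory}")
    paths = sorted(directory.glob(pattern), key=_natural_key)
    if len(paths) < 2:
        raise SequenceError(
            f"need >= 2 mask files matching {pattern!r} in {directory}, "
            f"found {len(paths)}"
        )
    frames = []
    for k, path in enumerate(paths, start=1):
        mask = read_mask(path, frame_index=k)
        if frames and (mask.height, mask.width) != (frames[0].height, frames[0].width):
            raise MaskFormatError(
                f"dimension mismatch: {paths[0]} is "
                f"{frames[0].height}x{frames[0].width} but {path} is "
                f"{mask.height}x{mask.width}"
            )
        frames.append(canonicalize_labels(mask) if canonicalize else mask)
    return MaskSequence(frames=frames, paths=paths)


def write_mask(mask: LabeledMask, path: str | Path) -> None:
    """Write a mask as a 16-bit grayscale image (TIFF or PNG by suffix).

    Raises :class:`LabelRangeError` if a label does not fit in 16 bits.
    The written file round-trips pixel-exactly through :func:`read_mask`.
    """
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise MaskIOError(
            f"unsupported mask output format {path.suffix!r} (use .tif or .png)"
        )
    max_label = int(mask.pixels.max()) if mask.pixels.size else 0
    limit = np.iinfo(np.uint16).max
    if max_label > limit:
        raise LabelRangeError(
            f"label {max_label} exceeds the 16-bit output range ({limit})"
        )
    data = mask.pixels.astype(np.uint16)
    try:
        if path.suffix.lower() in _TIFF_SUFFIXES:
            tifffile.imwrite(path, data)
        else:
            iio.imwrite(path, data)
    except Exception as exc:  # noqa: BLE001
        raise MaskIOError(f"could not write mask file {path}: {exc}") from exc


def write_sequence(
    sequence: MaskSequence, directory: str | Path, prefix: str = "frame", fmt: str = "tif"
) -> list[Path]:
    """Write each frame to ``directory`` as ``<prefix>_<k:03d>.<fmt>``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for mask in sequence:
        path = directory / f"{prefix}_{mask.frame_index:03d}.{fmt}"
        write_mask(mask, path)
        paths.append(path)
    return paths
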