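"""Chaining frame mappings into global tracks and relabeling masks.

Per-frame cell numbers are arbitrary: the segmenter numbers each frame
independently. Chaining the per-pair mappings through time replaces
them with global track numbers ``1..T`` so that one cell carries one
number in every frame it appears in, and the masks are rewritten with
those track numbers as pixel values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assignment import FrameMapping, solve_mapping
from .cost import CostMatrix, TrackerConfig, build_cost_matrix
from .errors import ConsistencyError
from .mask_io import LabeledMask, MaskSequence
from .regions import CellRegion, count_overlaps, extract_regions


@dataclass(frozen=True)
class TrackPoint:
    """One track's record in one frame."""

    frame_index: int
    label: int
    centroid: tuple[float, float]  # (row, col)
    size: int


@dataclass(frozen=True)
class TrackTable:
    """Global track numbers with per-frame centroid and size records.

    Track ids are ``1..T`` in order of first appearance (frame, then
    label within the frame); each track covers a consecutive frame
    range — a terminated track never resumes.
    """

    tracks: dict[int, tuple[TrackPoint, ...]]

    def __post_init__(self) -> None:
        ids = sorted(self.tracks)
        if ids != list(range(1, len(ids) + 1)):
            raise ConsistencyError(f"track ids must be 1..T without gaps, got {ids}")
        for tid, points in self.tracks.items():
            frames = [p.frame_index for p in points]
            if frames != list(range(frames[0], frames[0] + len(frames))):
                raise ConsistencyError(
                    f"track {tid} frames not consecutive: {frames}"
                )

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)

    def labels_in_frame(self, frame_index: int) -> dict[int, int]:
        """Map ``per-frame label -> track id`` for one frame."""
        out: dict[int, int] = {}
        for tid, points in self.tracks.items():
            for p in points:
                if p.frame_index == frame_index:
                    if p.label in out:
                        raise ConsistencyError(
                            f"label {p.label} claimed twice in frame {frame_index}"
                        )
                    out[p.label] = tid
        return out

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format records: frame, track_id, x, y, size_px."""
        rows = [
            {
                "frame": p.frame_index,
                "track_id": tid,
                "x": p.centroid[1],
                "y": p.centroid[0],
                "size_px": p.size,
            }
            for tid in sorted(self.tracks)
            for p in self.tracks[tid]
        ]
        return pd.DataFrame(
            rows, columns=["frame", "track_id", "x", "y", "size_px"]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def chain_mappings(
    sequence: MaskSequence,
    mappings: list[FrameMapping],
    regions_by_frame: list[list[CellRegion]] | None = None,
) -> TrackTable:
    """Chain consecutive-pair mappings into a global :class:`TrackTable`.

    Every cell of frame 1 seeds a track. Each link extends the source
    cell's track onto its target; each unmatched target starts a new
    track; an unmatched source's track ends. Track ids follow first
    appearance order (frame, then label).
    """
    if len(mappings) != len(sequence) - 1:
        raise ConsistencyError(
            f"need {len(sequence) - 1} frame mappings for {len(sequence)} frames, "
            f"got {len(mappings)}"
        )
    if regions_by_frame is None:
        regions_by_frame = [extract_regions(mask) for mask in sequence]

    region_index = [
        {r.label: r for r in regions} for regions in regions_by_frame
    ]

    def check_labels(frame_pos: int, labels, kind: str) -> None:
        known = region_index[frame_pos]
        for label in labels:
            if label not in known:
                raise ConsistencyError(
                    f"mapping references {kind} label {label} absent from "
                    f"frame {sequence[frame_pos].frame_index}"
                )

    tracks: dict[int, list[TrackPoint]] = {}
    next_id = 1

    def start_track(frame_pos: int, label: int) -> int:
        nonlocal next_id
        region = region_index[frame_pos][label]
        tid = next_id
        next_id += 1
        tracks[tid] = [
            TrackPoint(
                frame_index=sequence[frame_pos].frame_index,
                label=label,
                centroid=region.centroid,
                size=region.size,
            )
        ]
        return tid

    # live: per-frame label -> track id, for the current frame
    live = {
        region.label: start_track(0, region.label)
        for region in regions_by_frame[0]
    }

    for pos, mapping in enumerate(mappings):
        check_labels(pos, mapping.links.keys(), "source")
        check_labels(pos + 1, mapping.links.values(), "target")
        check_labels(pos, mapping.unmatched_sources, "source")
        check_labels(pos + 1, mapping.unmatched_targets, "target")
        next_live: dict[int, int] = {}
        for src_label, tgt_label in sorted(mapping.links.items()):
            tid = live[src_label]
            region = region_index[pos + 1][tgt_label]
            tracks[tid].append(
                TrackPoint(
                    frame_index=sequence[pos + 1].frame_index,
                    label=tgt_label,
                    centroid=region.centroid,
                    size=region.size,
                )
            )
            next_live[tgt_label] = tid
        for tgt_label in sorted(mapping.unmatched_targets):
            next_live[tgt_label] = start_track(pos + 1, tgt_label)
        live = next_live

    return TrackTable(tracks={tid: tuple(pts) for tid, pts in tracks.items()})


def relabel_masks(sequence: MaskSequence, table: TrackTable) -> MaskSequence:
    """Rewrite every frame so tracked pixels carry their track id.

    Geometry is untouched: only pixel values change, background stays 0.
    """
    out_frames = []
    for pos, mask in enumerate(sequence):
        label_to_track = table.labels_in_frame(mask.frame_index)
        present = set(int(v) for v in mask.labels)
        missing = present - set(label_to_track)
        if missing:
            raise ConsistencyError(
                f"frame {mask.frame_index}: labels {sorted(missing)} have no track"
            )
        max_label = int(mask.pixels.max()) if mask.pixels.size else 0
        lut = np.zeros(max_label + 1, dtype=np.int64)
        for label, tid in label_to_track.items():
            lut[label] = tid
        relabeled = lut[mask.pixels]
        dtype = np.uint16 if table.n_tracks <= np.iinfo(np.uint16).max else np.int64
        out_frames.append(mask.with_pixels(relabeled.astype(dtype)))
    return MaskSequence(frames=out_frames)


@dataclass(frozen=True)
class TrackingResult:
    """Everything the pipeline produces for one mask sequence."""

    table: TrackTable
    relabeled: MaskSequence
    mappings: tuple[FrameMapping, ...]
    cost_matrices: tuple[CostMatrix, ...] = field(repr=False, default=())


def track_sequence(
    sequence: MaskSequence, config: TrackerConfig | None = None
) -> TrackingResult:
    """Run the full tracker: costs -> mappings -> chaining -> relabeling."""
    config = config or TrackerConfig()
    regions_by_frame = [extract_regions(mask) for mask in sequence]
    mappings: list[FrameMapping] = []
    matrices: list[CostMatrix] = []
    for pos in range(len(sequence) - 1):
        overlaps = count_overlaps(sequence[pos], sequence[pos + 1])
        matrix = build_cost_matrix(
            regions_by_frame[pos],
            regions_by_frame[pos + 1],
            overlaps,
            config,
            sequence.height,
            sequence.width,
            frame_pair=(
                sequence[pos].frame_index,
                sequence[pos + 1].frame_index,
            ),
        )
        matrices.append(matrix)
        mappings.append(solve_mapping(matrix, config))
    table = chain_mappings(sequence, mappings, regions_by_frame)
    relabeled = relabel_masks(sequence, table)
    return TrackingResult(
        table=table,
        relabeled=relabeled,
        mappings=tuple(mappings),
        cost_matrices=tuple(matrices),
    )


def export_mappings_csv(mappings: list[FrameMapping], path: str | Path) -> None:
    """Audit dump: one row per chosen link (frame_k, source, target, cost)."""
    rows = [
        {
            "frame_k": m.frame_pair[0],
            "source_label": src,
            "target_label": tgt,
            "cost": m.link_costs.get(src, float("nan")),
        }
        for m in mappings
        for src, tgt in m.sorted_links()
    ]
    pd.DataFrame(
        rows, columns=["frame_k", "source_label", "target_label", "cost"]
    ).to_csv(path, index=False)
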