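"""Centroid trajectories, per-step displacements and travel rates.

These are the downstream products of tracking: for each global track, a
time-ordered centroid path, the displacement vector of each consecutive
frame pair, and the average traveling rate (path length over elapsed
time, in pixels per minute). Optional quiver / 3-D plots visualize the
paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ContractViolationError
from .tracking import TrackTable

#: Typical live-cell acquisition interval for this kind of imaging.
DEFAULT_FRAME_INTERVAL_MIN = 15.0


@dataclass(frozen=True)
class Trajectory:
    """One track's centroid path: ordered ``(frame, x, y)`` points."""

    track_id: int
    points: tuple[tuple[int, float, float], ...]
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN

    def __post_init__(self) -> None:
        if not self.points:
            raise ContractViolationError("a trajectory needs >= 1 point")
        frames = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ContractViolationError(
                f"trajectory frames must strictly increase, got {frames}"
            )
        if self.frame_interval_min <= 0:
            raise ContractViolationError("frame_interval_min must be > 0")
        object.__setattr__(self, "points", tuple(self.points))

    def __len__(self) -> int:
        return len(self.points)


def trajectories_from_table(
    table: TrackTable, frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN
) -> list[Trajectory]:
    """Build one :class:`Trajectory` per track, ordered by track id."""
    return [
        Trajectory(
            track_id=tid,
            points=tuple(
                (p.frame_index, p.centroid[1], p.centroid[0])
                for p in table.tracks[tid]
            ),
            frame_interval_min=frame_interval_min,
        )
        for tid in sorted(table.tracks)
    ]


def displacements(traj: Trajectory) -> list[tuple[int, float, float, float]]:
    """Per-step motion: ``(frame, dx, dy, step_length)`` for each pair.

    The frame is the step's starting frame; a single-point trajectory
    has no steps and yields an empty list.
    """
    out = []
    for (f0, x0, y0), (_f1, x1, y1) in zip(traj.points, traj.points[1:]):
        dx, dy = x1 - x0, y1 - y0
        out.append((f0, dx, dy, math.hypot(dx, dy)))
    return out


def travel_rate(traj: Trajectory) -> float:
    """Average traveling rate: path length / elapsed time, px per minute."""
    if len(traj) < 2:
        raise ContractViolationError(
            f"travel rate undefined for single-point track {traj.track_id}"
        )
    path_length = sum(step[3] for step in displacements(traj))
    elapsed = (traj.points[-1][0] - traj.points[0][0]) * traj.frame_interval_min
    return path_length / elapsed


def export_trajectories(table: TrackTable, path: str | Path) -> None:
    """Write the per-frame track records as CSV (frame, track_id, x, y, size_px)."""
    table.to_csv(path)


def read_trajectories_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def export_displacements(trajs: list[Trajectory], path: str | Path) -> None:
    rows = [
        {"track_id": t.track_id, "frame": f, "dx": dx, "dy": dy, "step_px": step}
        for t in trajs
        for f, dx, dy, step in displacements(t)
    ]
    pd.DataFrame(
        rows, columns=["track_id", "frame", "dx", "dy", "step_px"]
    ).to_csv(path, index=False)


def export_rates(trajs: list[Trajectory], path: str | Path) -> None:
    """Per-track travel rates; single-point tracks are recorded as NaN."""
    rows = [
        {
            "track_id": t.track_id,
            "n_frames": len(t),
            "rate_px_per_min": travel_rate(t) if len(t) >= 2 else float("nan"),
        }
        for t in trajs
    ]
    pd.DataFrame(
        rows, columns=["track_id", "n_frames", "rate_px_per_min"]
    ).to_csv(path, index=False)


def plot_trajectories_2d(
    trajs: list[Trajectory], path: str | Path, height: int, width: int
) -> None:
    """Quiver plot: one arrow per step, showing direction and distance."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 8 * height / max(width, 1)))
    for traj in trajs:
        xs = [p[1] for p in traj.points]
        ys = [p[2] for p in traj.points]
        if len(xs) >= 2:
            ax.quiver(
                xs[:-1],
                ys[:-1],
                [b - a for a, b in zip(xs, xs[1:])],
                [b - a for a, b in zip(ys, ys[1:])],
                angles="xy",
                scale_units="xy",
                scale=1,
                width=0.003,
            )
    ax.set_xlim(0, width)
    ax.set_ylim(height, 0)  # image convention: y grows downward
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_title("Cell centroid trajectories")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_trajectories_3d(trajs: list[Trajectory], path: str | Path) -> None:
    """3-D (x, y, frame) line plot of all trajectories."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(8, 8))
    ax = fig.add_subplot(projection="3d")
    for traj in trajs:
        ax.plot(
            [p[1] for p in traj.points],
            [p[2] for p in traj.points],
            [p[0] for p in traj.points],
        )
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_zlabel("frame")
    fig.savefig(path, dpi=120)
    plt.close(fig)
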