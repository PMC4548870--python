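"""Optimal one-to-one frame-to-frame mapping from a cost matrix.

Choosing which source cell becomes which target cell is a minimum-cost
bipartite assignment problem over the valid (finite-cost) pairs. The
mapping selected is the one that, lexicographically,

1. links as many cells as possible using only valid pairs,
2. among those, minimizes the total cost of the linked pairs,
3. among equal-cost optima, has the lexicographically smallest sorted
   link list (lowest source label first, then lowest target label).

Sources left unlinked end their tracks; targets left unlinked start new
ones. ``brute_force_mapping`` realizes the same objective by exhaustive
enumeration and serves as an independent oracle on small instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .cost import CostMatrix, TrackerConfig
from .errors import ContractViolationError

_REL_TOL = 1e-9
_ABS_TOL = 1e-9


@dataclass(frozen=True)
class FrameMapping:
    """The chosen source->target links for one consecutive frame pair."""

    frame_pair: tuple[int, int]
    links: dict[int, int]  # source_label -> target_label
    link_costs: dict[int, float] = field(default_factory=dict)
    unmatched_sources: tuple[int, ...] = ()
    unmatched_targets: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        targets = list(self.links.values())
        if len(set(targets)) != len(targets):
            raise ContractViolationError("mapping is not one-to-one on targets")

    @property
    def n_links(self) -> int:
        return len(self.links)

    @property
    def total_cost(self) -> float:
        return float(sum(self.link_costs.values()))

    def sorted_links(self) -> list[tuple[int, int]]:
        return sorted(self.links.items())


def _valid_mask(values: np.ndarray, max_cost: float) -> np.ndarray:
    return values < max_cost


def _optimum(values: np.ndarray, valid: np.ndarray) -> tuple[int, float]:
    """(max links, min total cost among max-link matchings) via assignment.

    Invalid entries get a finite penalty larger than the total of all
    valid costs, so the solver avoids them whenever any valid completion
    exists; surviving penalty picks are dropped afterwards.
    """
    if values.size == 0 or not valid.any():
        return 0, 0.0
    penalty = float(values[valid].sum()) + 1.0
    padded = np.where(valid, values, penalty)
    rows, cols = linear_sum_assignment(padded)
    keep = valid[rows, cols]
    return int(keep.sum()), float(values[rows[keep], cols[keep]].sum())


def _close(a: float, b: float) -> bool:
    return math.isclose(a, b, rel_tol=_REL_TOL, abs_tol=_ABS_TOL)


def solve_mapping(costs: CostMatrix, config: TrackerConfig) -> FrameMapping:
    """Globally optimal one-to-one partial matching of a cost matrix.

    Matches exhaustive enumeration (:func:`brute_force_mapping`) on any
    instance, including the deterministic tie-break.
    """
    values = costs.values
    valid = _valid_mask(values, config.max_cost)
    n_links, total = _optimum(values, valid)

    n_rows, n_cols = values.shape
    chosen: list[tuple[int, int]] = []  # (row, col) indices
    used_cols: set[int] = set()
    chosen_cost = 0.0
    # Fix each source in ascending order to its smallest optimal target
    # (or to "unmatched" when no target preserves the optimum).
    for i in range(n_rows):
        matched = False
        for j in range(n_cols):
            if j in used_cols or not valid[i, j]:
                continue
            free_cols = [c for c in range(n_cols) if c != j and c not in used_cols]
            sub = values[np.ix_(range(i + 1, n_rows), free_cols)]
            sub_valid = valid[np.ix_(range(i + 1, n_rows), free_cols)]
            rest_links, rest_cost = _optimum(sub, sub_valid)
            if len(chosen) + 1 + rest_links == n_links and _close(
                chosen_cost + values[i, j] + rest_cost, total
            ):
                chosen.append((i, j))
                used_cols.add(j)
                chosen_cost += values[i, j]
                matched = True
                break
        if not matched:
            # leaving i unmatched always preserves feasibility here
            continue

    links = {
        costs.source_labels[i]: costs.target_labels[j] for i, j in chosen
    }
    link_costs = {
        costs.source_labels[i]: float(values[i, j]) for i, j in chosen
    }
    matched_rows = {i for i, _ in chosen}
    return FrameMapping(
        frame_pair=costs.frame_pair,
        links=links,
        link_costs=link_costs,
        unmatched_sources=tuple(
            costs.source_labels[i] for i in range(n_rows) if i not in matched_rows
        ),
        unmatched_targets=tuple(
            costs.target_labels[j] for j in range(n_cols) if j not in used_cols
        ),
    )


def brute_force_mapping(costs: CostMatrix, config: TrackerConfig) -> FrameMapping:
    """Exhaustive-search oracle for :func:`solve_mapping`.

    Enumerates every injective partial mapping over valid pairs; refuses
    instances with min dimension above 8 (combinatorial blow-up).
    """
    values = costs.values
    n_rows, n_cols = values.shape
    if min(n_rows, n_cols) > 8:
        raise ContractViolationError(
            f"brute force limited to min dimension <= 8, got {values.shape}"
        )
    valid = _valid_mask(values, config.max_cost)

    best: tuple[int, float, tuple[tuple[int, int], ...]] | None = None

    def recurse(
        row: int, used_cols: frozenset[int], acc: list[tuple[int, int]], cost: float
    ) -> None:
        nonlocal best
        if row == n_rows:
            key_links = tuple(sorted(acc))
            candidate = (-len(acc), cost, key_links)
            if best is None or candidate < best:
                best = candidate
            return
        recurse(row + 1, used_cols, acc, cost)  # row unmatched
        for col in range(n_cols):
            if col in used_cols or not valid[row, col]:
                continue
            acc.append((row, col))
            recurse(row + 1, used_cols | {col}, acc, cost + values[row, col])
            acc.pop()

    recurse(0, frozenset(), [], 0.0)
    assert best is not None
    _, _, pairs = best
    links = {costs.source_labels[i]: costs.target_labels[j] for i, j in pairs}
    link_costs = {costs.source_labels[i]: float(values[i, j]) for i, j in pairs}
    matched_rows = {i for i, _ in pairs}
    matched_cols = {j for _, j in pairs}
    return FrameMapping(
        frame_pair=costs.frame_pair,
        links=links,
        link_costs=link_costs,
        unmatched_sources=tuple(
            costs.source_labels[i] for i in range(n_rows) if i not in matched_rows
        ),
        unmatched_targets=tuple(
            costs.target_labels[j] for j in range(n_cols) if j not in matched_cols
        ),
    )
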