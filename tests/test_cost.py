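import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from overlaptrack.cost import (
    CostMatrix,
    TrackerConfig,
    build_cost_matrix,
    centroid_metric,
    overlap_metric,
    pair_cost,
    size_metric,
)
from overlaptrack.errors import ContractViolationError
from overlaptrack.mask_io import LabeledMask
from overlaptrack.regions import OverlapTable, count_overlaps, extract_regions

from conftest import block_mask


def region_at(label, frame, size, centroid):
    """Minimal CellRegion stand-in via a real extraction is overkill here;
    build one directly with a consistent dummy pixel set."""
    from overlaptrack.regions import CellRegion

    pixels = frozenset((0, i) for i in range(size))
    return CellRegion(
        label=label, frame_index=frame, size=size, centroid=centroid,
        pixel_set=pixels,
    )


class TestMetrics:
    def test_overlap_metric_hand_values(self):
        assert overlap_metric(100, 100, 100) == 0.0
        assert overlap_metric(100, 100, 0) == 1.0
        assert overlap_metric(100, 50, 50) == pytest.approx(0.25, abs=1e-12)

    def test_overlap_metric_zero_only_for_perfect_match(self):
        assert overlap_metric(100, 99, 99) > 0.0

    def test_overlap_metric_rejects_out_of_range_overlap(self):
        with pytest.raises(ContractViolationError):
            overlap_metric(10, 5, 6)
        with pytest.raises(ContractViolationError):
            overlap_metric(10, 5, -1)

    def test_overlap_metric_symmetric(self):
        assert overlap_metric(30, 70, 20) == overlap_metric(70, 30, 20)

    def test_overlap_metric_strictly_decreasing_in_overlap(self):
        values = [overlap_metric(80, 60, n) for n in range(0, 61, 10)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_centroid_metric_hand_values(self):
        assert centroid_metric((5.0, 7.0), (5.0, 7.0), 100, 100) == 0.0
        # 3-4-5 displacement in the 520x696 field
        expected = 5.0 / math.hypot(520, 696)
        assert centroid_metric((0.0, 0.0), (3.0, 4.0), 520, 696) == pytest.approx(
            expected, abs=1e-12
        )

    def test_centroid_metric_full_diagonal_is_one(self):
        h, w = 200, 300
        assert centroid_metric((0.0, 0.0), (h, w), h, w) == pytest.approx(1.0)

    def test_size_metric_hand_values(self):
        assert size_metric(100, 100) == 0.0
        assert size_metric(100, 50) == 0.5
        assert size_metric(80, 100) == pytest.approx(0.2)

    def test_size_metric_symmetric_and_below_one(self):
        assert size_metric(3, 900) == size_metric(900, 3) < 1.0

    @settings(max_examples=300, derandomize=True)
    @given(
        s1=st.integers(1, 10_000),
        s2=st.integers(1, 10_000),
        frac=st.floats(0.0, 1.0),
        x1=st.floats(0, 695), y1=st.floats(0, 519),
        x2=st.floats(0, 695), y2=st.floats(0, 519),
    )
    def test_all_metrics_normalized(self, s1, s2, frac, x1, y1, x2, y2):
        n = int(frac * min(s1, s2))
        assert 0.0 <= overlap_metric(s1, s2, n) <= 1.0
        assert 0.0 <= centroid_metric((y1, x1), (y2, x2), 520, 696) <= 1.0
        assert 0.0 <= size_metric(s1, s2) < 1.0


class TestTrackerConfig:
    def test_defaults(self):
        config = TrackerConfig()
        assert (config.weight_overlap, config.weight_centroid,
                config.weight_size) == (2.0, 1.0, 0.5)
        assert config.weight_sum == 3.5

    def test_negative_weight_rejected(self):
        with pytest.raises(ContractViolationError):
            TrackerConfig(weight_overlap=-1)

    def test_max_cost_must_exceed_weight_sum(self):
        with pytest.raises(ContractViolationError):
            TrackerConfig(max_cost=3.0)

    def test_unknown_key_rejected_by_name(self):
        with pytest.raises(ContractViolationError, match="wieght_overlap"):
            TrackerConfig.from_dict({"wieght_overlap": 2})

    def test_json_round_trip(self, tmp_path):
        config = TrackerConfig(weight_size=0.8, max_centroid_distance=80)
        path = tmp_path / "cfg.json"
        import json

        path.write_text(json.dumps(config.to_dict()))
        assert TrackerConfig.from_json(path) == config


class TestPairCost:
    config = TrackerConfig()

    def test_identical_region_costs_zero(self):
        region = region_at(1, 1, 50, (10.0, 10.0))
        target = region_at(1, 2, 50, (10.0, 10.0))
        assert pair_cost(region, target, 50, self.config, 520, 696) == 0.0

    def test_pathological_pair_gets_max_cost(self):
        a = region_at(1, 1, 50, (10.0, 10.0))
        b = region_at(1, 2, 50, (310.0, 310.0))  # ~424 px away
        assert pair_cost(a, b, 0, self.config, 520, 696) == self.config.max_cost

    def test_filter_is_conjunctive_overlap_overrides_distance(self):
        # any shared pixels keep the pair valid, however far the centroids
        a = region_at(1, 1, 50, (10.0, 10.0))
        b = region_at(1, 2, 50, (310.0, 310.0))
        cost = pair_cost(a, b, 1, self.config, 520, 696)
        assert cost < self.config.max_cost

    def test_zero_overlap_within_threshold_stays_valid(self):
        a = region_at(1, 1, 50, (10.0, 10.0))
        b = region_at(1, 2, 50, (40.0, 40.0))  # ~42 px < 50
        cost = pair_cost(a, b, 0, self.config, 520, 696)
        assert cost < self.config.max_cost

    def test_weighted_sum_hand_value(self):
        # O=0.25, delta_c for a 3-4-5 offset in 520x696, delta_s=0.5
        a = region_at(1, 1, 100, (0.0, 0.0))
        b = region_at(1, 2, 50, (3.0, 4.0))
        expected = 2 * 0.25 + 1 * (5.0 / math.hypot(520, 696)) + 0.5 * 0.5
        assert pair_cost(a, b, 50, self.config, 520, 696) == pytest.approx(
            expected, abs=1e-12
        )

    def test_finite_cost_bounded_by_weight_sum(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            s1, s2 = rng.integers(1, 500, size=2)
            n = int(rng.integers(0, min(s1, s2) + 1))
            a = region_at(1, 1, int(s1), tuple(rng.uniform(0, 100, 2)))
            b = region_at(1, 2, int(s2), tuple(rng.uniform(0, 100, 2)))
            cost = pair_cost(a, b, n, self.config, 520, 696)
            assert cost == self.config.max_cost or cost <= self.config.weight_sum

    def test_cost_decreases_as_overlap_grows(self):
        a = region_at(1, 1, 80, (10.0, 10.0))
        b = region_at(1, 2, 60, (12.0, 11.0))
        costs = [
            pair_cost(a, b, n, self.config, 520, 696) for n in range(0, 61, 12)
        ]
        assert all(x > y for x, y in zip(costs, costs[1:]))


class TestBuildCostMatrix:
    config = TrackerConfig()

    def test_single_identical_cell(self):
        mask1 = block_mask((50, 50), [(1, 10, 20, 10, 20)], frame_index=1)
        mask2 = block_mask((50, 50), [(1, 10, 20, 10, 20)], frame_index=2)
        matrix = build_cost_matrix(
            extract_regions(mask1), extract_regions(mask2),
            count_overlaps(mask1, mask2), self.config, 50, 50,
        )
        assert matrix.shape == (1, 1)
        assert matrix.values[0, 0] == 0.0

    def test_empty_target_frame(self):
        mask1 = block_mask((30, 30), [(1, 0, 3, 0, 3)], frame_index=1)
        mask2 = LabeledMask(np.zeros((30, 30), dtype=np.int64), frame_index=2)
        matrix = build_cost_matrix(
            extract_regions(mask1), extract_regions(mask2),
            count_overlaps(mask1, mask2), self.config, 30, 30,
        )
        assert matrix.shape == (1, 0)

    def test_distant_stationary_cells_cross_costs_invalid(self):
        blocks = [(1, 2, 7, 2, 7), (2, 190, 195, 290, 295)]
        mask1 = block_mask((200, 300), blocks, frame_index=1)
        mask2 = block_mask((200, 300), blocks, frame_index=2)
        matrix = build_cost_matrix(
            extract_regions(mask1), extract_regions(mask2),
            count_overlaps(mask1, mask2), self.config, 200, 300,
        )
        assert matrix.values[0, 0] == 0.0 and matrix.values[1, 1] == 0.0
        assert matrix.values[0, 1] == self.config.max_cost
        assert matrix.values[1, 0] == self.config.max_cost

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractViolationError):
            CostMatrix(
                frame_pair=(1, 2), source_labels=(1,), target_labels=(1, 2),
                values=np.zeros((1, 1)),
            )
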