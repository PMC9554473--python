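"""Boxes, IoU/CIoU, counting errors, and average precision."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikedet.boxes import BBox, box_iou_matrix, ciou_loss, iou
from spikedet.metrics import (ConfusionCounts, CountSeries, accuracy,
                              average_precision, mae, match_detections,
                              mean_average_precision_range,
                              mean_error_accuracy, recall, rmse)


def random_box(rng, span=100.0):
    cx, cy = rng.uniform(0, span, 2)
    w, h = rng.uniform(0.5, span / 2, 2)
    return BBox(cx, cy, w, h)


class TestIou:
    def test_identical_boxes(self):
        b = BBox(5, 5, 4, 4)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(BBox(2, 2, 2, 2), BBox(20, 20, 2, 2)) == 0.0

    def test_unit_overlap_corner_case(self):
        a = BBox.from_xyxy(0, 0, 2, 2)
        b = BBox.from_xyxy(1, 1, 3, 3)
        assert iou(a, b) == pytest.approx(1 / 7)

    def test_symmetry_and_range(self, rng):
        for _ in range(200):
            a, b = random_box(rng), random_box(rng)
            v = iou(a, b)
            assert 0 <= v <= 1
            assert v == pytest.approx(iou(b, a))

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            BBox(0, 0, 0, 1)


class TestCiou:
    def test_zero_for_identical_boxes(self):
        b = BBox(3, 4, 5, 6)
        loss, terms = ciou_loss(b, b)
        assert loss == 0.0
        assert terms.iou == 1.0 and terms.rho2 == 0.0

    def test_concentric_same_aspect_squares(self):
        loss, terms = ciou_loss(BBox(0, 0, 2, 2), BBox(0, 0, 4, 4))
        assert terms.iou == pytest.approx(0.25)
        assert terms.rho2 == 0.0 and terms.v == 0.0
        assert loss == pytest.approx(0.75)

    def test_aspect_term_hand_value(self):
        # v for (w,h)=(1,1) against (2,1)
        _, terms = ciou_loss(BBox(0, 0, 1, 1), BBox(0, 0, 2, 1))
        expected = (4 / math.pi ** 2) * (math.atan(2) - math.atan(1)) ** 2
        assert terms.v == pytest.approx(expected, rel=1e-9)
        assert terms.v == pytest.approx(0.04195, abs=2e-5)

    def test_loss_bounds_and_center_distance_ratio(self, rng):
        for _ in range(1000):
            a, b = random_box(rng), random_box(rng)
            loss, terms = ciou_loss(a, b)
            assert loss >= 1 - terms.iou >= 0
            assert terms.rho2 <= terms.c2
            la, _ = ciou_loss(a, a)
            assert la == 0.0


class TestCountingErrors:
    def test_perfect_counts(self):
        s = CountSeries([3, 5, 7], [3, 5, 7])
        assert rmse(s) == 0.0 and mae(s) == 0.0
        assert mean_error_accuracy(s) == (0.0, 100.0)

    def test_hand_values(self):
        s = CountSeries([3, 5], [1, 1])
        assert rmse(s) == pytest.approx(math.sqrt(10))
        assert mae(s) == pytest.approx(3.0)
        assert rmse(CountSeries([5], [2])) == 3.0

    def test_sign_insensitive(self):
        assert mae(CountSeries([1, 1], [3, 5])) == pytest.approx(3.0)

    def test_relative_error_convention(self):
        assert mean_error_accuracy(CountSeries([8], [10])) == (
            pytest.approx(20.0), pytest.approx(80.0))
        err, acc = mean_error_accuracy(CountSeries([15, 9], [10, 10]))
        assert err == pytest.approx(30.0) and acc == pytest.approx(70.0)

    def test_zero_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            mean_error_accuracy(CountSeries([1], [0]))
        with pytest.raises(ValueError):
            CountSeries([], [])

    def test_mae_never_exceeds_rmse_on_random_series(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 30))
            s = CountSeries(rng.integers(0, 100, n), rng.integers(1, 100, n))
            assert mae(s) <= rmse(s) + 1e-12


class TestConfusion:
    def test_accuracy_recall_hand_values(self):
        c = ConfusionCounts(tp=7, fp=2, fn=3, tn=0)
        assert accuracy(c) == pytest.approx(7 / 12)
        assert recall(ConfusionCounts(tp=9, fp=0, fn=1)) == pytest.approx(0.9)
        assert accuracy(ConfusionCounts(5, 0, 0, 5)) == 1.0
        assert accuracy(ConfusionCounts(0, 3, 4, 0)) == 0.0
        assert recall(ConfusionCounts(3, 9, 0)) == 1.0
        assert recall(ConfusionCounts(0, 0, 4)) == 0.0

    def test_undefined_cases(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionCounts(0, 0, 0, 0))
        with pytest.raises(ValueError):
            recall(ConfusionCounts(0, 5, 0))

    @given(st.integers(1, 20), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, k, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0 or tp + fn == 0:
            return
        a = ConfusionCounts(tp, fp, fn, tn)
        b = ConfusionCounts(k * tp, k * fp, k * fn, k * tn)
        assert accuracy(a) == pytest.approx(accuracy(b))
        assert recall(a) == pytest.approx(recall(b))


def brute_force_ap(dets, gts, iou_match=0.5, levels=101):
    """Independent oracle: enumerate every ranked prefix, take the best
    precision at recall >= r for each of the 101 recall levels."""
    scores, tp, n_gt = match_detections(dets, gts, iou_match)
    if len(scores) == 0:
        return 0.0
    best = []
    for r in np.linspace(0, 1, levels):
        cand = [1.0] if r == 0 else []
        for k in range(1, len(scores) + 1):
            rec = tp[:k].sum() / n_gt
            prec = tp[:k].sum() / k
            if rec >= r:
                cand.append(prec)
        best.append(max(cand) if cand else 0.0)
    return float(np.mean(best))


class TestAveragePrecision:
    def test_perfect_detector(self):
        gts = {"a": np.array([[0, 0, 10, 10], [20, 20, 30, 30.0]])}
        dets = {"a": (gts["a"].copy(), np.array([0.9, 0.8]))}
        assert average_precision(dets, gts) == pytest.approx(1.0)
        assert mean_average_precision_range(dets, gts) == pytest.approx(1.0)

    def test_no_detections(self):
        gts = {"a": np.array([[0, 0, 10, 10.0]])}
        assert average_precision({"a": (np.zeros((0, 4)), np.zeros(0))}, gts) == 0.0

    def test_tp_above_fp_still_perfect_under_interpolation(self):
        gts = {"a": np.array([[0, 0, 10, 10.0]])}
        dets = {"a": (np.array([[0, 0, 10, 10], [50, 50, 60, 60.0]]),
                      np.array([0.9, 0.4]))}
        assert average_precision(dets, gts) == pytest.approx(1.0)

    def test_zero_ground_truth_signalled(self):
        with pytest.raises(ValueError):
            average_precision({"a": (np.zeros((0, 4)), np.zeros(0))}, {"a": []})

    def test_matches_brute_force_enumeration(self, rng):
        for trial in range(25):
            n_gt = int(rng.integers(1, 5))
            n_det = int(rng.integers(0, 10))
            xy = rng.uniform(0, 60, (n_gt, 2))
            gts = {"img": np.column_stack([xy, xy + rng.uniform(5, 20, (n_gt, 2))])}
            dxy = rng.uniform(0, 60, (n_det, 2))
            dets = {"img": (np.column_stack(
                [dxy, dxy + rng.uniform(5, 20, (n_det, 2))]),
                rng.random(n_det))}
            assert average_precision(dets, gts) == pytest.approx(
                brute_force_ap(dets, gts), abs=1e-9)

    def test_each_ground_truth_matched_at_most_once(self):
        gt = {"a": np.array([[0, 0, 10, 10.0]])}
        dets = {"a": (np.array([[0, 0, 10, 10], [0, 0, 10, 10.0]]),
                      np.array([0.9, 0.8]))}
        _, tp, n_gt = match_detections(dets, gt)
        assert tp.tolist() == [True, False] and n_gt == 1


def test_box_iou_matrix_agrees_with_scalar_iou(rng):
    a = np.array([[0, 0, 2, 2], [1, 1, 3, 3.0]])
    m = box_iou_matrix(a, a)
    assert m[0, 1] == pytest.approx(1 / 7)
    assert np.allclose(np.diag(m), 1.0)
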