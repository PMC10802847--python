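"""Detection metrics against independent brute-force oracles.

The oracles deliberately avoid the library's code paths: IoU by counting
pixels on a rasterized grid, matching by a plain re-implementation of the
greedy protocol on top of pixel-counted IoU, and average precision by
re-running the matcher from scratch at every distinct score threshold.
"""

import numpy as np
import pytest

from fracture3d import (
    BoxRecord,
    ConfusionCounts,
    iou,
    iou_stats,
    match,
    pr_curve,
    precision,
    recall,
)

# ---------------------------------------------------------------- oracles


def pixel_iou(a: BoxRecord, b: BoxRecord, grid=600) -> float:
    ga = np.zeros((grid, grid), dtype=bool)
    gb = np.zeros((grid, grid), dtype=bool)
    ga[a.y_start : a.y_start + a.y_extent, a.x_start : a.x_start + a.x_extent] = True
    gb[b.y_start : b.y_start + b.y_extent, b.x_start : b.x_start + b.x_extent] = True
    union = (ga | gb).sum()
    return (ga & gb).sum() / union


def brute_match(gt, pred, iou_min=0.5):
    """Greedy protocol, re-implemented with pixel-counting IoU."""
    order = sorted(
        pred,
        key=lambda p: (-(p.score if p.score is not None else 1.0), p.slice_index,
                       p.x_start, p.y_start, p.x_extent, p.y_extent),
    )
    claimed = set()
    ious = []
    tp = fp = 0
    for p in order:
        candidates = [
            (pixel_iou(g, p), i)
            for i, g in enumerate(gt)
            if g.slice_index == p.slice_index and i not in claimed
        ]
        best = max(candidates, default=(0.0, -1))
        if best[1] >= 0 and best[0] >= iou_min:
            claimed.add(best[1])
            ious.append(best[0])
            tp += 1
        else:
            fp += 1
    return (tp, fp, len(gt) - len(claimed)), ious


def brute_ap(gt, pred, iou_min=0.5):
    """Average precision by re-matching at every distinct threshold."""
    scores = sorted({p.score for p in pred}, reverse=True)
    points = []
    for t in scores:
        kept = [p for p in pred if p.score >= t]
        (tp, fp, fn), _ = brute_match(gt, kept, iou_min)
        prec = tp / (tp + fp) if tp + fp else 1.0
        rec = tp / (tp + fn) if tp + fn else 1.0
        points.append((rec, prec))
    ap = 0.0
    prev_r = 0.0
    for r, _ in points:
        if r > prev_r:
            envelope = max(p for rr, p in points if rr >= r)
            ap += (r - prev_r) * envelope
            prev_r = r
    return ap


def random_instance(rng, grid=60):
    n_slices = int(rng.integers(1, 4))
    gt, pred = [], []
    for k in range(n_slices):
        for _ in range(int(rng.integers(0, 5))):
            gt.append(
                BoxRecord(int(rng.integers(0, grid - 10)), int(rng.integers(0, grid - 10)),
                          int(rng.integers(3, 15)), int(rng.integers(3, 15)), slice_index=k)
            )
        for _ in range(int(rng.integers(0, 6))):
            pred.append(
                BoxRecord(int(rng.integers(0, grid - 10)), int(rng.integers(0, grid - 10)),
                          int(rng.integers(3, 15)), int(rng.integers(3, 15)), slice_index=k,
                          score=float(rng.uniform(0.01, 1.0)))
            )
    return gt, pred


# ------------------------------------------------------------------ tests


class TestIoU:
    def test_identical_boxes(self):
        a = BoxRecord(5, 5, 10, 10)
        assert iou(a, a) == 1.0

    def test_disjoint_boxes(self):
        assert iou(BoxRecord(0, 0, 5, 5), BoxRecord(20, 20, 5, 5)) == 0.0

    def test_quarter_overlap_fraction(self):
        """(0,0,10,10) vs (5,5,10,10): 25 shared pixels of 175 total."""
        v = iou(BoxRecord(0, 0, 10, 10), BoxRecord(5, 5, 10, 10))
        assert v == pytest.approx(25 / 175, abs=1e-12)

    def test_symmetry_and_pixel_count_agreement(self, rng):
        for _ in range(100):
            a = BoxRecord(int(rng.integers(0, 50)), int(rng.integers(0, 50)),
                          int(rng.integers(1, 20)), int(rng.integers(1, 20)))
            b = BoxRecord(int(rng.integers(0, 50)), int(rng.integers(0, 50)),
                          int(rng.integers(1, 20)), int(rng.integers(1, 20)))
            assert iou(a, b) == iou(b, a)
            assert iou(a, b) == pytest.approx(pixel_iou(a, b, grid=80), abs=1e-12)


class TestMatch:
    def test_perfect_detector(self):
        gt = [BoxRecord(i * 20, 0, 10, 10, slice_index=0) for i in range(3)]
        pred = [
            BoxRecord(b.x_start, b.y_start, b.x_extent, b.y_extent,
                      slice_index=0, score=0.5)
            for b in gt
        ]
        counts, ious = match(gt, pred)
        assert (counts.tp, counts.fp, counts.fn) == (3, 0, 0)
        assert ious == [1.0, 1.0, 1.0]

    def test_duplicate_prediction_is_false_positive(self):
        gt = [BoxRecord(10, 10, 10, 10, slice_index=0)]
        pred = [
            BoxRecord(10, 10, 10, 10, slice_index=0, score=0.9),
            BoxRecord(11, 10, 10, 10, slice_index=0, score=0.8),
        ]
        counts, _ = match(gt, pred)
        assert (counts.tp, counts.fp, counts.fn) == (1, 1, 0)

    def test_no_predictions_all_missed(self):
        gt = [BoxRecord(0, 0, 5, 5, slice_index=k) for k in range(2)]
        counts, ious = match(gt, [])
        assert (counts.tp, counts.fp, counts.fn) == (0, 0, 2)
        assert ious == []

    def test_matching_respects_slice_boundaries(self):
        gt = [BoxRecord(10, 10, 10, 10, slice_index=0)]
        pred = [BoxRecord(10, 10, 10, 10, slice_index=1, score=0.9)]
        counts, _ = match(gt, pred)
        assert (counts.tp, counts.fp, counts.fn) == (0, 1, 1)


class TestPrecisionRecall:
    def test_arithmetic(self):
        assert precision(ConfusionCounts(tp=3, fp=1)) == 0.75
        assert recall(ConfusionCounts(tp=3, fn=0)) == 1.0
        assert recall(ConfusionCounts(tp=2, fn=2)) == 0.5

    def test_degenerate_conventions(self):
        assert precision(ConfusionCounts()) == 1.0
        assert recall(ConfusionCounts()) == 1.0


class TestPRCurve:
    def test_perfect_detector_ap_1(self):
        gt = [BoxRecord(i * 20, 0, 10, 10, slice_index=0) for i in range(5)]
        pred = [
            BoxRecord(b.x_start, b.y_start, b.x_extent, b.y_extent,
                      slice_index=0, score=0.5 + 0.05 * i)
            for i, b in enumerate(gt)
        ]
        assert pr_curve(gt, pred).average_precision == 1.0

    def test_ranking_matters(self):
        gt = [BoxRecord(10, 10, 10, 10, slice_index=0)]
        hit = BoxRecord(10, 10, 10, 10, slice_index=0)
        miss = BoxRecord(40, 40, 10, 10, slice_index=0)

        def scored(box, s):
            return BoxRecord(box.x_start, box.y_start, box.x_extent, box.y_extent,
                             slice_index=0, score=s)

        assert pr_curve(gt, [scored(hit, 0.9), scored(miss, 0.8)]).average_precision == 1.0
        assert pr_curve(gt, [scored(miss, 0.9), scored(hit, 0.8)]).average_precision == 0.5

    def test_no_predictions(self):
        curve = pr_curve([BoxRecord(0, 0, 5, 5)], [])
        assert curve.average_precision == 0.0
        assert curve.recalls == [0.0]

    def test_recall_is_non_decreasing(self, rng):
        gt, pred = random_instance(rng)
        curve = pr_curve(gt, pred)
        assert all(b >= a for a, b in zip(curve.recalls, curve.recalls[1:]))

    def test_ap_invariant_to_monotone_score_rescale(self, rng):
        gt, pred = random_instance(rng)
        squeezed = [
            BoxRecord(p.x_start, p.y_start, p.x_extent, p.y_extent,
                      slice_index=p.slice_index, score=p.score**3)
            for p in pred
        ]
        assert pr_curve(gt, pred).average_precision == pytest.approx(
            pr_curve(gt, squeezed).average_precision, abs=1e-12
        )

    def test_11_point_close_to_all_points_for_perfect_ranking(self):
        gt = [BoxRecord(i * 20, 0, 10, 10, slice_index=0) for i in range(4)]
        pred = [
            BoxRecord(b.x_start, b.y_start, b.x_extent, b.y_extent,
                      slice_index=0, score=0.9 - 0.1 * i)
            for i, b in enumerate(gt)
        ]
        assert pr_curve(gt, pred, interpolation="11_point").average_precision == 1.0


def test_metrics_agree_with_brute_force_oracles(rng):
    """iou/match/pr_curve vs pixel counting, greedy re-run and threshold
    enumeration on seeded random instances."""
    for _ in range(40):
        gt, pred = random_instance(rng)
        counts, ious = match(gt, pred)
        (tp, fp, fn), oracle_ious = brute_match(gt, pred)
        assert (counts.tp, counts.fp, counts.fn) == (tp, fp, fn)
        np.testing.assert_allclose(ious, oracle_ious, atol=1e-9)
        ap = pr_curve(gt, pred).average_precision
        assert ap == pytest.approx(brute_ap(gt, pred), abs=1e-9)


class TestIoUStats:
    def test_two_values(self):
        stats = iou_stats([0.5, 0.7])
        assert stats.mean == pytest.approx(0.6)
        assert stats.sd == pytest.approx(0.1414213562, abs=1e-9)

    def test_single_value_warns_sd_zero(self):
        with pytest.warns(UserWarning, match="n=1"):
            stats = iou_stats([0.8])
        assert stats.mean == 0.8
        assert stats.sd == 0.0

    def test_equal_values_sd_zero(self):
        assert iou_stats([0.6, 0.6, 0.6]).sd == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            iou_stats([])
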