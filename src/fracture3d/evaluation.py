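"""Detection evaluation: IoU, greedy matching, PR curves, average precision.

Per-slice detections are scored boxes; ground truth is unscored.  The
matcher follows the conventional detection protocol: predictions are
visited in descending score order and each claims the still-unmatched
ground-truth box of highest IoU, provided that IoU reaches the ``iou_min``
floor (default 0.5, the usual compliance threshold).  Unclaimed
predictions are false positives, unclaimed ground truths false negatives.
True negatives are tracked for completeness but are undefined for box
detection and enter no metric, exactly as the precision/recall
definitions tp/(tp+fp) and tp/(tp+fn) require.

Average precision is the area under the monotone precision envelope over
recall (all-points interpolation) by default, with the 11-point variant
available, since published AP numbers do not always say which was used.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from fracture3d.annotation import BoxRecord

logger = logging.getLogger(__name__)

IOU_MIN_DEFAULT = 0.5


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0  # tracked only for completeness; no detection metric uses it

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class PRCurve:
    """Threshold-swept precision/recall points and their AP summary."""

    thresholds: list[float]
    precisions: list[float]
    recalls: list[float]
    average_precision: float

    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.recalls, self.precisions))


@dataclass
class IoUStats:
    ious: list[float]
    mean: float
    sd: float


def iou(a: BoxRecord, b: BoxRecord) -> float:
    """Intersection over union of two boxes under the half-open convention.

    Areas are covered-pixel counts, so extents multiply exactly.
    """
    if a.x_extent < 1 or a.y_extent < 1 or b.x_extent < 1 or b.y_extent < 1:
        raise ValueError("zero-extent box")
    ix = max(0, min(a.x_end, b.x_end) - max(a.x_start, b.x_start))
    iy = max(0, min(a.y_end, b.y_end) - max(a.y_start, b.y_start))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def _sorted_preds(pred: list[BoxRecord]) -> list[BoxRecord]:
    """Descending score with a deterministic tie-break on geometry."""
    return sorted(
        pred,
        key=lambda p: (
            -(p.score if p.score is not None else 1.0),
            p.slice_index,
            p.x_start,
            p.y_start,
            p.x_extent,
            p.y_extent,
        ),
    )


def match(
    gt: list[BoxRecord],
    pred: list[BoxRecord],
    iou_min: float = IOU_MIN_DEFAULT,
) -> tuple[ConfusionCounts, list[float]]:
    """Greedy one-to-one matching of predictions to ground truth per slice.

    Returns the confusion counts and the IoU of each matched pair (in the
    order predictions claimed them).
    """
    order = _sorted_preds(pred)
    gt_by_slice: dict[int, list[int]] = {}
    for i, g in enumerate(gt):
        gt_by_slice.setdefault(g.slice_index, []).append(i)
    claimed = set()
    matched_ious: list[float] = []
    tp = fp = 0
    for p in order:
        best_i = -1
        best_iou = 0.0
        for i in gt_by_slice.get(p.slice_index, []):
            if i in claimed:
                continue
            v = iou(gt[i], p)
            if v > best_iou:
                best_iou = v
                best_i = i
        if best_i >= 0 and best_iou >= iou_min:
            claimed.add(best_i)
            matched_ious.append(best_iou)
            tp += 1
        else:
            fp += 1
    fn = len(gt) - len(claimed)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn), matched_ious


def precision(c: ConfusionCounts) -> float:
    """tp / (tp + fp); with no predictions at all, 1.0 by convention."""
    if c.tp + c.fp == 0:
        logger.info("precision: no predictions, returning 1.0 by convention")
        return 1.0
    return c.tp / (c.tp + c.fp)


def recall(c: ConfusionCounts) -> float:
    """tp / (tp + fn); with no ground truth, 1.0 by convention."""
    if c.tp + c.fn == 0:
        logger.info("recall: no ground truth, returning 1.0 by convention")
        return 1.0
    return c.tp / (c.tp + c.fn)


def _ap_all_points(recalls: np.ndarray, precisions: np.ndarray) -> float:
    """Area under the monotone precision envelope over recall."""
    r = np.concatenate([[0.0], recalls, [recalls[-1] if len(recalls) else 0.0]])
    p = np.concatenate([[1.0], precisions, [0.0]])
    # envelope: precision at recall x is the max precision at recall >= x
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    ap = 0.0
    for i in range(1, len(r)):
        ap += (r[i] - r[i - 1]) * p[i]
    return float(ap)


def _ap_11_point(recalls: np.ndarray, precisions: np.ndarray) -> float:
    values = []
    for t in np.linspace(0.0, 1.0, 11):
        mask = recalls >= t - 1e-12
        values.append(precisions[mask].max() if mask.any() else 0.0)
    return float(np.mean(values))


def pr_curve(
    gt: list[BoxRecord],
    pred: list[BoxRecord],
    iou_min: float = IOU_MIN_DEFAULT,
    interpolation: str = "all_points",
) -> PRCurve:
    """Sweep the score threshold over all distinct scores, descending.

    At each threshold the greedy matcher runs on the predictions at or
    above it; because matching is greedy in score order, lowering the
    threshold never changes earlier assignments, so the sweep is computed
    cumulatively.  ``interpolation`` selects the AP definition
    ("all_points" or "11_point").
    """
    if interpolation not in ("all_points", "11_point"):
        raise ValueError(f"unknown AP interpolation {interpolation!r}")
    n_gt = len(gt)
    if not pred:
        return PRCurve(
            thresholds=[], precisions=[], recalls=[0.0], average_precision=0.0
        )
    order = _sorted_preds(pred)
    gt_by_slice: dict[int, list[int]] = {}
    for i, g in enumerate(gt):
        gt_by_slice.setdefault(g.slice_index, []).append(i)
    claimed: set[int] = set()
    is_tp = np.zeros(len(order), dtype=bool)
    for j, p in enumerate(order):
        best_i, best_iou = -1, 0.0
        for i in gt_by_slice.get(p.slice_index, []):
            if i in claimed:
                continue
            v = iou(gt[i], p)
            if v > best_iou:
                best_iou, best_i = v, i
        if best_i >= 0 and best_iou >= iou_min:
            claimed.add(best_i)
            is_tp[j] = True

    scores = np.array([p.score if p.score is not None else 1.0 for p in order])
    tp_cum = np.cumsum(is_tp)
    fp_cum = np.cumsum(~is_tp)
    # one PR point per distinct score: the last (cumulative) entry at that score
    keep = np.ones(len(order), dtype=bool)
    keep[:-1] = scores[1:] != scores[:-1]
    precisions = tp_cum / (tp_cum + fp_cum)
    recalls = tp_cum / n_gt if n_gt else np.ones_like(tp_cum, dtype=float)
    thresholds = scores[keep]
    precisions = precisions[keep]
    recalls = recalls[keep]

    if interpolation == "all_points":
        ap = _ap_all_points(recalls, precisions)
    else:
        ap = _ap_11_point(recalls, precisions)
    return PRCurve(
        thresholds=[float(t) for t in thresholds],
        precisions=[float(p) for p in precisions],
        recalls=[float(r) for r in recalls],
        average_precision=ap,
    )


def iou_stats(matched_ious: list[float]) -> IoUStats:
    """Sample mean and sample (n−1) standard deviation of matched IoUs.

    A single observation has no sample SD; it is reported as 0 with a
    warning so small runs do not abort.
    """
    if not matched_ious:
        raise ValueError("iou_stats requires at least one matched pair")
    arr = np.asarray(matched_ious, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("IoU values must lie in [0, 1]")
    mean = float(arr.mean())
    if len(arr) == 1:
        warnings.warn("iou_stats: sample SD undefined for n=1, reporting 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(arr.std(ddof=1))
    return IoUStats(ious=[float(v) for v in arr], mean=mean, sd=sd)


def plot_pr_curve(curve: PRCurve, path) -> None:
    """Save the PR curve as an image (format from the extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    r = [0.0] + curve.recalls
    p = [1.0] + (curve.precisions if curve.precisions else [0.0] * (len(curve.recalls)))
    ax.step(r, p, where="post")
    ax.set_xlabel("Recall")
    ax.set_ylabel("Precision")
    ax.set_xlim(0, 1.02)
    ax.set_ylim(0, 1.02)
    ax.set_title(f"AP = {curve.average_precision:.3f}")
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)


def metrics_report(
    counts: ConfusionCounts,
    curve: PRCurve,
    stats: IoUStats | None,
) -> dict:
    """JSON-serializable metrics bundle (counts, PR table, AP, IoU stats)."""
    report = {
        "counts": {"tp": counts.tp, "fp": counts.fp, "fn": counts.fn},
        "precision": precision(counts),
        "recall": recall(counts),
        "pr_curve": {
            "thresholds": curve.thresholds,
            "precisions": curve.precisions,
            "recalls": curve.recalls,
        },
        "average_precision": curve.average_precision,
    }
    if stats is not None:
        report["iou"] = {"mean": stats.mean, "sd": stats.sd, "n": len(stats.ious)}
    return report
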