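"""Detection evaluation: precision, recall, AP, mAP, and F1.

With TP the correctly detected objects, FP the misidentifications, and FN
the missed objects:

    P  = TP / (TP + FP)
    R  = TP / (TP + FN)
    F1 = 2 TP / (2 TP + FP + FN)     (the harmonic mean of P and R)
    AP = area under the precision-recall curve
    mAP = mean AP over classes

A prediction counts as a true positive when it can be matched one-to-one to
a ground-truth box with IOU at or above ``iou_min`` (default 0.5, the common
detection-benchmark criterion).  Matching is greedy by descending IOU, ties
broken by higher confidence then lower prediction index.  AP uses all-points
interpolation: precision at recall r is the maximum precision attained at
any recall >= r, and the integral is taken exactly over that step function.
"""

from __future__ import annotations

from dataclasses import dataclass

from .boxes import Box, Detection, iou
from .errors import InvalidInputError

__all__ = [
    "MatchOutcome",
    "PRCurve",
    "match",
    "precision",
    "recall",
    "f1",
    "pr_curve",
    "average_precision",
    "mean_ap",
]

DEFAULT_IOU_MIN = 0.5


@dataclass(frozen=True)
class MatchOutcome:
    tp: int
    fp: int
    fn: int
    matched_pairs: list[tuple[int, int, float]]  # (prediction idx, truth idx, IOU)


@dataclass(frozen=True)
class PRCurve:
    """Cumulative (recall, precision) points along a confidence ranking."""

    points: list[tuple[float, float]]

    def __post_init__(self) -> None:
        recalls = [r for r, _p in self.points]
        if recalls != sorted(recalls):
            raise InvalidInputError("recalls must be non-decreasing along the ranking")
        for r, p in self.points:
            if not (0.0 <= r <= 1.0 and 0.0 <= p <= 1.0):
                raise InvalidInputError(f"point ({r}, {p}) outside the unit square")


def match(
    predictions: list[Detection], truths: list[Box], iou_min: float = DEFAULT_IOU_MIN
) -> MatchOutcome:
    """One-to-one greedy matching of predictions to ground-truth boxes."""
    candidates = [
        (iou(pred.box, truth), pi, ti)
        for pi, pred in enumerate(predictions)
        for ti, truth in enumerate(truths)
    ]
    candidates = [c for c in candidates if c[0] >= iou_min]
    candidates.sort(key=lambda c: (-c[0], -predictions[c[1]].confidence, c[1], c[2]))
    used_pred: set[int] = set()
    used_truth: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for v, pi, ti in candidates:
        if pi in used_pred or ti in used_truth:
            continue
        used_pred.add(pi)
        used_truth.add(ti)
        pairs.append((pi, ti, v))
    tp = len(pairs)
    return MatchOutcome(tp=tp, fp=len(predictions) - tp, fn=len(truths) - tp, matched_pairs=pairs)


def _check_counts(*counts: int) -> None:
    if any(c < 0 for c in counts):
        raise InvalidInputError(f"counts must be non-negative, got {counts}")


def precision(tp: int, fp: int) -> float:
    _check_counts(tp, fp)
    return tp / (tp + fp) if tp + fp else 0.0


def recall(tp: int, fn: int) -> float:
    _check_counts(tp, fn)
    return tp / (tp + fn) if tp + fn else 0.0


def f1(tp: int, fp: int, fn: int) -> float:
    _check_counts(tp, fp, fn)
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def pr_curve(
    predictions: list[Detection], truths: list[Box], iou_min: float = DEFAULT_IOU_MIN
) -> PRCurve:
    """Walk the confidence ranking, recording cumulative recall and precision.

    Each prediction, taken in descending confidence order, greedily claims
    the still-unmatched truth of maximal IOU (if any reaches ``iou_min``).
    """
    if not truths:
        raise InvalidInputError("pr_curve undefined without ground-truth boxes")
    order = sorted(range(len(predictions)), key=lambda i: (-predictions[i].confidence, i))
    matched_truth: set[int] = set()
    tp = 0
    points: list[tuple[float, float]] = []
    for rank, pi in enumerate(order, start=1):
        best_ti, best_iou = -1, 0.0
        for ti, truth in enumerate(truths):
            if ti in matched_truth:
                continue
            v = iou(predictions[pi].box, truth)
            if v >= iou_min and v > best_iou:
                best_ti, best_iou = ti, v
        if best_ti >= 0:
            matched_truth.add(best_ti)
            tp += 1
        points.append((tp / len(truths), tp / rank))
    return PRCurve(points)


def average_precision(curve: PRCurve) -> float:
    """Exact area under the all-points-interpolated precision envelope.

    The interpolated precision at recall r is the maximum precision over
    curve points with recall >= r; beyond the maximum recall it is 0.  The
    step function is integrated exactly over its breakpoints.
    """
    if not curve.points:
        raise InvalidInputError("average_precision needs a non-empty curve")
    # envelope precision at each distinct recall level, scanning right to left
    pts = sorted(curve.points)
    recalls: list[float] = []
    env: list[float] = []
    best = 0.0
    for r, p in reversed(pts):
        best = max(best, p)
        if recalls and recalls[-1] == r:
            env[-1] = best
        else:
            recalls.append(r)
            env.append(best)
    recalls.reverse()
    env.reverse()
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(recalls, env):
        ap += (r - prev_r) * p
        prev_r = r
    return ap


def mean_ap(aps: list[float]) -> float:
    """Arithmetic mean of per-class APs."""
    if not aps:
        raise InvalidInputError("mean_ap needs at least one AP value")
    return sum(aps) / len(aps)
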