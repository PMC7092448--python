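"""Imbalance-aware evaluation metrics.

Labels follow the convention used throughout the package: the minority class
is positive (+1) and the majority negative (-1).  Besides the usual confusion
rates, this module implements ROC / precision-recall curves under the strict
``score > threshold`` prediction rule and a *lower trapezoidal* area rule
over distinct FPR values F_1 < ... < F_K: where several curve points share an
FPR (vertical runs), the segment to the next FPR links this group's departure
point to the next group's arrival point,

    AUCROC = sum_k 0.5 * (T_k_departure + T_{k+1}_arrival) * (F_{k+1} - F_k)

which reproduces the empirical staircase (= pair-counting Mann-Whitney AUC)
on tie-free scores and interpolates tied jumps conservatively, never
exceeding the pair-counting value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError

__all__ = [
    "ConfusionCounts",
    "RocCurve",
    "PrCurve",
    "confusion",
    "rates",
    "roc_points",
    "auc_roc_lower_trapezoid",
    "pr_points",
    "auc_prc",
]


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    bad = set(np.unique(y)) - {-1, 1}
    if bad:
        raise InvalidInputError(f"labels must be in {{-1,+1}}, found {sorted(bad)}")
    return y


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class RocCurve:
    """Ordered (fpr, tpr) points, one per distinct threshold, plus endpoints."""

    points: list = field(default_factory=list)
    thresholds: list = field(default_factory=list)

    @property
    def fpr(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def tpr(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


@dataclass(frozen=True)
class PrCurve:
    """Ordered (recall, precision) points, one per distinct threshold."""

    points: list = field(default_factory=list)
    thresholds: list = field(default_factory=list)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Confusion counts with the minority (+1) treated as positive."""
    y_true = _check_binary(y_true)
    y_pred = _check_binary(y_pred)
    if y_true.shape != y_pred.shape:
        raise InvalidInputError(
            f"length mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    pos = y_true == 1
    pred_pos = y_pred == 1
    return ConfusionCounts(
        tp=int(np.sum(pos & pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
    )


def _safe_div(num: float, den: float) -> float:
    # 0/0 convention: return 0 (conservative; keeps the all-negative
    # classifier well-defined).
    return num / den if den > 0 else 0.0


def rates(c: ConfusionCounts) -> dict:
    """TPR, TNR, FPR, precision, G-mean and F-measure from counts."""
    tpr = _safe_div(c.tp, c.tp + c.fn)
    tnr = _safe_div(c.tn, c.tn + c.fp)
    fpr = _safe_div(c.fp, c.fp + c.tn)
    precision = _safe_div(c.tp, c.tp + c.fp)
    f_measure = _safe_div(2.0 * precision * tpr, precision + tpr)
    return {
        "tpr": tpr,
        "tnr": tnr,
        "fpr": fpr,
        "precision": precision,
        "g_mean": math.sqrt(tpr * tnr),
        "f_measure": f_measure,
    }


def _threshold_counts(scores: np.ndarray, y: np.ndarray):
    """Cumulative TP/FP counts per distinct threshold under the ``>`` rule.

    Returns (thresholds, tp, fp) where thresholds runs from +inf down through
    every distinct score; at threshold c a sample is predicted positive iff
    its score is strictly greater than c.
    """
    scores = np.asarray(scores, dtype=float)
    y = _check_binary(y)
    if scores.shape != y.shape:
        raise InvalidInputError("scores and labels must have the same length")
    if not np.isfinite(scores).all():
        raise InvalidInputError("non-finite scores")
    if len(np.unique(y)) < 2:
        raise InvalidInputError("both classes must be present")

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    pos_sorted = (y[order] == 1).astype(np.int64)

    # last index of each distinct score value in the descending order
    distinct_mask = np.ones(len(s_sorted), dtype=bool)
    distinct_mask[:-1] = s_sorted[:-1] != s_sorted[1:]
    idx = np.flatnonzero(distinct_mask)

    cum_tp = np.cumsum(pos_sorted)
    cum_fp = np.cumsum(1 - pos_sorted)

    thresholds = np.concatenate(([np.inf], s_sorted[idx]))
    tp = np.concatenate(([0], cum_tp[idx]))
    fp = np.concatenate(([0], cum_fp[idx]))
    return thresholds, tp, fp


def roc_points(scores, y) -> RocCurve:
    """ROC curve: one (fpr, tpr) point per distinct threshold.

    Predicting positive means ``score > c``; thresholds run from +inf (nothing
    positive, the (0,0) point) down to the minimum score (everything positive,
    the (1,1) point).
    """
    thresholds, tp, fp = _threshold_counts(scores, y)
    n_pos = tp[-1]
    n_neg = fp[-1]
    pts = list(zip((fp / n_neg).tolist(), (tp / n_pos).tolist()))
    return RocCurve(points=pts, thresholds=thresholds.tolist())


def _lower_trapezoid(x: np.ndarray, y: np.ndarray) -> float:
    """Area under sweep-ordered curve points, grouped by distinct x.

    Points must be in threshold-sweep order (x non-decreasing).  Where
    several points share an x value (vertical runs produced by consecutive
    same-class thresholds or score ties), the segment to the next x links the
    *departure* point of this group (last in sweep order) to the *arrival*
    point of the next group (first in sweep order) and contributes
    ``0.5 * (y_dep_k + y_arr_{k+1}) * (x_{k+1} - x_k)``.  On tie-free score
    data this reproduces the empirical staircase exactly (= pair-counting
    AUC); under ties it linearly interpolates the jump, never exceeding the
    pair-counting value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        return 0.0
    if np.any(np.diff(x) < 0):
        raise InvalidInputError("curve points must be in sweep order")
    # first (arrival) and last (departure) index of each distinct x
    first = np.ones(x.size, dtype=bool)
    first[1:] = x[1:] != x[:-1]
    starts = np.flatnonzero(first)
    ends = np.append(starts[1:] - 1, x.size - 1)
    xs = x[starts]
    if xs.size < 2:
        return 0.0
    y_arr = y[starts]
    y_dep = y[ends]
    return float(np.sum(0.5 * (y_dep[:-1] + y_arr[1:]) * np.diff(xs)))


def auc_roc_lower_trapezoid(scores, y) -> float:
    """Area under the ROC curve by the lower trapezoidal rule, in [0, 1]."""
    curve = roc_points(scores, y)
    return _lower_trapezoid(curve.fpr, curve.tpr)


def pr_points(scores, y) -> PrCurve:
    """Precision-recall curve, one (recall, precision) point per threshold.

    Thresholds where nothing is predicted positive are replaced by a single
    recall-0 anchor whose precision continues the first non-empty threshold's
    precision (so a constant-score input yields the flat prevalence line and a
    perfect ranking yields precision 1 throughout).
    """
    thresholds, tp, fp = _threshold_counts(scores, y)
    n_pos = tp[-1]
    pred_pos = tp + fp
    keep = pred_pos > 0
    recall = tp[keep] / n_pos
    precision = tp[keep] / pred_pos[keep]
    thr = np.asarray(thresholds)[keep]
    pts = [(0.0, float(precision[0]))]
    pts += list(zip(recall.tolist(), precision.tolist()))
    return PrCurve(points=pts, thresholds=[np.inf] + thr.tolist())


def auc_prc(scores, y) -> float:
    """Area under the PR curve by the same lower trapezoidal rule."""
    curve = pr_points(scores, y)
    rec = np.array([p[0] for p in curve.points])
    prec = np.array([p[1] for p in curve.points])
    return _lower_trapezoid(rec, prec)
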