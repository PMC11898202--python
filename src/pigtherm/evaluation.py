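"""Evaluation metrics: oriented-box detection, pairing accuracy, and
temperature agreement.

Detection quality uses precision ``P = TP/(TP+FP)``, recall
``R = TP/(TP+FN)`` and mean average precision (area under the
precision-recall envelope per class, averaged over classes) with a
rotated-IoU matching criterion.  True negatives are not applicable to
detection and are reported as such.

Pairing quality is the fraction of predicted pairs that are correct,
``A = Pc / Pt``.

Temperature agreement between predicted and reference values combines
the Pearson correlation coefficient with a measurement-system bias
analysis: per-sample bias ``x_i - y_i``, its mean, standard deviation,
and 95% confidence interval; the bias is acceptable when 0 lies inside
the interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .geometry import EarSide, OrientedBox, boxes_equal, rotated_iou
from .io import LabelSet
from .pairing import EarPair

__all__ = [
    "ClassMatches",
    "ClassStats",
    "DetectionEvalReport",
    "PairingReport",
    "AgreementReport",
    "ZeroVarianceError",
    "match_detections",
    "precision_recall",
    "average_precision",
    "mean_ap",
    "evaluate_detections",
    "pairing_accuracy",
    "count_correct_pairs",
    "pearson_r",
    "bias_analysis",
]


class ZeroVarianceError(ValueError):
    """Correlation is undefined because one input has zero variance."""


@dataclass
class ClassMatches:
    """Ranked match flags for one class: confidence-ordered TP/FP + truth count."""

    flags: list[bool]
    n_truth: int

    @property
    def tp(self) -> int:
        return sum(self.flags)

    @property
    def fp(self) -> int:
        return len(self.flags) - self.tp

    @property
    def fn(self) -> int:
        return self.n_truth - self.tp


def _as_framesets(x: LabelSet | Sequence[LabelSet]) -> list[LabelSet]:
    if isinstance(x, LabelSet):
        return [x]
    return list(x)


def match_detections(preds: LabelSet | Sequence[LabelSet],
                     truths: LabelSet | Sequence[LabelSet],
                     iou_threshold: float = 0.5) -> dict[EarSide, ClassMatches]:
    """Assign predictions to ground-truth boxes per class.

    Within each frame and class, predictions are taken in order of
    descending confidence (missing confidence ranks last; ties keep file
    order) and matched to the unmatched same-class truth box of highest
    rotated IoU at or above `iou_threshold`.  Matched predictions are
    true positives, unmatched predictions false positives, and unmatched
    truths false negatives.
    """
    pred_sets, truth_sets = _as_framesets(preds), _as_framesets(truths)
    if len(pred_sets) != len(truth_sets):
        raise ValueError("prediction and truth frame lists differ in length")
    out = {side: ClassMatches(flags=[], n_truth=0) for side in EarSide}
    ranked: dict[EarSide, list[tuple[float, int, bool]]] = {side: [] for side in EarSide}
    for f, (pset, tset) in enumerate(zip(pred_sets, truth_sets)):
        for side in EarSide:
            truth_boxes = [b for b in tset.boxes if b.label == side]
            out[side].n_truth += len(truth_boxes)
            preds_side = [(i, b) for i, b in enumerate(pset.boxes) if b.label == side]
            preds_side.sort(key=lambda ib: (-(ib[1].confidence if ib[1].confidence is not None else -1.0), ib[0]))
            taken = [False] * len(truth_boxes)
            for order, (i, pbox) in enumerate(preds_side):
                best_iou, best_k = 0.0, -1
                for k, tbox in enumerate(truth_boxes):
                    if taken[k]:
                        continue
                    iou = rotated_iou(pbox, tbox)
                    if iou > best_iou:
                        best_iou, best_k = iou, k
                conf = pbox.confidence if pbox.confidence is not None else -1.0
                is_tp = best_iou >= iou_threshold and best_k >= 0
                if is_tp:
                    taken[best_k] = True
                ranked[side].append((conf, f * 10_000 + order, is_tp))
    for side in EarSide:
        ranked[side].sort(key=lambda t: (-t[0], t[1]))
        out[side].flags = [is_tp for _, _, is_tp in ranked[side]]
    return out


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float | None, float | None]:
    """Precision and recall from counts.

    Degenerate conventions: with no predictions (TP+FP = 0) precision is
    reported as 1.0 (no false claim was made); with no positives
    (TP+FN = 0) recall is undefined and reported as None.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = tp / (tp + fp) if (tp + fp) > 0 else 1.0
    r = tp / (tp + fn) if (tp + fn) > 0 else None
    return p, r


def average_precision(flags: Sequence[bool], n_truth: int) -> float:
    """All-point interpolated area under the precision-recall envelope.

    `flags` are TP/FP indicators ranked by descending confidence;
    `n_truth` is the number of ground-truth positives of the class.
    """
    if n_truth <= 0:
        raise ValueError("average precision undefined with zero ground-truth positives")
    if len(flags) == 0:
        return 0.0
    tp_cum = np.cumsum(np.asarray(flags, dtype=float))
    recall = tp_cum / n_truth
    precision = tp_cum / np.arange(1, len(flags) + 1)
    # precision envelope (running max from the right), all-point interpolation
    env = np.maximum.accumulate(precision[::-1])[::-1]
    recall = np.concatenate([[0.0], recall])
    env = np.concatenate([[env[0] if len(env) else 0.0], env])
    return float(np.sum((recall[1:] - recall[:-1]) * env[1:]))


def mean_ap(per_class_ap: Iterable[float]) -> float:
    """Unweighted mean of per-class average precisions."""
    values = list(per_class_ap)
    if not values:
        raise ValueError("no class AP values to average")
    return float(np.mean(values))


@dataclass
class ClassStats:
    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None
    ap: float | None
    precision_degenerate: bool = False


@dataclass
class DetectionEvalReport:
    """Detection metrics at a fixed rotated-IoU threshold.

    ``tn`` is always None: true negatives are not defined for detection.
    Classes with no ground-truth positives are excluded from the mAP with
    a warning.
    """

    per_class: dict[EarSide, ClassStats]
    map_: float | None
    iou_threshold: float
    n_classes: int
    tn: None = None

    def to_dict(self) -> dict:
        return {
            "iou_threshold": self.iou_threshold,
            "mAP": self.map_,
            "tn": "not applicable",
            "classes": {
                side.name.lower(): {
                    "tp": s.tp, "fp": s.fp, "fn": s.fn,
                    "precision": s.precision, "recall": s.recall, "ap": s.ap,
                }
                for side, s in self.per_class.items()
            },
        }


def evaluate_detections(preds: LabelSet | Sequence[LabelSet],
                        truths: LabelSet | Sequence[LabelSet],
                        iou_threshold: float = 0.5) -> DetectionEvalReport:
    """Full detection evaluation: match, per-class P/R/AP, and mAP."""
    matches = match_detections(preds, truths, iou_threshold)
    per_class: dict[EarSide, ClassStats] = {}
    aps = []
    for side, m in matches.items():
        p, r = precision_recall(m.tp, m.fp, m.fn)
        if m.n_truth > 0:
            ap = average_precision(m.flags, m.n_truth)
            aps.append(ap)
        else:
            ap = None
            warnings.warn(f"class {side.name}: no ground-truth positives, excluded from mAP")
        per_class[side] = ClassStats(tp=m.tp, fp=m.fp, fn=m.fn, precision=p,
                                     recall=r, ap=ap,
                                     precision_degenerate=(m.tp + m.fp == 0))
    map_ = mean_ap(aps) if aps else None
    return DetectionEvalReport(per_class=per_class, map_=map_,
                               iou_threshold=iou_threshold, n_classes=len(EarSide))


@dataclass(frozen=True)
class PairingReport:
    """Pairing accuracy A = Pc / Pt."""

    correct: int
    total: int
    accuracy: float


def pairing_accuracy(correct: int, total: int) -> PairingReport:
    """Accuracy of left/right ear-root pairing from counts."""
    if total <= 0:
        raise ValueError("total pair count must be positive")
    if not 0 <= correct <= total:
        raise ValueError(f"need 0 <= correct <= total, got ({correct}, {total})")
    return PairingReport(correct=correct, total=total, accuracy=correct / total)


def count_correct_pairs(pairs: Sequence[EarPair],
                        true_pairs: Sequence[tuple[OrientedBox, OrientedBox]],
                        tol: float = 1e-6) -> int:
    """Number of predicted pairs matching a ground-truth (left, right) pair.

    A pair is correct when both of its boxes coincide geometrically with
    the same pig's boxes *and* the left/right slots match that pig's
    anatomy.
    """
    n = 0
    for pair in pairs:
        for t_left, t_right in true_pairs:
            if boxes_equal(pair.left, t_left, tol) and boxes_equal(pair.right, t_right, tol):
                n += 1
                break
    return n


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient between paired samples.

    Raises
    ------
    ZeroVarianceError
        If either input is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class AgreementReport:
    """Measurement-system agreement between predicted and reference values.

    The verdict is ``acceptable`` exactly when 0 lies within the
    ``(1 - alpha)`` confidence interval of the mean bias.
    """

    n: int
    r: float | None
    biases: np.ndarray
    mean_bias: float
    sd: float
    ci: tuple[float, float]
    p_value: float
    alpha: float
    acceptable: bool


def bias_analysis(predicted: Sequence[float], reference: Sequence[float],
                  alpha: float = 0.05) -> AgreementReport:
    """Bias (predicted minus reference) with confidence interval and t-test.

    The confidence interval is ``mean +- t(1 - alpha/2, n-1) * sd / sqrt(n)``
    with the sample standard deviation (n-1 denominator); the p-value is
    the two-sided one-sample t-test of zero mean bias.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("predicted and reference must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired samples")
    biases = x - y
    mean = float(biases.mean())
    sd = float(biases.std(ddof=1))
    if sd == 0.0:
        ci = (mean, mean)
        p = 1.0 if mean == 0.0 else 0.0
    else:
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, n - 1)
        half = tcrit * sd / np.sqrt(n)
        ci = (mean - half, mean + half)
        p = float(stats.ttest_1samp(biases, 0.0).pvalue)
    try:
        r = pearson_r(x, y)
    except ZeroVarianceError:
        r = None
    return AgreementReport(n=n, r=r, biases=biases, mean_bias=mean, sd=sd,
                           ci=ci, p_value=p, alpha=alpha,
                           acceptable=(ci[0] <= 0.0 <= ci[1]))
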