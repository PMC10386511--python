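"""Classification metrics and the manual-vs-automatic comparison.

Unit-level classification is summarized by a confusion matrix (rows =
true class, columns = predicted class) from which accuracy and one-vs-
rest precision / recall / F1 are derived:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)   (= trace / total)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

Ethogram comparison against a manual annotation counts how many
manually recorded behaviors the automatic ethogram reproduced: a manual
interval is matched when an unmatched predicted interval has the same
label, overlaps it, and deviates by at most ``tolerance_frames``
(default 25) at both boundaries. The per-video *difference degree* is
100 * (n_manual - n_matched) / n_manual, truncated (not rounded) to two
decimals — the convention that reproduces every row of the published
comparison table.
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction
import math

import numpy as np


@dataclasses.dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    #: True when the class was never predicted (precision reported as 0)
    no_predictions: bool = False


@dataclasses.dataclass(frozen=True)
class ComparisonResult:
    video_id: str
    n_manual: int
    n_matched: int
    difference_degree: float

    def __post_init__(self):
        if not 0 <= self.n_matched <= self.n_manual:
            raise ValueError("n_matched must be in [0, n_manual]")


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    y_true = np.asarray(y_true, dtype=np.intp)
    y_pred = np.asarray(y_pred, dtype=np.intp)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must align")
    if len(y_true) == 0:
        raise ValueError("no samples")
    if (y_true.min() < 0 or y_true.max() >= n_classes
            or y_pred.min() < 0 or y_pred.max() >= n_classes):
        raise ValueError("labels out of range")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def accuracy(cm: np.ndarray) -> float:
    """Correct predictions over all predictions: trace / total."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm) / total)


def per_class_metrics(cm: np.ndarray) -> list[ClassMetrics]:
    """One-vs-rest precision/recall/F1 per class.

    A class that is never predicted gets precision 0 with the
    ``no_predictions`` flag set; a zero denominator anywhere yields 0
    for that metric.
    """
    cm = np.asarray(cm)
    if cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    out = []
    for k in range(cm.shape[0]):
        tp = int(cm[k, k])
        fp = int(cm[:, k].sum() - tp)
        fn = int(cm[k, :].sum() - tp)
        predicted = tp + fp
        precision = tp / predicted if predicted else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        out.append(ClassMetrics(precision, recall, f1,
                                no_predictions=predicted == 0))
    return out


def _check_sorted(intervals, name):
    prev_end = None
    for iv in intervals:
        if prev_end is not None and iv.start_frame <= prev_end:
            raise ValueError(f"{name} ethogram is unsorted or overlapping "
                             f"near frame {iv.start_frame}")
        prev_end = iv.end_frame


def match_intervals(predicted, manual, tolerance_frames: int = 25) -> int:
    """Count manual intervals reproduced by the predicted ethogram.

    Greedy in temporal order with one-to-one consumption: each manual
    interval takes the first unmatched predicted interval that has the
    same behavior label, overlaps it in time, and whose start and end
    both deviate by at most ``tolerance_frames``.
    """
    _check_sorted(predicted, "predicted")
    _check_sorted(manual, "manual")
    used = [False] * len(predicted)
    n_matched = 0
    for man in manual:
        for i, pred in enumerate(predicted):
            if used[i] or pred.behavior != man.behavior:
                continue
            overlaps = (pred.start_frame <= man.end_frame
                        and man.start_frame <= pred.end_frame)
            close = (abs(pred.start_frame - man.start_frame)
                     <= tolerance_frames
                     and abs(pred.end_frame - man.end_frame)
                     <= tolerance_frames)
            if overlaps and close:
                used[i] = True
                n_matched += 1
                break
    return n_matched


def difference_degree(n_manual: int, n_matched: int) -> float:
    """Percent of manually recorded behaviors the method missed,
    truncated to two decimals (13.888... reports as 13.88)."""
    if n_manual <= 0:
        raise ValueError("n_manual must be positive")
    if not 0 <= n_matched <= n_manual:
        raise ValueError("n_matched must be in [0, n_manual]")
    return math.floor(Fraction(10000 * (n_manual - n_matched), n_manual)) / 100


def compare_ethograms(video_id, predicted, manual,
                      tolerance_frames: int = 25) -> ComparisonResult:
    n_matched = match_intervals(predicted, manual, tolerance_frames)
    return ComparisonResult(str(video_id), len(manual), n_matched,
                            difference_degree(len(manual), n_matched))


def comparison_report(results: list[ComparisonResult]) -> dict:
    """Summary over videos: mean counts to one decimal, mean of the
    *untruncated* per-video difference ratios to two decimals."""
    if not results:
        raise ValueError("no comparison results")
    mean_manual = np.mean([r.n_manual for r in results])
    mean_matched = np.mean([r.n_matched for r in results])
    mean_diff = np.mean([100.0 * (r.n_manual - r.n_matched) / r.n_manual
                         for r in results])
    return {
        "n_videos": len(results),
        "mean_n_manual": round(float(mean_manual), 1),
        "mean_n_matched": round(float(mean_matched), 1),
        "mean_difference_degree": round(float(mean_diff), 2),
    }
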