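"""Multi-label evaluation: contingency counts, macro/micro averages, ROC.

Conventions: an undefined ratio (0/0) contributes 0.  Similarity is the
Jaccard-style overlap TP/(TP+FP+FN); the macro variant averages it per
class, the micro variant computes it once from pooled counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ClassCounts",
    "class_counts",
    "macro_metrics",
    "micro_metrics",
    "roc_curve",
]


@dataclass
class ClassCounts:
    labels: list[str]
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def n_documents(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0]) if len(self.labels) else 0


def class_counts(
    predicted: Sequence[set[str]],
    gold: Sequence[set[str]],
    label_vocabulary: Sequence[str],
) -> ClassCounts:
    """Per-class TP/FP/FN/TN over equal-length prediction/gold sequences."""
    if len(predicted) != len(gold):
        raise ValueError("predicted and gold sequences differ in length")
    vocab = list(label_vocabulary)
    index = {lab: i for i, lab in enumerate(vocab)}
    k = len(vocab)
    tp = np.zeros(k, dtype=int)
    fp = np.zeros(k, dtype=int)
    fn = np.zeros(k, dtype=int)
    tn = np.zeros(k, dtype=int)
    for pred, gld in zip(predicted, gold):
        for lab in pred | gld:
            if lab not in index:
                raise ValueError(f"label {lab!r} outside vocabulary")
        pred_idx = {index[lab] for lab in pred}
        gold_idx = {index[lab] for lab in gld}
        for i in range(k):
            in_p, in_g = i in pred_idx, i in gold_idx
            if in_p and in_g:
                tp[i] += 1
            elif in_p:
                fp[i] += 1
            elif in_g:
                fn[i] += 1
            else:
                tn[i] += 1
    return ClassCounts(vocab, tp, fp, fn, tn)


def _ratio(num: np.ndarray | float, den: np.ndarray | float) -> np.ndarray | float:
    """num/den with the 0/0 -> 0 convention (elementwise)."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 0)
    return out


def macro_metrics(counts: ClassCounts) -> dict[str, float]:
    """Unweighted per-class means of precision, recall, F1 and similarity."""
    p = _ratio(counts.tp, counts.tp + counts.fp)
    r = _ratio(counts.tp, counts.tp + counts.fn)
    f1 = _ratio(2 * p * r, p + r)
    s = _ratio(counts.tp, counts.tp + counts.fp + counts.fn)
    return {
        "MaP": float(np.mean(p)),
        "MaR": float(np.mean(r)),
        "MaF1": float(np.mean(f1)),
        "MaS": float(np.mean(s)),
    }


def micro_metrics(counts: ClassCounts) -> dict[str, float]:
    """Pool counts over classes, then apply the ratio formulas once."""
    tp = float(counts.tp.sum())
    fp = float(counts.fp.sum())
    fn = float(counts.fn.sum())
    p = float(_ratio(tp, tp + fp))
    r = float(_ratio(tp, tp + fn))
    f1 = float(_ratio(2 * p * r, p + r))
    s = float(_ratio(tp, tp + fp + fn))
    return {"MiP": p, "MiR": r, "MiF1": f1, "MiS": s}


def roc_curve(
    scores: Sequence[float], truth: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Threshold-sweep ROC.

    Returns ``(thresholds, fpr, tpr, auc)``.  The sweep visits the distinct
    scores in descending order (equal scores form a single step); the curve
    is anchored at (0,0) and (1,1) and the AUC is the trapezoid-rule area.
    Raises ``ValueError`` when the truth vector is all-positive or
    all-negative.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if scores.shape != truth.shape or scores.ndim != 1:
        raise ValueError("scores and truth must be 1-D and equal length")
    n_pos = int(truth.sum())
    n_neg = int(len(truth) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_truth = truth[order]
    cum_tp = np.cumsum(sorted_truth)
    cum_fp = np.cumsum(1 - sorted_truth)
    # keep only the last index of each tied-score group
    last_of_group = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    thresholds = sorted_scores[last_of_group]
    tpr = cum_tp[last_of_group] / n_pos
    fpr = cum_fp[last_of_group] / n_neg
    thresholds = np.r_[np.inf, thresholds]
    tpr = np.r_[0.0, tpr]
    fpr = np.r_[0.0, fpr]
    auc = float(np.trapezoid(tpr, fpr))
    return thresholds, fpr, tpr, auc
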