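"""Binary-classification metrics and the stratified 70:15:15 node split.

Sick (label 1) is the positive class throughout.  ACC = (TP+TN)/(TP+FP+TN+FN)
and F1 = 2TP/(2TP+FN+FP); F1 is defined as 0 in the degenerate case
2TP+FN+FP = 0.  AUC and AUPRC delegate to scikit-learn (trapezoidal ROC with
midrank tie handling; step-wise average precision for the PR curve, the
unbiased construction for imbalanced data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .io import HEALTHY, SICK, OTUTable, ValidationError

__all__ = [
    "MetricsReport",
    "confusion",
    "accuracy",
    "f1",
    "auc",
    "auprc",
    "stratified_split",
    "evaluate_predictions",
]


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    f1: float
    auc: float
    auprc: float
    n_train: int = 0
    n_val: int = 0
    n_test: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {b.shape}")
    return a, b


def confusion(labels_true, labels_pred) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with sick=1 as the positive class."""
    y, p = _check_pair(labels_true, labels_pred)
    tp = int(np.sum((y == SICK) & (p == SICK)))
    fp = int(np.sum((y == HEALTHY) & (p == SICK)))
    tn = int(np.sum((y == HEALTHY) & (p == HEALTHY)))
    fn = int(np.sum((y == SICK) & (p == HEALTHY)))
    return tp, fp, tn, fn


def accuracy(tp: int, fp: int, tn: int, fn: int) -> float:
    total = tp + fp + tn + fn
    if total == 0:
        raise ValidationError("accuracy undefined on an empty evaluation set")
    return (tp + tn) / total


def f1(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fn + fp
    if denom == 0:
        return 0.0
    return 2 * tp / denom


def auc(labels_true, scores) -> float:
    """ROC AUC (probability of correct ranking); NaN with a warning when the
    truth contains a single class."""
    y, s = _check_pair(labels_true, np.asarray(scores, dtype=float))
    if len(np.unique(y)) < 2:
        warnings.warn("AUC undefined for single-class truth; returning NaN", stacklevel=2)
        return float("nan")
    return float(roc_auc_score(y, s))


def auprc(labels_true, scores) -> float:
    """Area under the precision-recall curve via step-wise average precision."""
    y, s = _check_pair(labels_true, np.asarray(scores, dtype=float))
    return float(average_precision_score(y, s, pos_label=SICK))


def _largest_remainder(n: int, ratios: tuple[float, ...]) -> list[int]:
    exact = [n * r for r in ratios]
    counts = [int(np.floor(e)) for e in exact]
    short = n - sum(counts)
    order = np.argsort([c - e for c, e in zip(counts, exact)], kind="stable")
    for k in order[:short]:
        counts[k] += 1
    return counts


def stratified_split(
    table_or_labels,
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/val/test index sets, stratified by label.

    Within each class the partition sizes follow largest-remainder rounding
    of the ratios (so each class's counts match the ratios to within one
    node); assignment within a class is a seeded shuffle.
    """
    labels = (
        table_or_labels.labels
        if isinstance(table_or_labels, OTUTable)
        else np.asarray(table_or_labels, dtype=int)
    )
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValidationError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    parts: list[list[np.ndarray]] = [[], [], []]
    for cls in (HEALTHY, SICK):
        idx = np.nonzero(labels == cls)[0]
        if len(idx) < 3:
            raise ValidationError(
                f"class {cls} has {len(idx)} samples; need >= 3 to fill all partitions"
            )
        rng.shuffle(idx)
        n_tr, n_va, n_te = _largest_remainder(len(idx), ratios)
        parts[0].append(idx[:n_tr])
        parts[1].append(idx[n_tr:n_tr + n_va])
        parts[2].append(idx[n_tr + n_va:])
    train, val, test = (np.sort(np.concatenate(p)) for p in parts)
    return train, val, test


def evaluate_predictions(
    labels_true, labels_pred, scores, *, n_train: int = 0, n_val: int = 0, seed: int = 0
) -> MetricsReport:
    """Assemble a full MetricsReport from labels, predictions and scores."""
    tp, fp, tn, fn = confusion(labels_true, labels_pred)
    return MetricsReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        acc=accuracy(tp, fp, tn, fn),
        f1=f1(tp, fp, fn),
        auc=auc(labels_true, scores),
        auprc=auprc(labels_true, scores),
        n_train=n_train,
        n_val=n_val,
        n_test=len(np.asarray(labels_true)),
        seed=seed,
    )
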