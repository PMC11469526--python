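"""Confusion matrices, classification metrics and n-fold cross-validation.

Conventions: confusion-matrix rows index the *predicted* class and columns
the *actual* class, so column sums give per-class sample counts.  For three
or more classes every metric is computed one-vs-rest per class:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    specificity = TN / (TN + FP)
    sensitivity = recall = TP / (TP + FN)
    precision   = TP / (TP + FP)
    F1          = 2 * recall * precision / (recall + precision)

A metric with a zero denominator is reported as NaN with an explicit
``undefined`` flag rather than silently coerced to 0 or 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "MetricsReport",
    "CVPlan",
    "confusion_matrix",
    "compute_metrics",
    "nfold_split",
    "cross_validate",
    "roc_curve",
]


@dataclass
class ConfusionMatrix:
    """Integer class x class table; rows = predicted, columns = actual."""

    counts: np.ndarray
    classes: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, index: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for one class against all others."""
        tp = int(self.counts[index, index])
        fp = int(self.counts[index].sum() - tp)  # predicted c, actually other
        fn = int(self.counts[:, index].sum() - tp)  # actually c, predicted other
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn

    def to_csv(self, path) -> None:
        pd.DataFrame(self.counts, index=self.classes, columns=self.classes).to_csv(path)


def confusion_matrix(y_true, y_pred, classes: Sequence) -> ConfusionMatrix:
    """Exact integer counts; order of (true, pred) pairs is irrelevant."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}; classes are {list(classes)}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}; classes are {list(classes)}")
        counts[index[p], index[t]] += 1
    return ConfusionMatrix(counts=counts, classes=list(classes))


@dataclass
class ClassMetrics:
    accuracy: float
    specificity: float
    sensitivity: float
    precision: float
    f1: float
    undefined: list[str] = field(default_factory=list)


def _safe_div(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return math.nan
    return num / den


def _binary_metrics(tp: int, fp: int, fn: int, tn: int) -> ClassMetrics:
    undefined: list[str] = []
    acc = _safe_div(tp + tn, tp + tn + fp + fn, "accuracy", undefined)
    spec = _safe_div(tn, tn + fp, "specificity", undefined)
    sens = _safe_div(tp, tp + fn, "sensitivity", undefined)
    prec = _safe_div(tp, tp + fp, "precision", undefined)
    if math.isnan(sens) or math.isnan(prec):
        undefined.append("f1")
        f1 = math.nan
    elif sens + prec == 0:
        f1 = 0.0  # documented convention: no true or predicted positives
    else:
        f1 = 2 * sens * prec / (sens + prec)
    return ClassMetrics(acc, spec, sens, prec, f1, undefined)


@dataclass
class MetricsReport:
    """Per-class one-vs-rest metrics plus micro/macro aggregates."""

    per_class: dict
    micro_accuracy: float
    macro_accuracy: float

    def to_dict(self) -> dict:
        return {
            "per_class": {
                str(k): {
                    "accuracy": v.accuracy,
                    "specificity": v.specificity,
                    "sensitivity": v.sensitivity,
                    "precision": v.precision,
                    "f1": v.f1,
                    "undefined": v.undefined,
                }
                for k, v in self.per_class.items()
            },
            "micro_accuracy": self.micro_accuracy,
            "macro_accuracy": self.macro_accuracy,
        }


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Apply the metric formulas per class (one-vs-rest) and overall.

    ``micro_accuracy`` is trace/total (the fraction of correctly classified
    samples); ``macro_accuracy`` is the mean of the per-class one-vs-rest
    accuracies.  Both are reported because multi-class "average accuracy"
    is ambiguous between the two.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per_class = {}
    for i, cls in enumerate(cm.classes):
        per_class[cls] = _binary_metrics(*cm.one_vs_rest(i))
    micro = float(np.trace(cm.counts) / cm.total)
    macro = float(np.mean([m.accuracy for m in per_class.values()]))
    return MetricsReport(per_class=per_class, micro_accuracy=micro, macro_accuracy=macro)


@dataclass
class CVPlan:
    """n-fold split: disjoint covering folds, stratified by default.

    ``p`` is the test fraction #(test samples)/#(all samples) = 1/n up to
    integer rounding of fold sizes.
    """

    n: int
    seed: int
    stratified: bool
    folds: list[np.ndarray]
    p: float

    def test_indices(self, fold: int) -> np.ndarray:
        return self.folds[fold]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.concatenate([f for i, f in enumerate(self.folds) if i != fold])


def nfold_split(labels, n: int, seed: int = 0, stratified: bool = True) -> CVPlan:
    """Assign samples to n disjoint covering folds.

    Stratified assignment deals each class's shuffled indices round-robin
    across folds, keeping class proportions within one sample per fold.  If
    any class has fewer samples than folds, falls back to unstratified with
    a warning.
    """
    import warnings

    labels = np.asarray(labels)
    size = labels.shape[0]
    if n < 2:
        raise ValueError("need at least 2 folds")
    if size < n:
        raise ValueError(f"dataset of {size} samples cannot be split into {n} folds")
    rng = np.random.default_rng(seed)
    if stratified:
        classes, counts = np.unique(labels, return_counts=True)
        if counts.min() < n:
            warnings.warn(
                f"a class has fewer than {n} samples; falling back to unstratified folds"
            )
            stratified = False
    fold_lists: list[list[int]] = [[] for _ in range(n)]
    if stratified:
        offset = 0
        for cls in classes:
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            for k, i in enumerate(idx):
                fold_lists[(k + offset) % n].append(int(i))
            offset += len(idx)  # rotate so remainders spread across folds
    else:
        idx = rng.permutation(size)
        for k, i in enumerate(idx):
            fold_lists[k % n].append(int(i))
    folds = [np.sort(np.asarray(f, dtype=int)) for f in fold_lists]
    p = float(np.mean([len(f) for f in folds]) / size)
    return CVPlan(n=n, seed=seed, stratified=stratified, folds=folds, p=p)


def cross_validate(
    model_builder: Callable[[int], object],
    train_fn: Callable[[object, np.ndarray, np.ndarray], object],
    predict_fn: Callable[[object, np.ndarray], np.ndarray],
    inputs: np.ndarray,
    labels: np.ndarray,
    plan: CVPlan,
    classes: Sequence | None = None,
) -> dict:
    """Train a fresh model per fold and aggregate per-class metrics.

    ``model_builder(fold_seed)`` builds a model with a fold-specific seed
    (master seed + fold index); per-fold micro accuracy and per-class
    one-vs-rest accuracies are aggregated as mean +- std.
    """
    labels = np.asarray(labels)
    classes = list(classes) if classes is not None else sorted(np.unique(labels).tolist())
    fold_reports = []
    fold_micro = []
    for fold in range(plan.n):
        try:
            model = model_builder(plan.seed + fold)
            tr, te = plan.train_indices(fold), plan.test_indices(fold)
            train_fn(model, inputs[tr], labels[tr])
            pred = predict_fn(model, inputs[te])
        except Exception as exc:  # noqa: BLE001 - annotate fold and re-raise
            raise RuntimeError(f"training failed in fold {fold}") from exc
        cm = confusion_matrix(labels[te], pred, classes)
        report = compute_metrics(cm)
        fold_reports.append(report)
        fold_micro.append(report.micro_accuracy)
    per_class = {
        cls: {
            "mean": float(np.mean([r.per_class[cls].accuracy for r in fold_reports])),
            "std": float(np.std([r.per_class[cls].accuracy for r in fold_reports])),
        }
        for cls in classes
    }
    return {
        "n": plan.n,
        "p": plan.p,
        "micro_accuracy_mean": float(np.mean(fold_micro)),
        "micro_accuracy_std": float(np.std(fold_micro)),
        "per_class_accuracy": per_class,
        "fold_reports": fold_reports,
    }


def format_fold_table(result: dict) -> str:
    """Plain-text ``mean ± std`` table of a cross-validation result."""
    lines = [f"n = {result['n']}   p = {result['p']:.3g}"]
    lines.append(
        f"Accuracy (micro): {100 * result['micro_accuracy_mean']:.2f} "
        f"± {100 * result['micro_accuracy_std']:.2f} %"
    )
    for cls, stats in result["per_class_accuracy"].items():
        lines.append(f"Acc {cls}: {100 * stats['mean']:.2f} ± {100 * stats['std']:.2f} %")
    return "\n".join(lines)


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Threshold sweep over positive-class scores.

    Returns (fpr, tpr, auc); ``auc`` is ``None`` (undefined) when only one
    class is present.  AUC uses the trapezoid rule and is invariant to
    strictly monotone transforms of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # merge tied scores into single threshold steps
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    if n_pos == 0 or n_neg == 0:
        return np.r_[0.0, 1.0], np.r_[0.0, 1.0], None
    fpr = np.r_[0.0, fp / n_neg]
    tpr = np.r_[0.0, tp / n_pos]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc
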