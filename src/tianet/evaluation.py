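"""Classification metrics and stratified k-fold cross-validation.

Positive class is glaucoma (label 1).  Sensitivity = TP/(TP+FN) and
specificity = TN/(TN+FP); a zero denominator yields NaN with a warning
rather than an exception.  AUC is the area under the ROC curve, equal to
the probability that a random positive outscores a random negative with
ties counted half.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "Confusion",
    "MetricsReport",
    "confusion_counts",
    "sensitivity",
    "specificity",
    "accuracy",
    "roc_auc",
    "kfold_cv",
]


class Confusion(NamedTuple):
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion_counts(labels, predictions) -> Confusion:
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    for name, a in (("labels", labels), ("predictions", predictions)):
        if not np.isin(a, (0, 1)).all():
            raise ValueError(f"{name} must be binary (0/1)")
    tp = int(((labels == 1) & (predictions == 1)).sum())
    tn = int(((labels == 0) & (predictions == 0)).sum())
    fp = int(((labels == 0) & (predictions == 1)).sum())
    fn = int(((labels == 1) & (predictions == 0)).sum())
    return Confusion(tp, tn, fp, fn)


def _safe_ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); returning NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def sensitivity(counts: Confusion) -> float:
    """TP / (TP + FN)."""
    return _safe_ratio(counts.TP, counts.TP + counts.FN, "sensitivity")


def specificity(counts: Confusion) -> float:
    """TN / (TN + FP)."""
    return _safe_ratio(counts.TN, counts.TN + counts.FP, "specificity")


def accuracy(counts: Confusion) -> float:
    return _safe_ratio(counts.TP + counts.TN, counts.total, "accuracy")


def roc_auc(labels, scores) -> float:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc requires both classes present")
    return float(roc_auc_score(labels, scores))


@dataclass
class MetricsReport:
    """Per-fold and aggregated binary classification metrics."""

    confusion: Confusion
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    per_fold: list["MetricsReport"] = field(default_factory=list)
    mean: dict[str, float] = field(default_factory=dict)
    variance: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_scores(cls, labels, scores, threshold: float = 0.5) -> "MetricsReport":
        labels = np.asarray(labels)
        scores = np.asarray(scores, dtype=float)
        preds = (scores > threshold).astype(int)
        c = confusion_counts(labels, preds)
        return cls(
            confusion=c,
            accuracy=accuracy(c),
            sensitivity=sensitivity(c),
            specificity=specificity(c),
            auc=roc_auc(labels, scores),
        )

    def to_dict(self) -> dict:
        d = {
            "TP": self.confusion.TP,
            "TN": self.confusion.TN,
            "FP": self.confusion.FP,
            "FN": self.confusion.FN,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }
        if self.per_fold:
            d["per_fold"] = [f.to_dict() for f in self.per_fold]
            d["mean"] = self.mean
            d["variance"] = self.variance
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def per_fold_frame(self) -> pd.DataFrame:
        rows = [
            {"fold": i, **{k: v for k, v in f.to_dict().items()
                           if not isinstance(v, (list, dict))}}
            for i, f in enumerate(self.per_fold)
        ]
        return pd.DataFrame(rows)


def kfold_cv(
    dataset,
    k: int,
    train_fn: Callable[[list[np.ndarray], np.ndarray], Callable[[list[np.ndarray]], np.ndarray]],
    seed: int = 0,
) -> MetricsReport:
    """Stratified k-fold cross-validation over a binary LabeledDataset.

    ``train_fn(images, labels)`` returns a scorer mapping images to
    positive-class probabilities.  Folds are stratified so each test fold
    contains both classes; per-fold metrics plus their mean and variance
    are aggregated into one report whose top-level confusion is the sum
    over folds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(dataset.labels)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} samples; cannot stratify into {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[MetricsReport] = []
    agg = np.zeros(4, dtype=int)
    all_labels, all_scores = [], []
    for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
        scorer = train_fn([dataset.images[i] for i in train_idx], labels[train_idx])
        scores = np.asarray(scorer([dataset.images[i] for i in test_idx]), dtype=float)
        rep = MetricsReport.from_scores(labels[test_idx], scores)
        folds.append(rep)
        agg += np.array(rep.confusion)
        all_labels.append(labels[test_idx])
        all_scores.append(scores)
    c = Confusion(*agg.tolist())
    keys = ("accuracy", "sensitivity", "specificity", "auc")
    values = {key: np.array([getattr(f, key) for f in folds]) for key in keys}
    report = MetricsReport(
        confusion=c,
        accuracy=accuracy(c),
        sensitivity=sensitivity(c),
        specificity=specificity(c),
        auc=roc_auc(np.concatenate(all_labels), np.concatenate(all_scores)),
        per_fold=folds,
        mean={key: float(np.nanmean(v)) for key, v in values.items()},
        variance={key: float(np.nanvar(v)) for key, v in values.items()},
    )
    return report
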