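"""Confusion-matrix evaluation metrics.

All four measures derive from a K x K confusion matrix of (true, predicted)
counts.  Accuracy is trace/total — in the binary case exactly
(TP+TN)/(TP+FP+TN+FN).  Precision TP/(TP+FP), recall TP/(TP+FN) and
F1 = 2PR/(P+R) are computed per class one-vs-rest and macro-averaged by
default (micro averaging available).  A class with no predicted instances
(precision) or no actual instances (recall) contributes 0 and triggers a
logged warning, which keeps the averages total while flagging degenerate
classifiers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = self.counts.shape[0]
        if self.counts.ndim != 2 or self.counts.shape[1] != k:
            raise ValueError(f"counts must be square, got {self.counts.shape}")
        if k < 2:
            raise ValueError(f"need >= 2 classes, got {k}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not self.class_names:
            self.class_names = [f"class_{i}" for i in range(k)]
        if len(self.class_names) != k:
            raise ValueError("class_names length must match matrix size")

    @classmethod
    def from_labels(
        cls, true, predicted, n_classes: int, class_names=None
    ) -> "ConfusionMatrix":
        true = np.asarray(true, dtype=np.int64)
        predicted = np.asarray(predicted, dtype=np.int64)
        if true.shape != predicted.shape:
            raise ValueError("true and predicted must have the same length")
        for name, arr in (("true", true), ("predicted", predicted)):
            if len(arr) and (arr.min() < 0 or arr.max() >= n_classes):
                raise ValueError(
                    f"{name} labels must lie in [0, {n_classes})"
                )
        counts = np.zeros((n_classes, n_classes), dtype=np.int64)
        np.add.at(counts, (true, predicted), 1)
        return cls(counts, list(class_names) if class_names else [])

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.counts.shape != other.counts.shape:
            raise ValueError("cannot pool confusion matrices of different sizes")
        return ConfusionMatrix(self.counts + other.counts, list(self.class_names))

    def per_class_counts(self) -> pd.DataFrame:
        """One-vs-rest TP/FP/FN/TN per class."""
        tp = np.diag(self.counts)
        fp = self.counts.sum(axis=0) - tp
        fn = self.counts.sum(axis=1) - tp
        tn = self.total - tp - fp - fn
        return pd.DataFrame(
            {"TP": tp, "FP": fp, "FN": fn, "TN": tn}, index=self.class_names
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.counts, index=self.class_names, columns=self.class_names
        ).to_csv(path)


def _check_nonempty(cm: ConfusionMatrix) -> None:
    if cm.total == 0:
        raise ValueError("empty confusion matrix: no observations")


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correct predictions: trace / total."""
    _check_nonempty(cm)
    return float(np.trace(cm.counts) / cm.total)


def _per_class_ratio(
    numer: np.ndarray, denom: np.ndarray, what: str, cm: ConfusionMatrix
) -> np.ndarray:
    vals = np.zeros(len(numer))
    ok = denom > 0
    vals[ok] = numer[ok] / denom[ok]
    for c in np.flatnonzero(~ok):
        msg = (
            f"class {cm.class_names[c]!r} has no "
            f"{'predicted' if what == 'precision' else 'actual'} instances; "
            f"its {what} counts as 0"
        )
        warnings.warn(msg, stacklevel=3)
        logger.debug(msg)
    return vals


def per_class_precision(cm: ConfusionMatrix) -> np.ndarray:
    _check_nonempty(cm)
    tp = np.diag(cm.counts).astype(float)
    predicted = cm.counts.sum(axis=0).astype(float)
    return _per_class_ratio(tp, predicted, "precision", cm)


def per_class_recall(cm: ConfusionMatrix) -> np.ndarray:
    _check_nonempty(cm)
    tp = np.diag(cm.counts).astype(float)
    actual = cm.counts.sum(axis=1).astype(float)
    return _per_class_ratio(tp, actual, "recall", cm)


def precision(cm: ConfusionMatrix, averaging: str = "macro") -> float:
    """TP/(TP+FP), averaged over classes (macro) or pooled counts (micro)."""
    if averaging == "macro":
        return float(per_class_precision(cm).mean())
    if averaging == "micro":
        _check_nonempty(cm)
        return float(np.trace(cm.counts) / cm.total)
    raise ValueError(f"averaging must be 'macro' or 'micro', got {averaging!r}")


def recall(cm: ConfusionMatrix, averaging: str = "macro") -> float:
    """TP/(TP+FN), averaged over classes (macro) or pooled counts (micro)."""
    if averaging == "macro":
        return float(per_class_recall(cm).mean())
    if averaging == "micro":
        _check_nonempty(cm)
        return float(np.trace(cm.counts) / cm.total)
    raise ValueError(f"averaging must be 'macro' or 'micro', got {averaging!r}")


def f1_score(cm: ConfusionMatrix, averaging: str = "macro") -> float:
    """Harmonic mean 2PR/(P+R) per class, then averaged.

    Classes where precision + recall = 0 contribute an F1 of 0.
    """
    if averaging == "micro":
        return precision(cm, "micro")  # == recall == accuracy for single-label
    if averaging != "macro":
        raise ValueError(f"averaging must be 'macro' or 'micro', got {averaging!r}")
    p = per_class_precision(cm)
    r = per_class_recall(cm)
    denom = p + r
    f1 = np.zeros_like(p)
    ok = denom > 0
    f1[ok] = 2.0 * p[ok] * r[ok] / denom[ok]
    return float(f1.mean())


def all_metrics(cm: ConfusionMatrix, averaging: str = "macro") -> dict[str, float]:
    """Accuracy, precision, recall and F1 in one dict."""
    return {
        "accuracy": accuracy(cm),
        "precision": precision(cm, averaging),
        "recall": recall(cm, averaging),
        "f1": f1_score(cm, averaging),
    }
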