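"""Cross-validated evaluation: confusion matrices and one-vs-rest metrics.

All methods are scored the same way: stratified 10-fold cross-validation,
out-of-fold predictions pooled into a single K x K confusion matrix, from
which come overall accuracy and per-class sensitivity (recall), specificity
(true-negative rate) and precision (positive predictive value), reported as
percentages.  Pooling (rather than averaging per-fold metrics) keeps the
counts interpretable and matches presenting one confusion matrix per
method.  Undefined ratios (0/0, e.g. precision of a never-predicted class)
are reported as not-available (NaN), never as 0.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn import metrics as _skm
from sklearn.base import BaseEstimator, clone
from sklearn.model_selection import KFold, StratifiedKFold

from . import learners
from .learners import ClassifierSpec

logger = logging.getLogger(__name__)

__all__ = [
    "confusion_matrix",
    "per_class_metrics",
    "accuracy_from_confusion",
    "EvaluationReport",
    "report_from_predictions",
    "cross_validate",
]


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """K x K count matrix; entry (t, p) = samples of true class t predicted p."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    labels = np.arange(1, n_classes + 1)
    if y_true.size:
        for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
            if arr.min() < 1 or arr.max() > n_classes:
                raise ValueError(f"{name} contains labels outside 1..{n_classes}")
        return _skm.confusion_matrix(y_true, y_pred, labels=labels)
    return np.zeros((n_classes, n_classes), dtype=int)


def per_class_metrics(cm: np.ndarray) -> pd.DataFrame:
    """One-vs-rest sensitivity/specificity/precision (percent) per class.

    For class c: TP = cm[c, c], FN = row c minus TP, FP = column c minus
    TP, TN = everything else.  A zero denominator yields NaN.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion matrix counts must be non-negative")
    tp = np.diag(cm).astype(float)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = cm.sum() - tp - fn - fp

    def ratio(num, den):
        return np.where(den > 0, 100.0 * num / np.where(den > 0, den, 1), np.nan)

    return pd.DataFrame(
        {
            "sensitivity": ratio(tp, tp + fn),
            "specificity": ratio(tn, tn + fp),
            "precision": ratio(tp, tp + fp),
        },
        index=pd.RangeIndex(1, cm.shape[0] + 1, name="class"),
    )


def accuracy_from_confusion(cm: np.ndarray) -> float:
    """Overall accuracy in percent: 100 * trace / total."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        return float("nan")
    return 100.0 * np.trace(cm) / total


@dataclass
class EvaluationReport:
    """Pooled cross-validation result for one method."""

    method: str
    confusion: np.ndarray
    metrics: pd.DataFrame  # per-class %, columns sensitivity/specificity/precision
    accuracy: float  # percent
    n: int
    folds: int | None = None
    seed: int | None = None
    fold_assignment: np.ndarray | None = None

    @property
    def macro(self) -> dict[str, float]:
        """Unweighted class means, ignoring not-available entries."""
        return {col: float(np.nanmean(self.metrics[col])) for col in self.metrics}

    def summary(self) -> str:
        lines = [f"method: {self.method}   n={self.n}"
                 + (f"   folds={self.folds}" if self.folds else "")]
        lines.append(f"accuracy: {self.accuracy:.1f}%")
        macro = self.macro
        lines.append(
            "macro: sensitivity {sensitivity:.1f}%  specificity {specificity:.1f}%  "
            "precision {precision:.1f}%".format(**macro)
        )
        table = self.metrics.map(lambda v: "n/a" if np.isnan(v) else f"{v:.1f}")
        lines.append(table.to_string())
        return "\n".join(lines)

    def confusion_frame(self) -> pd.DataFrame:
        K = self.confusion.shape[0]
        names = [f"disease_{j + 1}" for j in range(K)]
        return pd.DataFrame(self.confusion, index=names, columns=names)

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.confusion_frame().to_csv(
            directory / "confusion.tsv", sep="\t", index_label="true\\pred"
        )
        self.metrics.round(4).to_csv(directory / "metrics.tsv", sep="\t")
        (directory / "summary.txt").write_text(self.summary() + "\n", encoding="utf-8")


def report_from_predictions(
    method: str,
    y_true,
    y_pred,
    n_classes: int,
    folds: int | None = None,
    seed: int | None = None,
    fold_assignment=None,
) -> EvaluationReport:
    cm = confusion_matrix(y_true, y_pred, n_classes)
    return EvaluationReport(
        method=method,
        confusion=cm,
        metrics=per_class_metrics(cm),
        accuracy=accuracy_from_confusion(cm),
        n=int(np.asarray(y_true).size),
        folds=folds,
        seed=seed,
        fold_assignment=None if fold_assignment is None else np.asarray(fold_assignment),
    )


def _fresh(estimator):
    if isinstance(estimator, BaseEstimator):
        return clone(estimator)
    return copy.deepcopy(estimator)


def cross_validate(
    classifier_or_spec,
    X,
    y,
    folds: int = 10,
    seed: int = 0,
    stratified: bool = True,
    method: str | None = None,
) -> EvaluationReport:
    """Pooled stratified K-fold evaluation of a classifier or spec.

    Accepts either a :class:`~rxclassify.learners.ClassifierSpec` or any
    object with ``fit(X, y)`` / ``predict(X)``.  Folds are stratified by
    default so that rare classes appear in every training split; classes
    with fewer members than folds trigger a logged warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    if folds < 2:
        raise ValueError("folds must be at least 2")
    if n < folds:
        raise ValueError(f"cannot split {n} samples into {folds} folds")
    classes, counts = np.unique(y, return_counts=True)
    thin = classes[counts < folds]
    if stratified and thin.size:
        logger.warning(
            "classes %s have fewer members than folds=%d; some folds may lack them",
            thin.tolist(),
            folds,
        )
    splitter = (StratifiedKFold if stratified else KFold)(
        n_splits=folds, shuffle=True, random_state=seed
    )
    y_pred = np.zeros(n, dtype=int)
    fold_assignment = np.zeros(n, dtype=int)
    import warnings as _warnings

    for j, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        fold_assignment[test_idx] = j
        if isinstance(classifier_or_spec, ClassifierSpec):
            fitted = learners.fit(classifier_or_spec, X[train_idx], y[train_idx])
            y_pred[test_idx] = learners.predict(fitted, X[test_idx])
        else:
            model = _fresh(classifier_or_spec)
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", category=UserWarning)
                model.fit(X[train_idx], y[train_idx])
            y_pred[test_idx] = np.asarray(model.predict(X[test_idx]), dtype=int)
    if method is None:
        method = (
            classifier_or_spec.name
            if isinstance(classifier_or_spec, ClassifierSpec)
            else type(classifier_or_spec).__name__
        )
    return report_from_predictions(
        method,
        y,
        y_pred,
        n_classes=int(y.max()),
        folds=folds,
        seed=seed,
        fold_assignment=fold_assignment,
    )
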