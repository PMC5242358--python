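"""Hard-label combining of heterogeneous classifiers.

Three combiners over the base-learner bank:

* **Voting** — each classifier casts one vote; the class with the most
  votes wins.
* **Weighted voting** — each classifier's vote carries weight
  ``beta ** e_j`` where ``e_j`` is its number of training errors and
  ``beta`` in (0, 1] is the updating rate: every error shrinks the weight
  multiplicatively by ``beta``.  ``beta = 1`` gives every classifier the
  same weight and recovers plain voting exactly.
* **Stacking** — out-of-fold predictions of the N base learners form an
  n x (N+1) meta-dataset (N predicted labels plus the actual class); a
  second-level learner (default: 3-nearest-neighbour) is trained on it.
  Predicted labels are categorical, so the meta-learner sees them one-hot
  encoded, which makes nearest-neighbour distance Hamming-like rather
  than imposing a spurious ordering on class indices.

Weights and the meta-dataset are built from out-of-fold predictions
(models never predict rows they trained on), so overfit learners are not
rewarded; resubstitution is available behind a flag for fidelity
experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import OneHotEncoder

from . import learners
from .learners import ClassifierSpec, make_spec

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleWeights",
    "MetaDataset",
    "BetaTuneResult",
    "learn_weights",
    "vote",
    "weighted_vote",
    "majority_vote",
    "build_meta_dataset",
    "stack_fit_predict",
    "tune_beta",
    "default_base_specs",
    "VotingEnsemble",
    "WeightedVotingEnsemble",
    "StackingEnsemble",
]


def default_base_specs(seed: int = 0) -> list[ClassifierSpec]:
    """The six canonical base-learner specs, in their fixed column order."""
    return [make_spec(name, seed=seed) for name in learners.CLASSIFIER_NAMES]


@dataclass
class EnsembleWeights:
    """Per-classifier vote weights ``beta ** errors`` plus provenance."""

    weights: np.ndarray
    beta: float
    error_counts: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.error_counts = np.asarray(self.error_counts, dtype=int)

    def to_frame(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        names = names or [f"clf{j + 1}" for j in range(len(self.weights))]
        return pd.DataFrame(
            {"classifier": list(names), "errors": self.error_counts, "weight": self.weights}
        )


def learn_weights(P, y, beta: float) -> EnsembleWeights:
    """Weighted-majority weights from a prediction matrix.

    Conceptually each classifier starts at weight 1 and is multiplied by
    ``beta`` once per sample it mislabels; the closed form is
    ``w_j = beta ** e_j`` with ``e_j`` the error count of column ``j``.
    """
    if not 0.0 < beta <= 1.0:
        raise ValueError(f"beta must lie in (0, 1], got {beta}")
    P = np.asarray(P)
    y = np.asarray(y)
    if P.ndim != 2 or P.shape[0] != y.shape[0]:
        raise ValueError("prediction matrix rows must align with labels")
    errors = (P != y[:, None]).sum(axis=0)
    return EnsembleWeights(weights=beta ** errors.astype(float), beta=beta, error_counts=errors)


def _resolve_weights(weights, n: int) -> np.ndarray:
    if weights is None:
        return np.ones(n)
    if isinstance(weights, EnsembleWeights):
        weights = weights.weights
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"expected {n} weights, got shape {w.shape}")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    return w


def weighted_vote(P, weights=None, n_classes: int | None = None) -> np.ndarray:
    """Row-wise weighted vote over an n x N label matrix.

    The winner maximizes the summed weight of its voters.  Ties go to the
    class backed by the single heaviest voter; any remaining tie to the
    lowest class index.  Tie events are logged.
    """
    P = np.asarray(P, dtype=int)
    if P.ndim != 2 or P.shape[1] == 0:
        raise ValueError("prediction matrix must be n x N with N >= 1")
    n, N = P.shape
    w = _resolve_weights(weights, N)
    K = int(n_classes or P.max())
    if P.min() < 1 or P.max() > K:
        raise ValueError(f"labels must lie in 1..{K}")
    scores = np.zeros((n, K))
    heaviest = np.full((n, K), -np.inf)
    rows = np.arange(n)
    for j in range(N):
        cols = P[:, j] - 1
        scores[rows, cols] += w[j]
        np.maximum.at(heaviest, (rows, cols), w[j])
    best = scores.max(axis=1, keepdims=True)
    contenders = np.isclose(scores, best, rtol=1e-9, atol=1e-12)
    n_ties = int((contenders.sum(axis=1) > 1).sum())
    if n_ties:
        logger.info("vote: %d rows decided by tie-break", n_ties)
    # among contenders prefer the class with the heaviest single voter,
    # then the lowest class index (argmax returns the first maximum)
    key = np.where(contenders, heaviest, -np.inf)
    return key.argmax(axis=1) + 1


def vote(preds_row, weights=None, n_classes: int | None = None) -> int:
    """Combine one row of base predictions into a single label."""
    preds_row = np.asarray(preds_row, dtype=int)
    if preds_row.ndim != 1 or preds_row.size == 0:
        raise ValueError("prediction row must be a non-empty 1-D label vector")
    return int(weighted_vote(preds_row[None, :], weights, n_classes=n_classes)[0])


def majority_vote(P, n_classes: int | None = None) -> np.ndarray:
    """Plain (unweighted) majority vote; ties to the lowest class index."""
    return weighted_vote(P, None, n_classes=n_classes)


# ---------------------------------------------------------------------------
# Stacking machinery


@dataclass
class MetaDataset:
    """Out-of-fold base predictions plus the actual class, fold-tagged.

    ``predictions[i, j]`` is the label learner ``j`` assigned to sample
    ``i`` when trained on every fold except the one containing ``i``;
    ``train_indices`` records, per fold, exactly which rows the models
    predicting that fold were trained on, enabling a structural
    no-leakage audit.
    """

    predictions: np.ndarray  # n x N
    y: np.ndarray  # n
    fold: np.ndarray  # n, values 0..J-1
    classifier_names: list[str]
    train_indices: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_learners(self) -> int:
        return self.predictions.shape[1]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.predictions, columns=self.classifier_names)
        frame["actual"] = self.y
        frame["fold"] = self.fold
        return frame

    def assert_no_leakage(self) -> None:
        """Fail if any row was predicted by a model trained on that row."""
        for j, train_idx in self.train_indices.items():
            fold_rows = np.flatnonzero(self.fold == j)
            overlap = np.intersect1d(fold_rows, train_idx)
            if overlap.size:
                raise AssertionError(
                    f"fold {j}: rows {overlap[:5]}... predicted by their own training model"
                )


def _fold_splitter(J: int, seed: int, stratified: bool):
    cls = StratifiedKFold if stratified else KFold
    return cls(n_splits=J, shuffle=True, random_state=seed)


def build_meta_dataset(
    base_specs: Sequence[ClassifierSpec],
    X,
    y,
    J: int = 10,
    seed: int = 0,
    stratified: bool = True,
) -> MetaDataset:
    """J-fold out-of-fold predictions of every base learner.

    The data are split into J folds; for each fold the N learners are
    trained on the complement and predict the held-out fold, so each row
    is predicted exactly once per learner, by a model that never saw it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    if J < 2:
        raise ValueError("J must be at least 2")
    if J > n:
        raise ValueError(f"cannot split {n} samples into {J} folds")
    N = len(base_specs)
    predictions = np.zeros((n, N), dtype=int)
    fold = np.zeros(n, dtype=int)
    train_indices: dict[int, np.ndarray] = {}
    splitter = _fold_splitter(J, seed, stratified)
    for j, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        fold[test_idx] = j
        train_indices[j] = train_idx.copy()
        for col, spec in enumerate(base_specs):
            fitted = learners.fit(spec, X[train_idx], y[train_idx])
            predictions[test_idx, col] = learners.predict(fitted, X[test_idx])
    return MetaDataset(
        predictions=predictions,
        y=y,
        fold=fold,
        classifier_names=[s.name for s in base_specs],
        train_indices=train_indices,
    )


class _MetaLearner:
    """Second-level learner on one-hot encoded base predictions."""

    def __init__(self, meta_spec: ClassifierSpec, n_classes: int):
        if meta_spec.name != "knn":
            raise ValueError("only a k-nearest-neighbour meta-learner is supported")
        p = dict(meta_spec.hyperparameters)
        self.encoder = OneHotEncoder(
            categories="auto", handle_unknown="ignore", sparse_output=False
        )
        self.model = KNeighborsClassifier(
            n_neighbors=p.get("k", 3), metric=p.get("metric", "manhattan")
        )
        self.n_classes = n_classes

    def fit(self, P, y):
        self.encoder.fit(np.asarray(P, dtype=int))
        self.model.fit(self.encoder.transform(np.asarray(P, dtype=int)), y)
        return self

    def predict(self, P):
        return np.asarray(
            self.model.predict(self.encoder.transform(np.asarray(P, dtype=int))),
            dtype=int,
        )


def stack_fit_predict(
    meta: MetaDataset,
    new_preds,
    meta_spec: ClassifierSpec | None = None,
) -> np.ndarray:
    """Fit the meta-learner on the meta-dataset; label new prediction rows."""
    if meta_spec is None:
        meta_spec = make_spec("knn", {"k": 3})
    new_preds = np.asarray(new_preds, dtype=int)
    if new_preds.ndim != 2 or new_preds.shape[1] != meta.n_learners:
        raise ValueError(
            f"new predictions must have {meta.n_learners} columns, got {new_preds.shape}"
        )
    K = int(max(meta.y.max(), meta.predictions.max()))
    learner = _MetaLearner(meta_spec, n_classes=K)
    learner.fit(meta.predictions, meta.y)
    return learner.predict(new_preds)


# ---------------------------------------------------------------------------
# Beta tuning


@dataclass
class BetaTuneResult:
    best_beta: float
    table: pd.DataFrame  # columns: beta, accuracy
    meta: MetaDataset

    def __iter__(self):  # allows ``beta, table = tune_beta(...)`` style use
        yield self.best_beta
        yield self.table


def fold_aligned_vote(meta: MetaDataset, beta: float, n_classes: int | None = None) -> np.ndarray:
    """Out-of-fold weighted-vote predictions at a given ``beta``.

    For every fold the weights are learned from the error counts of the
    remaining folds only, then applied to that fold's prediction rows.
    """
    preds = np.zeros_like(meta.y)
    for j in np.unique(meta.fold):
        test = meta.fold == j
        w = learn_weights(meta.predictions[~test], meta.y[~test], beta)
        preds[test] = weighted_vote(meta.predictions[test], w, n_classes=n_classes)
    return preds


def tune_beta(
    base_specs: Sequence[ClassifierSpec],
    X,
    y,
    grid: Sequence[float],
    cv_folds: int = 10,
    seed: int = 0,
    meta: MetaDataset | None = None,
) -> BetaTuneResult:
    """Grid-search the weight-updating rate by cross-validated accuracy.

    One J-fold out-of-fold prediction matrix is built (or reused via
    ``meta``); each candidate ``beta`` is scored by fold-aligned weighted
    voting, weights always learned on the training folds only.  Ties go to
    the largest ``beta`` (the least aggressive down-weighting).
    """
    grid = sorted(float(b) for b in grid)
    if not grid:
        raise ValueError("beta grid must be non-empty")
    if any(not 0.0 < b <= 1.0 for b in grid):
        raise ValueError("beta grid values must lie in (0, 1]")
    if cv_folds < 2:
        raise ValueError("cv_folds must be at least 2")
    if meta is None:
        meta = build_meta_dataset(base_specs, X, y, J=cv_folds, seed=seed)
    y = np.asarray(y, dtype=int)
    K = int(y.max())
    accuracies = []
    for beta in grid:
        preds = fold_aligned_vote(meta, beta, n_classes=K)
        accuracies.append(float((preds == y).mean()))
    table = pd.DataFrame({"beta": grid, "accuracy": accuracies})
    # argmax with ties resolved to the largest beta: scan in grid order,
    # keeping >= so later (larger) betas win exact ties
    best_idx = 0
    for i in range(1, len(grid)):
        if accuracies[i] >= accuracies[best_idx]:
            best_idx = i
    return BetaTuneResult(best_beta=grid[best_idx], table=table, meta=meta)


# ---------------------------------------------------------------------------
# Estimator-style wrappers (fit/predict interface for CV harnesses)


class WeightedVotingEnsemble(BaseEstimator, ClassifierMixin):
    """Weighted-vote combiner as a fit/predict estimator.

    ``fit`` learns the vote weights from inner out-of-fold predictions
    (``weight_mode="out_of_fold"``, the default) or from resubstitution
    predictions, then refits every base learner on the full training set.
    """

    def __init__(
        self,
        base_specs: Sequence[ClassifierSpec] | None = None,
        beta: float = 0.94,
        inner_folds: int = 5,
        weight_mode: str = "out_of_fold",
        seed: int = 0,
    ):
        self.base_specs = base_specs
        self.beta = beta
        self.inner_folds = inner_folds
        self.weight_mode = weight_mode
        self.seed = seed

    def _specs(self) -> list[ClassifierSpec]:
        return list(self.base_specs) if self.base_specs else default_base_specs(self.seed)

    def fit(self, X, y):
        if self.weight_mode not in ("out_of_fold", "resubstitution"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        specs = self._specs()
        self.fitted_ = [learners.fit(spec, X, y) for spec in specs]
        if self.beta == 1.0:
            # plain voting: weights are 1 regardless of errors
            P = np.column_stack([learners.predict(f, X) for f in self.fitted_])
            self.weights_ = learn_weights(P, y, 1.0)
        elif self.weight_mode == "resubstitution":
            P = np.column_stack([learners.predict(f, X) for f in self.fitted_])
            self.weights_ = learn_weights(P, y, self.beta)
        else:
            meta = build_meta_dataset(specs, X, y, J=self.inner_folds, seed=self.seed)
            self.weights_ = learn_weights(meta.predictions, y, self.beta)
        self.classes_ = np.unique(y)
        self.n_classes_ = int(y.max())
        return self

    def predict(self, X):
        P = np.column_stack(
            [learners.predict(f, np.asarray(X, dtype=float)) for f in self.fitted_]
        )
        return weighted_vote(P, self.weights_, n_classes=self.n_classes_)


class VotingEnsemble(WeightedVotingEnsemble):
    """Plain majority voting: every classifier has the same weight."""

    def __init__(self, base_specs=None, seed: int = 0):
        super().__init__(base_specs=base_specs, beta=1.0, seed=seed)


class StackingEnsemble(BaseEstimator, ClassifierMixin):
    """Two-layer combiner: base learners feed a nearest-neighbour meta-learner."""

    def __init__(
        self,
        base_specs: Sequence[ClassifierSpec] | None = None,
        meta_spec: ClassifierSpec | None = None,
        inner_folds: int = 5,
        seed: int = 0,
    ):
        self.base_specs = base_specs
        self.meta_spec = meta_spec
        self.inner_folds = inner_folds
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        specs = list(self.base_specs) if self.base_specs else default_base_specs(self.seed)
        meta_spec = self.meta_spec or make_spec("knn", {"k": 3})
        self.meta_ = build_meta_dataset(specs, X, y, J=self.inner_folds, seed=self.seed)
        K = int(max(y.max(), self.meta_.predictions.max()))
        self.meta_learner_ = _MetaLearner(meta_spec, n_classes=K).fit(
            self.meta_.predictions, y
        )
        self.fitted_ = [learners.fit(spec, X, y) for spec in specs]
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        P = np.column_stack(
            [learners.predict(f, np.asarray(X, dtype=float)) for f in self.fitted_]
        )
        return self.meta_learner_.predict(P)
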