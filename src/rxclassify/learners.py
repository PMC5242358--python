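"""The six configured base classifiers.

A thin, uniform contract (spec -> fit -> predict) over established
scikit-learn learners, pre-configured with the hyperparameters used
throughout this analysis:

* decision tree — entropy splits, minimum leaf size 1, unpruned.  The
  C4.5-style "confidence factor 0.55" pruning knob has no direct
  counterpart here; a confidence factor of 0.5 or more prunes essentially
  nothing, so the tree is grown unpruned (``ccp_alpha=0``).
* support vector machine — polynomial kernel (degree 3), C = 1.6; the
  underlying implementation trains one-vs-one binary machines and couples
  them pairwise for the multiclass decision.
* neural network — one hidden layer of 63 units between the 60 count
  inputs and the class outputs, plain SGD with learning rate 0.3 and
  momentum 0.2, exactly 500 epochs (no convergence-based early stop).
* naive Bayes — Gaussian per-feature likelihoods.
* ridge-penalized logistic regression — L2 with ridge factor 10
  (``C = 0.1``), multinomial.
* k-nearest neighbour — one neighbour, Manhattan distance.

Learner internals (tree induction, SMO, backprop) are deliberately
delegated; this module owns only the configuration surface.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "CLASSIFIER_NAMES",
    "ClassifierSpec",
    "FittedClassifier",
    "make_spec",
    "build_estimator",
    "fit",
    "predict",
]

CLASSIFIER_NAMES = (
    "decision_tree",
    "svm",
    "neural_net",
    "naive_bayes",
    "logistic_ridge",
    "knn",
)

_DEFAULTS: dict[str, dict[str, Any]] = {
    "decision_tree": {"criterion": "entropy", "min_leaf": 1, "ccp_alpha": 0.0},
    "svm": {"kernel": "poly", "C": 1.6, "degree": 3, "gamma": "scale", "coef0": 0.0},
    "neural_net": {
        "hidden_units": 63,
        "epochs": 500,
        "learning_rate": 0.3,
        "momentum": 0.2,
    },
    "naive_bayes": {"var_smoothing": 1e-9},
    "logistic_ridge": {"ridge": 10.0, "max_iter": 2000},
    "knn": {"k": 1, "metric": "manhattan"},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """Name + hyperparameters + seed; the unit the rest of the pipeline
    passes around instead of estimator objects."""

    name: str
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)
    seed: int = 0


def make_spec(
    name: str, overrides: Mapping[str, Any] | None = None, seed: int = 0
) -> ClassifierSpec:
    """Spec for ``name`` with its canonical defaults, ``overrides`` last."""
    if name not in _DEFAULTS:
        raise ValueError(
            f"unknown classifier {name!r}; expected one of {CLASSIFIER_NAMES}"
        )
    params = dict(_DEFAULTS[name])
    for key, value in (overrides or {}).items():
        if key not in params:
            raise ValueError(f"{name} has no hyperparameter {key!r}")
        params[key] = value
    return ClassifierSpec(name=name, hyperparameters=params, seed=seed)


def build_estimator(spec: ClassifierSpec):
    """Fresh, unfitted scikit-learn estimator realising ``spec``."""
    p = dict(_DEFAULTS[spec.name])
    p.update(spec.hyperparameters)
    if spec.name == "decision_tree":
        return DecisionTreeClassifier(
            criterion=p["criterion"],
            min_samples_leaf=p["min_leaf"],
            ccp_alpha=p["ccp_alpha"],
            random_state=spec.seed,
        )
    if spec.name == "svm":
        return SVC(
            kernel=p["kernel"],
            C=p["C"],
            degree=p["degree"],
            gamma=p["gamma"],
            coef0=p["coef0"],
            random_state=spec.seed,
        )
    if spec.name == "neural_net":
        return MLPClassifier(
            hidden_layer_sizes=(p["hidden_units"],),
            solver="sgd",
            learning_rate_init=p["learning_rate"],
            momentum=p["momentum"],
            nesterovs_momentum=False,
            max_iter=p["epochs"],
            n_iter_no_change=p["epochs"],  # run the full epoch budget
            early_stopping=False,
            random_state=spec.seed,
        )
    if spec.name == "naive_bayes":
        return GaussianNB(var_smoothing=p["var_smoothing"])
    if spec.name == "logistic_ridge":
        return LogisticRegression(
            C=1.0 / p["ridge"],
            max_iter=p["max_iter"],
            random_state=spec.seed,
        )
    if spec.name == "knn":
        return KNeighborsClassifier(n_neighbors=p["k"], metric=p["metric"])
    raise ValueError(f"unknown classifier {spec.name!r}")


@dataclass
class FittedClassifier:
    spec: ClassifierSpec
    estimator: Any
    n_features_in: int
    classes_: np.ndarray
    train_fingerprint: str


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def fit(spec: ClassifierSpec, X, y) -> FittedClassifier:
    """Fit the configured learner; deterministic given ``spec.seed``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty 2-D array")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X rows must align with y")
    if np.unique(y).size < 2:
        raise ValueError("training data must contain at least two classes")
    estimator = build_estimator(spec)
    with warnings.catch_warnings():
        # the neural net intentionally runs its full epoch budget
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        estimator.fit(X, y)
    return FittedClassifier(
        spec=spec,
        estimator=estimator,
        n_features_in=X.shape[1],
        classes_=np.unique(y),
        train_fingerprint=_fingerprint(X, y),
    )


def predict(fitted: FittedClassifier, X) -> np.ndarray:
    """Labels (from the training label set) for each row of ``X``."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or (X.size and X.shape[1] != fitted.n_features_in):
        raise ValueError(
            f"X must have {fitted.n_features_in} columns, got shape {X.shape}"
        )
    if X.shape[0] == 0:
        return np.empty(0, dtype=int)
    return np.asarray(fitted.estimator.predict(X), dtype=int)
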