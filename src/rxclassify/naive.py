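"""Shared-drug-group baseline classifier.

The baseline scores a prescription against each disease by the number of
drug groups the two have in common, normalized so that diseases with many
characteristic groups do not dominate: for prescription *i* and disease *j*

    m_ij = a_ij / sqrt(b_i * c_j)

where ``a_ij`` is the number of shared drug groups, ``b_i`` the number of
distinct drug groups on the prescription, and ``c_j`` the number of drug
groups linked to the disease.  ``m_ij`` lies in [0, 1] and equals 1 exactly
when the prescription's group support coincides with the disease signature.
The prescription is tagged with the argmax disease.

Only supports matter: counts of 2 (duplicated drugs within a group) neither
raise ``b_i`` nor weight the overlap, so scores are invariant to scaling
the count vector.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseSignatureTable",
    "shared_group_count",
    "naive_score",
    "naive_classify",
    "NaiveSharedGroupClassifier",
]


class DiseaseSignatureTable:
    """Binary K x G matrix linking each disease class to its drug groups.

    Row ``j`` (disease ``j+1``) carries 1 in the columns of the drug groups
    characteristic of that disease.  Every row must name at least one group.
    """

    def __init__(self, values, group_names: Sequence[str] | None = None):
        values = np.asarray(values)
        if values.ndim != 2:
            raise ValueError("signature table must be two-dimensional")
        if not np.isin(values, (0, 1)).all():
            raise ValueError("signature table entries must be 0 or 1")
        if (values.sum(axis=1) < 1).any():
            raise ValueError("every disease needs at least one drug group")
        self.values = values.astype(np.uint8)
        if group_names is None:
            group_names = [f"g{i + 1}" for i in range(values.shape[1])]
        if len(group_names) != values.shape[1]:
            raise ValueError("group_names length must match column count")
        self.group_names = list(group_names)

    @property
    def n_classes(self) -> int:
        return self.values.shape[0]

    @property
    def n_groups(self) -> int:
        return self.values.shape[1]

    @property
    def row_sizes(self) -> np.ndarray:
        """c_j: number of drug groups of each disease."""
        return self.values.sum(axis=1).astype(int)

    def signature_indices(self, class_label: int) -> np.ndarray:
        """0-based group indices of disease ``class_label`` (1-based)."""
        if not 1 <= class_label <= self.n_classes:
            raise ValueError(f"class label {class_label} out of range")
        return np.flatnonzero(self.values[class_label - 1])

    def to_frame(self) -> pd.DataFrame:
        index = [f"disease_{j + 1}" for j in range(self.n_classes)]
        return pd.DataFrame(self.values, index=index, columns=self.group_names)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=True, index_label="disease")

    @classmethod
    def from_tsv(cls, path) -> "DiseaseSignatureTable":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(frame.to_numpy(), group_names=list(frame.columns))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DiseaseSignatureTable)
            and np.array_equal(self.values, other.values)
            and self.group_names == other.group_names
        )

    def __repr__(self) -> str:
        return f"DiseaseSignatureTable(K={self.n_classes}, G={self.n_groups})"


def shared_group_count(x, signature_row) -> int:
    """Number of drug groups present on the prescription and in the signature.

    Supports intersect as sets: a count of 2 in ``x`` contributes one shared
    group, not two.
    """
    x = np.asarray(x)
    signature_row = np.asarray(signature_row)
    if x.shape != signature_row.shape:
        raise ValueError(
            f"length mismatch: prescription {x.shape} vs signature {signature_row.shape}"
        )
    return int(np.count_nonzero((x > 0) & (signature_row > 0)))


def naive_score(a: int, b: int, c: int) -> float:
    """Normalized shared-group score a / sqrt(b * c) in [0, 1]."""
    if b <= 0 or c <= 0:
        raise ValueError("b and c must be positive group counts")
    if not 0 <= a <= min(b, c):
        raise ValueError("a must satisfy 0 <= a <= min(b, c)")
    return a / np.sqrt(b * c)


def _score_matrix(X: np.ndarray, table: DiseaseSignatureTable) -> np.ndarray:
    support = (X > 0).astype(np.int64)
    b = support.sum(axis=1)
    if (b == 0).any():
        raise ValueError("empty prescription: at least one drug group required")
    a = support @ table.values.T.astype(np.int64)
    c = table.row_sizes
    return a / np.sqrt(np.outer(b, c))


def naive_classify(x, table: DiseaseSignatureTable, tie_rule: str = "lowest") -> int:
    """Tag one prescription with the disease of largest normalized score."""
    return int(
        NaiveSharedGroupClassifier(table, tie_rule=tie_rule).predict(
            np.asarray(x).reshape(1, -1)
        )[0]
    )


class NaiveSharedGroupClassifier(BaseEstimator, ClassifierMixin):
    """Argmax-of-normalized-overlap classifier over a fixed signature table.

    The signature table is domain knowledge supplied up front, so ``fit``
    only validates dimensions; predictions do not depend on training data.
    Ties (including the degenerate all-zero-score case) resolve to the
    lowest class index and are counted in ``tie_count_`` / logged.
    """

    def __init__(self, table: DiseaseSignatureTable, tie_rule: str = "lowest"):
        self.table = table
        self.tie_rule = tie_rule

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.table.n_groups:
            raise ValueError(
                f"X must have {self.table.n_groups} drug-group columns"
            )
        self.classes_ = np.arange(1, self.table.n_classes + 1)
        self.n_features_in_ = self.table.n_groups
        return self

    def score_matrix(self, X) -> np.ndarray:
        """n x K matrix of normalized scores m_ij."""
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.table.n_groups:
            raise ValueError(
                f"X must have {self.table.n_groups} drug-group columns"
            )
        return _score_matrix(X, self.table)

    def predict(self, X) -> np.ndarray:
        if self.tie_rule != "lowest":
            raise ValueError(f"unknown tie rule {self.tie_rule!r}")
        scores = self.score_matrix(np.asarray(X))
        best = scores.max(axis=1, keepdims=True)
        ties = (np.isclose(scores, best, rtol=0, atol=1e-12).sum(axis=1) > 1).sum()
        zero_rows = int((best == 0).sum())
        if ties:
            logger.info("naive classifier: %d rows had tied top scores", ties)
        if zero_rows:
            logger.warning(
                "naive classifier: %d rows share no group with any disease", zero_rows
            )
        self.tie_count_ = int(ties)
        self.zero_score_count_ = zero_rows
        # np.argmax picks the first (lowest-index) maximizer
        return scores.argmax(axis=1) + 1
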