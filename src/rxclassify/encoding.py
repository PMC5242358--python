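"""Drug-group count encoding of raw prescriptions.

A prescription is a multiset of drug identifiers; drugs are grouped into G
pharmacological groups to keep the feature space small relative to the
sample size.  The encoding places, for every drug on the prescription, a 1
in each group the drug belongs to, accumulating additively: a drug in two
groups raises both cells, two drugs of one group yield a 2.  Counts are
unbounded non-negative integers; the encoding depends only on the multiset,
not on drug order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DrugGroupMapping",
    "Prescription",
    "UnknownDrugError",
    "encode_prescription",
    "build_feature_matrix",
    "read_prescriptions",
    "read_mapping",
]


class UnknownDrugError(KeyError):
    """A prescription names a drug absent from the drug-group mapping."""


@dataclass(frozen=True)
class Prescription:
    identifier: str
    drugs: tuple[str, ...]

    def __post_init__(self):
        if not self.drugs:
            raise ValueError(f"prescription {self.identifier!r} has no drugs")


class DrugGroupMapping:
    """Map from drug identifier to its (non-empty) set of 1-based groups."""

    def __init__(self, mapping: Mapping[str, Iterable[int]], n_groups: int):
        if n_groups <= 0:
            raise ValueError("n_groups must be positive")
        if not mapping:
            raise ValueError("mapping must contain at least one drug")
        self.n_groups = int(n_groups)
        self._map: dict[str, frozenset[int]] = {}
        for drug, groups in mapping.items():
            groups = frozenset(int(g) for g in groups)
            if not groups:
                raise ValueError(f"drug {drug!r} maps to no group")
            bad = [g for g in groups if not 1 <= g <= n_groups]
            if bad:
                raise ValueError(f"drug {drug!r} maps to out-of-range groups {bad}")
            self._map[str(drug)] = groups

    def __contains__(self, drug: str) -> bool:
        return drug in self._map

    def __len__(self) -> int:
        return len(self._map)

    def groups_of(self, drug: str) -> frozenset[int]:
        try:
            return self._map[drug]
        except KeyError:
            raise UnknownDrugError(drug) from None

    @property
    def drugs(self) -> list[str]:
        return sorted(self._map)


def encode_prescription(
    prescription: Prescription,
    mapping: DrugGroupMapping,
    unknown: str = "error",
) -> np.ndarray:
    """Count vector of length G for one prescription.

    ``unknown`` controls what happens when a drug is missing from the
    mapping: ``"error"`` (default) raises :class:`UnknownDrugError`,
    ``"skip"`` drops the drug with a logged warning.  Silent dropping is
    never the default because it biases class signals.
    """
    if unknown not in ("error", "skip"):
        raise ValueError(f"unknown-drug policy {unknown!r} not recognised")
    counts = np.zeros(mapping.n_groups, dtype=np.int64)
    for drug in prescription.drugs:
        if drug not in mapping:
            if unknown == "error":
                raise UnknownDrugError(
                    f"drug {drug!r} of prescription {prescription.identifier!r} "
                    "is not in the drug-group mapping"
                )
            logger.warning(
                "skipping unknown drug %r in prescription %r",
                drug,
                prescription.identifier,
            )
            continue
        for g in mapping.groups_of(drug):
            counts[g - 1] += 1
    return counts


def build_feature_matrix(
    prescriptions: Sequence[Prescription],
    mapping: DrugGroupMapping,
    labels: Sequence[int] | None = None,
    unknown: str = "error",
) -> pd.DataFrame:
    """n x G count matrix, one row per prescription in input order.

    Columns are ``g1..gG``; when ``labels`` is given (aligned 1:1) a
    ``disease`` column is appended.
    """
    if labels is not None and len(labels) != len(prescriptions):
        raise ValueError("labels must align 1:1 with prescriptions")
    rows = [encode_prescription(p, mapping, unknown=unknown) for p in prescriptions]
    frame = pd.DataFrame(
        np.asarray(rows).reshape(len(prescriptions), mapping.n_groups),
        columns=[f"g{i + 1}" for i in range(mapping.n_groups)],
        index=[p.identifier for p in prescriptions],
    )
    if labels is not None:
        frame["disease"] = np.asarray(labels, dtype=int)
    return frame


def read_prescriptions(path, sep: str = "\t") -> list[Prescription]:
    """Read prescriptions from delimited text: ``id<sep>drug;drug;...``."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                ident, drug_field = line.split(sep, maxsplit=1)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: expected 'id{sep}drugs'") from None
            drugs = tuple(d.strip() for d in drug_field.split(";") if d.strip())
            out.append(Prescription(identifier=ident.strip(), drugs=drugs))
    return out


def read_mapping(path, n_groups: int | None = None, sep: str = "\t") -> DrugGroupMapping:
    """Read a drug-group mapping from two-column text (drug, group id).

    Multi-group drugs appear on repeated rows.  ``n_groups`` defaults to
    the largest group index seen.
    """
    pairs: dict[str, set[int]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                drug, group = line.split(sep)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: expected 'drug{sep}group'") from None
            pairs.setdefault(drug.strip(), set()).add(int(group))
    if n_groups is None:
        n_groups = max((g for gs in pairs.values() for g in gs), default=0)
    return DrugGroupMapping(pairs, n_groups=n_groups)
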