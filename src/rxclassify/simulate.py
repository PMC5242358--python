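"""Synthetic prescription-table generator.

Real outpatient prescription tables of the kind this package analyses
(n prescriptions x G drug-group counts, one disease label per row) are not
publicly deposited, so the generator emulates their structure: each disease
class has a binary drug-group signature; a prescription drawn for a class
carries count 1 on each signature group (2 when two drugs of the group were
prescribed together), plus optional unrelated "noise" drug groups; the
catch-all "other diseases" class is heterogeneous and is modelled as a
union of several sub-signatures, one of which a prescription draws on.
Signatures may be forced to overlap pairwise, e.g. an asthma-like class
sharing its steroid group with the respiratory infections hidden inside the
"other" class.

Everything is driven by a single seeded :class:`numpy.random.Generator`
stream, so a configuration reproduces its dataset bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .naive import DiseaseSignatureTable

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "SignatureLayout",
    "GeneratedDataset",
    "generate_signature_table",
    "sample_prescription",
    "generate_dataset",
    "default_config",
    "separable_config",
    "overlap_scenario_config",
    "write_dataset",
    "read_dataset",
    "read_feature_table",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is inconsistent or infeasible."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic prescription-table generator.

    ``signature_sizes`` is either a 2-tuple ``(lo, hi)`` — each class draws
    its signature size uniformly from that range — or an explicit list of
    ``n_classes`` sizes.  ``overlap_pairs`` entries ``(a, b, s)`` force
    classes ``a`` and ``b`` (1-based) to share exactly ``s`` drug groups.
    ``noise_rate`` is the probability that a prescription carries unrelated
    medication; when it does, the number of extra off-signature groups is
    drawn uniformly from ``extra_noise_range``.  ``duplicate_prob`` is the
    probability that a signature group holds two drugs (cell value 2).
    The last class plays the heterogeneous "other diseases" role: its
    signature is split into ``other_subsignatures`` parts and each of its
    prescriptions draws on a single part.
    """

    n_prescriptions: int = 1412
    n_classes: int = 11
    n_groups: int = 60
    signature_sizes: Sequence[int] = (2, 6)
    overlap_pairs: Sequence[tuple[int, int, int]] = ()
    noise_rate: float = 0.75
    extra_noise_range: tuple[int, int] = (1, 2)
    duplicate_prob: float = 0.2
    class_prevalence: Sequence[float] | None = None
    other_subsignatures: int = 3
    seed: int = 0

    def resolved_prevalence(self) -> np.ndarray:
        if self.class_prevalence is None:
            return np.full(self.n_classes, 1.0 / self.n_classes)
        return np.asarray(self.class_prevalence, dtype=float)

    def validate(self) -> None:
        if self.n_prescriptions <= 0:
            raise ConfigurationError("n_prescriptions must be positive")
        if self.n_classes <= 0 or self.n_groups <= 0:
            raise ConfigurationError("n_classes and n_groups must be positive")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ConfigurationError("noise_rate must lie in [0, 1]")
        if not 0.0 <= self.duplicate_prob <= 1.0:
            raise ConfigurationError("duplicate_prob must lie in [0, 1]")
        lo, hi = self.extra_noise_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("extra_noise_range must satisfy 1 <= lo <= hi")
        if self.other_subsignatures < 1:
            raise ConfigurationError("other_subsignatures must be >= 1")
        sizes = list(self.signature_sizes)
        if len(sizes) == 2 and isinstance(self.signature_sizes, tuple):
            if not (1 <= sizes[0] <= sizes[1] <= self.n_groups):
                raise ConfigurationError("signature size range out of bounds")
        elif len(sizes) == self.n_classes:
            if any(not 1 <= s <= self.n_groups for s in sizes):
                raise ConfigurationError("explicit signature sizes out of bounds")
        else:
            raise ConfigurationError(
                "signature_sizes must be a (lo, hi) tuple or one size per class"
            )
        prev = self.resolved_prevalence()
        if prev.shape != (self.n_classes,):
            raise ConfigurationError("class_prevalence must have one entry per class")
        if (prev < 0).any() or abs(prev.sum() - 1.0) > 1e-9:
            raise ConfigurationError("class_prevalence must be non-negative and sum to 1")
        for a, b, s in self.overlap_pairs:
            if not (1 <= a <= self.n_classes and 1 <= b <= self.n_classes) or a == b:
                raise ConfigurationError(f"overlap pair ({a}, {b}) invalid")
            if s < 1:
                raise ConfigurationError("overlap share must be >= 1")

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["signature_sizes"] = list(self.signature_sizes)
        data["overlap_pairs"] = [list(p) for p in self.overlap_pairs]
        data["extra_noise_range"] = list(self.extra_noise_range)
        if self.class_prevalence is not None:
            data["class_prevalence"] = [float(p) for p in self.class_prevalence]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if "overlap_pairs" in data:
            data["overlap_pairs"] = tuple(tuple(p) for p in data["overlap_pairs"])
        if "extra_noise_range" in data:
            data["extra_noise_range"] = tuple(data["extra_noise_range"])
        if "signature_sizes" in data:
            sizes = data["signature_sizes"]
            data["signature_sizes"] = tuple(sizes) if len(sizes) == 2 else list(sizes)
        if data.get("class_prevalence") is not None:
            data["class_prevalence"] = tuple(data["class_prevalence"])
        return cls(**data)


@dataclass
class SignatureLayout:
    """Ground-truth signatures: the binary table plus the sub-signature
    partition of each class (a single part for ordinary diseases, several
    for the heterogeneous last class)."""

    table: DiseaseSignatureTable
    parts: list[list[np.ndarray]]

    def full_signature(self, class_label: int) -> np.ndarray:
        return self.table.signature_indices(class_label)


@dataclass
class GeneratedDataset:
    features: pd.DataFrame  # n x G counts, columns g1..gG
    labels: np.ndarray  # n-vector in 1..K
    layout: SignatureLayout
    config: SimulationConfig

    @property
    def signature_table(self) -> DiseaseSignatureTable:
        return self.layout.table

    def to_frame(self) -> pd.DataFrame:
        frame = self.features.copy()
        frame["disease"] = self.labels
        return frame


def _resolve_sizes(config: SimulationConfig, rng: np.random.Generator):
    """Per-class signature sizes and the part sizes of the last class."""
    K = config.n_classes
    sizes = list(config.signature_sizes)
    if len(sizes) == 2 and isinstance(config.signature_sizes, tuple):
        lo, hi = sizes
        class_sizes = list(rng.integers(lo, hi + 1, size=K))
        if K >= 1 and config.other_subsignatures > 1:
            part_sizes = list(rng.integers(lo, hi + 1, size=config.other_subsignatures))
            class_sizes[K - 1] = int(sum(part_sizes))
        else:
            part_sizes = [class_sizes[K - 1]]
    else:
        class_sizes = [int(s) for s in sizes]
        total = class_sizes[K - 1]
        n_parts = min(config.other_subsignatures, total)
        base, rem = divmod(total, n_parts)
        part_sizes = [base + (1 if i < rem else 0) for i in range(n_parts)]
    return [int(s) for s in class_sizes], part_sizes


def generate_signature_table(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SignatureLayout:
    """Build the ground-truth K x G signature table.

    Groups are taken from a seeded random permutation of ``1..G``: overlap
    requests are carved out first (so they are honoured exactly), then each
    class fills its remaining quota with fresh groups, which keeps all
    non-overlapping assignments disjoint.  Overlap groups with the last
    class land in its first sub-signature.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    K, G = config.n_classes, config.n_groups
    class_sizes, part_sizes = _resolve_sizes(config, rng)

    for a, b, s in config.overlap_pairs:
        if s > min(class_sizes[a - 1], class_sizes[b - 1]):
            raise ConfigurationError(
                f"overlap ({a}, {b}, {s}) exceeds a signature size"
            )
    shared_total = sum(s for _, _, s in config.overlap_pairs)
    distinct_needed = sum(class_sizes) - shared_total
    if distinct_needed > G:
        raise ConfigurationError(
            f"signatures demand {distinct_needed} distinct groups but only {G} exist"
        )

    perm = iter(rng.permutation(G))
    assigned: list[list[int]] = [[] for _ in range(K)]
    shared_with_last: list[int] = []
    for a, b, s in config.overlap_pairs:
        groups = [int(next(perm)) for _ in range(s)]
        assigned[a - 1].extend(groups)
        assigned[b - 1].extend(groups)
        if K in (a, b):
            shared_with_last.extend(groups)
    for c in range(K):
        need = class_sizes[c] - len(assigned[c])
        if need < 0:
            raise ConfigurationError(
                f"class {c + 1} receives more overlap groups than its signature size"
            )
        assigned[c].extend(int(next(perm)) for _ in range(need))

    table = np.zeros((K, G), dtype=np.uint8)
    for c, groups in enumerate(assigned):
        table[c, groups] = 1

    # partition the last class: overlap groups first (into part 0), then fresh
    last = shared_with_last + [g for g in assigned[K - 1] if g not in shared_with_last]
    parts_last: list[np.ndarray] = []
    pos = 0
    for size in part_sizes:
        parts_last.append(np.array(last[pos : pos + size], dtype=int))
        pos += size
    parts_last = [p for p in parts_last if len(p)]
    parts = [[np.array(sorted(assigned[c]), dtype=int)] for c in range(K - 1)]
    parts.append(parts_last)
    return SignatureLayout(table=DiseaseSignatureTable(table), parts=parts)


def sample_prescription(
    class_label: int,
    layout: SignatureLayout,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one count vector of length G for a prescription of ``class_label``."""
    K, G = config.n_classes, config.n_groups
    if not 1 <= class_label <= K:
        raise ValueError(f"class label {class_label} out of range 1..{K}")
    class_parts = layout.parts[class_label - 1]
    part = class_parts[rng.integers(len(class_parts))] if len(class_parts) > 1 else class_parts[0]
    x = np.zeros(G, dtype=np.int64)
    x[part] = 1 + (rng.random(len(part)) < config.duplicate_prob)
    if config.noise_rate > 0 and rng.random() < config.noise_rate:
        lo, hi = config.extra_noise_range
        k = int(rng.integers(lo, hi + 1))
        off = np.setdiff1d(np.arange(G), layout.full_signature(class_label))
        if len(off):
            extra = rng.choice(off, size=min(k, len(off)), replace=False)
            x[extra] = 1
    return x


def generate_dataset(config: SimulationConfig) -> GeneratedDataset:
    """Sample a labelled dataset; reproducible from ``config.seed`` alone."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    layout = generate_signature_table(config, rng)
    prevalence = config.resolved_prevalence()
    labels = rng.choice(
        np.arange(1, config.n_classes + 1), size=config.n_prescriptions, p=prevalence
    )
    X = np.stack(
        [sample_prescription(int(lab), layout, config, rng) for lab in labels]
    )
    features = pd.DataFrame(X, columns=[f"g{i + 1}" for i in range(config.n_groups)])
    return GeneratedDataset(
        features=features, labels=labels.astype(int), layout=layout, config=config
    )


# ---------------------------------------------------------------------------
# Canonical study conditions


def default_config(n_prescriptions: int = 1412, seed: int = 0) -> SimulationConfig:
    """Study conditions emulating an outpatient prescription sample.

    Eleven classes over sixty drug groups at the sample size of the
    motivating study (1412): ten diseases plus a heterogeneous catch-all.
    An asthma-like class (1) shares two of its four groups with the first
    sub-signature of the catch-all (respiratory infections treated with the
    same steroid/bronchodilator groups); two thyroid-like classes (9, 10)
    have single-drug-group signatures; most prescriptions carry one or two
    unrelated medications; a fifth of signature groups hold a duplicated
    drug.  Prevalences are skewed, the catch-all collecting 30% of rows.
    """
    return SimulationConfig(
        n_prescriptions=n_prescriptions,
        n_classes=11,
        n_groups=60,
        signature_sizes=[4, 3, 3, 3, 3, 3, 3, 3, 1, 1, 6],
        overlap_pairs=((1, 11, 2),),
        noise_rate=0.75,
        extra_noise_range=(1, 2),
        duplicate_prob=0.2,
        class_prevalence=(
            0.10, 0.09, 0.09, 0.09, 0.07, 0.06, 0.07, 0.06, 0.03, 0.04, 0.30,
        ),
        other_subsignatures=3,
        seed=seed,
    )


def separable_config(n_prescriptions: int = 1100, seed: int = 0) -> SimulationConfig:
    """Noise-free conditions with pairwise-disjoint signatures.

    Every class is perfectly identifiable from its drug groups, so a
    nearest-signature rule should be error-free; used to check that the
    pipeline recovers a separable structure exactly.
    """
    return SimulationConfig(
        n_prescriptions=n_prescriptions,
        n_classes=11,
        n_groups=60,
        signature_sizes=[3, 3, 3, 3, 3, 3, 3, 3, 2, 2, 6],
        overlap_pairs=(),
        noise_rate=0.0,
        duplicate_prob=0.2,
        class_prevalence=None,
        other_subsignatures=3,
        seed=seed,
    )


def overlap_scenario_config(n_prescriptions: int = 1412, seed: int = 0) -> SimulationConfig:
    """Conditions isolating the asthma-vs-catch-all confusion pattern.

    Class 1 shares half of its four groups with one sub-signature of the
    catch-all class 11, so a third of catch-all prescriptions look like
    richly-matched asthma ones; class 9 keeps a unique single-group
    signature.  Exactly one noise drug is added per noisy prescription:
    with two, a pair of noise groups falling inside one three-group
    signature would outscore a single-group class (2/sqrt(3*3) > 1/sqrt(3)),
    muddying the pattern this scenario is meant to isolate.
    """
    return SimulationConfig(
        n_prescriptions=n_prescriptions,
        n_classes=11,
        n_groups=60,
        signature_sizes=[4, 3, 3, 3, 3, 3, 3, 3, 1, 3, 6],
        overlap_pairs=((1, 11, 2),),
        noise_rate=0.75,
        extra_noise_range=(1, 1),
        duplicate_prob=0.2,
        class_prevalence=(
            0.10, 0.09, 0.09, 0.09, 0.07, 0.06, 0.07, 0.06, 0.03, 0.04, 0.30,
        ),
        other_subsignatures=3,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Text I/O


def write_dataset(dataset: GeneratedDataset, features_path, table_path) -> None:
    """Write features+label and the signature table as TSV."""
    dataset.to_frame().to_csv(features_path, sep="\t", index=False)
    dataset.signature_table.to_tsv(table_path)


def read_feature_table(path) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Read a features TSV; returns (counts frame, labels or None)."""
    frame = pd.read_csv(path, sep="\t")
    labels = None
    if "disease" in frame.columns:
        labels = frame.pop("disease").to_numpy(dtype=int)
    return frame, labels


def read_dataset(features_path, table_path) -> tuple[pd.DataFrame, np.ndarray | None, DiseaseSignatureTable]:
    features, labels = read_feature_table(features_path)
    table = DiseaseSignatureTable.from_tsv(table_path)
    return features, labels, table
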