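"""End-to-end experiment: generate data, evaluate every method, write a bundle.

The workflow mirrors the analysis this package reproduces: a labelled
drug-group count table is generated (or loaded), the shared-group baseline
and the six base classifiers are evaluated by stratified 10-fold
cross-validation, and the three combiners — voting, weighted voting with a
grid-tuned updating rate beta, and stacking — are evaluated fold-aligned on
the same out-of-fold prediction matrix: for each test fold, vote weights
and the stacking meta-learner are learned from the other folds only.  This
keeps every base learner at one fit per fold while preserving the
train/test separation everywhere.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import ensembles, evaluate, learners
from .ensembles import BetaTuneResult, MetaDataset, _MetaLearner
from .learners import ClassifierSpec, make_spec
from .naive import NaiveSharedGroupClassifier
from .simulate import GeneratedDataset, SimulationConfig, default_config, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ExperimentResult", "run_experiment", "plot_comparison"]

ALL_METHODS = ("naive", "base", "voting", "weighted_voting", "stacking")


@dataclass
class RunConfig:
    """Fully resolved settings of one experiment run."""

    simulation: SimulationConfig = field(default_factory=default_config)
    classifier_names: Sequence[str] = learners.CLASSIFIER_NAMES
    classifier_overrides: Mapping[str, Mapping] = field(default_factory=dict)
    methods: Sequence[str] = ALL_METHODS
    folds: int = 10
    beta_grid: tuple[float, float, float] = (0.1, 1.0, 0.01)  # start, stop, step
    meta_learner: Mapping = field(
        default_factory=lambda: {"name": "knn", "overrides": {"k": 3}}
    )
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        self.simulation.validate()
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        for name in self.classifier_names:
            if name not in learners.CLASSIFIER_NAMES:
                raise ValueError(f"unknown classifier {name!r}")
        if self.folds < 2:
            raise ValueError("folds must be at least 2")
        start, stop, step = self.beta_grid
        if not (0.0 < start <= stop <= 1.0) or step <= 0:
            raise ValueError("beta grid must satisfy 0 < start <= stop <= 1, step > 0")

    def resolved_beta_grid(self) -> list[float]:
        start, stop, step = self.beta_grid
        n = int(round((stop - start) / step))
        grid = [round(start + i * step, 10) for i in range(n + 1)]
        return [b for b in grid if b <= 1.0 + 1e-12]

    def base_specs(self) -> list[ClassifierSpec]:
        return [
            make_spec(name, self.classifier_overrides.get(name), seed=self.seed)
            for name in self.classifier_names
        ]

    def meta_spec(self) -> ClassifierSpec:
        return make_spec(
            self.meta_learner.get("name", "knn"),
            self.meta_learner.get("overrides", {"k": 3}),
            seed=self.seed,
        )

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["simulation"] = dataclasses.asdict(self.simulation)
        sim = data["simulation"]
        sim["signature_sizes"] = list(self.simulation.signature_sizes)
        sim["overlap_pairs"] = [list(p) for p in self.simulation.overlap_pairs]
        sim["extra_noise_range"] = list(self.simulation.extra_noise_range)
        if self.simulation.class_prevalence is not None:
            sim["class_prevalence"] = [float(p) for p in self.simulation.class_prevalence]
        data["classifier_names"] = list(self.classifier_names)
        data["methods"] = list(self.methods)
        data["beta_grid"] = list(self.beta_grid)
        data["classifier_overrides"] = {
            k: dict(v) for k, v in self.classifier_overrides.items()
        }
        data["meta_learner"] = dict(self.meta_learner)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        sim = data.pop("simulation", None)
        if sim is not None:
            if "overlap_pairs" in sim:
                sim["overlap_pairs"] = tuple(tuple(p) for p in sim["overlap_pairs"])
            if "extra_noise_range" in sim:
                sim["extra_noise_range"] = tuple(sim["extra_noise_range"])
            if "signature_sizes" in sim and len(sim["signature_sizes"]) == 2:
                sim["signature_sizes"] = tuple(sim["signature_sizes"])
            if sim.get("class_prevalence") is not None:
                sim["class_prevalence"] = tuple(sim["class_prevalence"])
            data["simulation"] = SimulationConfig(**sim)
        if "beta_grid" in data:
            data["beta_grid"] = tuple(data["beta_grid"])
        return cls(**data)


@dataclass
class ExperimentResult:
    config: RunConfig
    dataset: GeneratedDataset
    reports: dict[str, evaluate.EvaluationReport]
    meta: MetaDataset | None = None
    beta_result: BetaTuneResult | None = None
    weights: ensembles.EnsembleWeights | None = None
    timings: dict[str, float] = field(default_factory=dict)

    def comparison(self) -> pd.DataFrame:
        rows = []
        for name, rep in self.reports.items():
            macro = rep.macro
            rows.append(
                {
                    "method": name,
                    "accuracy": rep.accuracy,
                    "sensitivity": macro["sensitivity"],
                    "specificity": macro["specificity"],
                    "precision": macro["precision"],
                }
            )
        return pd.DataFrame(rows).set_index("method").round(2)

    def summary(self) -> str:
        lines = [
            f"n={self.dataset.config.n_prescriptions}  K={self.dataset.config.n_classes}"
            f"  G={self.dataset.config.n_groups}  folds={self.config.folds}"
            f"  seed={self.config.seed}"
        ]
        if self.beta_result is not None:
            lines.append(f"selected beta: {self.beta_result.best_beta:.2f}")
        lines.append(self.comparison().to_string())
        return "\n".join(lines)


def _stacked_fold_aligned(
    meta: MetaDataset, meta_spec: ClassifierSpec, n_classes: int
) -> np.ndarray:
    """Out-of-fold meta-learner predictions over the meta-dataset."""
    preds = np.zeros_like(meta.y)
    for j in np.unique(meta.fold):
        test = meta.fold == j
        learner = _MetaLearner(meta_spec, n_classes=n_classes)
        learner.fit(meta.predictions[~test], meta.y[~test])
        preds[test] = learner.predict(meta.predictions[test])
    return preds


def run_experiment(
    config: RunConfig, output_dir: str | None = None
) -> ExperimentResult:
    """Run every enabled method on one generated dataset; optionally write
    the full bundle (resolved config, per-method reports, weights, beta
    table, comparison table) as delimited text."""
    config.validate()
    out = Path(output_dir or config.output_dir) if (output_dir or config.output_dir) else None

    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    dataset = generate_dataset(config.simulation)
    X = dataset.features.to_numpy(dtype=float)
    y = dataset.labels
    K = config.simulation.n_classes
    timings["simulate"] = time.perf_counter() - t0
    logger.info("generated dataset: n=%d, K=%d, G=%d", len(y), K, X.shape[1])

    reports: dict[str, evaluate.EvaluationReport] = {}
    meta: MetaDataset | None = None
    beta_result: BetaTuneResult | None = None
    weights: ensembles.EnsembleWeights | None = None

    if "naive" in config.methods:
        t0 = time.perf_counter()
        clf = NaiveSharedGroupClassifier(dataset.signature_table).fit(X)
        reports["naive"] = evaluate.report_from_predictions(
            "naive", y, clf.predict(X), n_classes=K, seed=config.seed
        )
        timings["naive"] = time.perf_counter() - t0

    need_meta = bool({"base", "voting", "weighted_voting", "stacking"} & set(config.methods))
    if need_meta:
        t0 = time.perf_counter()
        meta = ensembles.build_meta_dataset(
            config.base_specs(), X, y, J=config.folds, seed=config.seed
        )
        timings["base_fits"] = time.perf_counter() - t0

    if "base" in config.methods:
        for col, name in enumerate(meta.classifier_names):
            reports[name] = evaluate.report_from_predictions(
                name,
                y,
                meta.predictions[:, col],
                n_classes=K,
                folds=config.folds,
                seed=config.seed,
                fold_assignment=meta.fold,
            )

    if "voting" in config.methods:
        t0 = time.perf_counter()
        preds = ensembles.fold_aligned_vote(meta, beta=1.0, n_classes=K)
        reports["voting"] = evaluate.report_from_predictions(
            "voting", y, preds, n_classes=K, folds=config.folds, seed=config.seed
        )
        timings["voting"] = time.perf_counter() - t0

    if "weighted_voting" in config.methods:
        t0 = time.perf_counter()
        beta_result = ensembles.tune_beta(
            config.base_specs(),
            X,
            y,
            grid=config.resolved_beta_grid(),
            cv_folds=config.folds,
            seed=config.seed,
            meta=meta,
        )
        preds = ensembles.fold_aligned_vote(meta, beta_result.best_beta, n_classes=K)
        reports["weighted_voting"] = evaluate.report_from_predictions(
            "weighted_voting", y, preds, n_classes=K, folds=config.folds, seed=config.seed
        )
        weights = ensembles.learn_weights(meta.predictions, y, beta_result.best_beta)
        timings["weighted_voting"] = time.perf_counter() - t0

    if "stacking" in config.methods:
        t0 = time.perf_counter()
        preds = _stacked_fold_aligned(meta, config.meta_spec(), n_classes=K)
        reports["stacking"] = evaluate.report_from_predictions(
            "stacking", y, preds, n_classes=K, folds=config.folds, seed=config.seed
        )
        timings["stacking"] = time.perf_counter() - t0

    result = ExperimentResult(
        config=config,
        dataset=dataset,
        reports=reports,
        meta=meta,
        beta_result=beta_result,
        weights=weights,
        timings=timings,
    )

    if out is not None:
        _write_bundle(result, out)
    return result


def _write_bundle(result: ExperimentResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out / "config.yaml")
    from .simulate import write_dataset

    write_dataset(result.dataset, out / "features.tsv", out / "signatures.tsv")
    for name, report in result.reports.items():
        report.write(out / "reports" / name)
    result.comparison().to_csv(out / "comparison.tsv", sep="\t")
    if result.weights is not None and result.meta is not None:
        result.weights.to_frame(result.meta.classifier_names).to_csv(
            out / "weights.tsv", sep="\t", index=False
        )
    if result.beta_result is not None:
        result.beta_result.table.to_csv(out / "beta_search.tsv", sep="\t", index=False)
        (out / "beta_selected.txt").write_text(
            f"{result.beta_result.best_beta:.2f}\n", encoding="utf-8"
        )
    timing = pd.Series(result.timings, name="seconds").round(3)
    timing.to_csv(out / "timings.tsv", sep="\t", header=True)
    (out / "summary.txt").write_text(result.summary() + "\n", encoding="utf-8")
    logger.info("experiment bundle written to %s", out)


def plot_comparison(result: ExperimentResult, path=None):
    """Grouped bar chart of accuracy and macro metrics per method."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = result.comparison()
    ax = frame.plot.bar(figsize=(10, 5), rot=30)
    ax.set_ylabel("percent")
    ax.set_ylim(0, 105)
    ax.legend(loc="lower right")
    ax.figure.tight_layout()
    if path is not None:
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax
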