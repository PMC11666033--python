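"""End-to-end study driver: sweep, evaluate, analyze, serialize.

``run_study`` chains the whole analysis from one configuration: build or
load the base dataset, run the constant-n prevalence sweep, fit every
model on every dataset, evaluate every metric at the 0.5 cutoff (AUC over
all thresholds), rank models, compute value- and rank-variances and the
variance-homogeneity tests, run the all-thresholds analysis, and write
every table as CSV plus a JSON summary and a run manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifiers import (ClassifierSpec, Dataset, FAMILIES, SplitSpec)
from .confusion import STUDY_METRICS
from .consistency import (RANDOM_GUESS, EvaluationTable, MetricGroups,
                          evaluate_predictions, rank_table, ranking_variance,
                          score_series, variance_equality_tests)
from .sweep import SweepConfig, correlation_drift, run_sweep
from .synthetic import GeneratorConfig, generate_dataset
from .thresholds import incremental_average, metric_threshold_grid, ols_slope

__all__ = ["StudyConfig", "StudyResult", "run_study"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to reproduce one full study run."""

    input_csv: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    model_families: tuple[str, ...] = FAMILIES
    include_random_guess: bool = True
    cv_folds: int = 10
    metrics: tuple[str, ...] = STUDY_METRICS
    threshold_mode: str = "unique-scores"
    threshold_grid_size: int = 201
    write_threshold_grid: bool = False
    out_dir: str = "study_output"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        kw = dict(raw)
        if "generator" in kw:
            kw["generator"] = GeneratorConfig(**kw["generator"])
        if "sweep" in kw:
            kw["sweep"] = SweepConfig(**kw["sweep"])
        if "split" in kw:
            kw["split"] = SplitSpec(**kw["split"])
        for key in ("model_families", "metrics"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)

    def with_seed(self, seed: int) -> "StudyConfig":
        """Re-derive every component seed from one global seed."""
        ss = np.random.SeedSequence(seed)
        g, sw, sp = (int(s.generate_state(1)[0] % (2 ** 31))
                     for s in ss.spawn(3))
        gen = GeneratorConfig(**{**asdict(self.generator), "seed": g})
        sweep = SweepConfig(**{**asdict(self.sweep), "seed": sw})
        split = SplitSpec(train_fraction=self.split.train_fraction, seed=sp)
        return StudyConfig(**{**asdict(self), "generator": gen, "sweep": sweep,
                              "split": split, "seed": seed})

    def models(self) -> dict[str, ClassifierSpec | None]:
        out: dict[str, ClassifierSpec | None] = {
            fam: ClassifierSpec(family=fam, cv_folds=self.cv_folds)
            for fam in self.model_families
        }
        if self.include_random_guess:
            out[RANDOM_GUESS] = None
        return out


def _asdict_config(cfg: StudyConfig) -> dict:
    d = asdict(cfg)
    return d


@dataclass
class StudyResult:
    """In-memory handles to every table the study writes."""

    series_summary: pd.DataFrame
    drift: pd.DataFrame
    evaluation: EvaluationTable
    ranks: pd.DataFrame
    variances: pd.DataFrame
    variance_tests: dict
    aggregation_curves: pd.DataFrame
    slopes: pd.DataFrame
    out_dir: Path


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"study stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def load_base_dataset(cfg: StudyConfig) -> Dataset:
    if cfg.input_csv is not None:
        df = pd.read_csv(cfg.input_csv)
        if "label" not in df.columns:
            raise ValueError("input CSV must have a binary 'label' column")
        return Dataset.from_frame(df)
    return generate_dataset(cfg.generator)


def run_study(cfg: StudyConfig) -> StudyResult:
    """Run the full pipeline and serialize every artifact under cfg.out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()

    data = _stage("load")(load_base_dataset)(cfg)
    full_prevalence = data.prevalence
    series = _stage("sweep")(run_sweep)(data, cfg.sweep)
    summary = series.summary()
    summary.to_csv(out / "sweep_summary.csv", index=False)

    drift = _stage("correlation_drift")(correlation_drift)(series)
    drift.to_csv(out / "correlation_drift.csv", index=False)

    predictions = _stage("fit_and_score")(score_series)(
        series, cfg.models(), cfg.split)

    table = _stage("evaluate")(evaluate_predictions)(predictions, cfg.metrics)
    table.table.to_csv(out / "metric_values.csv", index=False)

    ranks = _stage("rank")(rank_table)(table)
    ranks.to_csv(out / "model_ranks.csv", index=False)

    variances = _stage("variance")(ranking_variance)(table)
    variances.to_csv(out / "ranking_variance.csv", index=False)

    groups = MetricGroups(
        sensitive=MetricGroups().sensitive & set(cfg.metrics),
        insensitive=MetricGroups().insensitive & set(cfg.metrics))
    tests = {
        "values": _stage("variance_tests_values")(variance_equality_tests)(
            table, groups),
        "ranks": _stage("variance_tests_ranks")(variance_equality_tests)(
            ranks, groups, value_col="rank"),
    }
    (out / "variance_tests.json").write_text(json.dumps(tests, indent=2))

    grid = _stage("threshold_grid")(metric_threshold_grid)(
        predictions, cfg.metrics, mode=cfg.threshold_mode)
    if cfg.write_threshold_grid:
        grid.to_frame().to_csv(out / "threshold_grid.csv", index=False)
    curves = _stage("incremental_average")(incremental_average)(grid)
    curves.to_csv(out / "aggregation_curves.csv", index=False)
    slopes = _stage("ols_slope")(ols_slope)(curves)
    slopes.to_csv(out / "threshold_slopes.csv", index=False)

    # Prevalence is reported twice: for the full sample and for the test
    # sets the metrics are actually computed on (the operative one).
    test_prev = {int(k[0]): float(p.labels.mean())
                 for k, p in predictions.items()}
    manifest = {
        "package_version": __version__,
        "config": _asdict_config(cfg),
        "n_datasets": len(series),
        "n_models": len(cfg.models()),
        "n_metrics": len(cfg.metrics),
        "full_sample_prevalence": full_prevalence,
        "test_set_prevalence": test_prev,
        "prevalence_used_by_metrics": "test_set",
        "undefined_cells": table.n_undefined,
        "runtime_seconds": time.perf_counter() - t_start,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    auc_var = (variances[variances["metric"] == "AUC"]["rank_variance"].mean()
               if "AUC" in cfg.metrics else None)
    summary_json = {
        "n_datasets": len(series),
        "prevalence_range": [float(series.prevalences.min()),
                             float(series.prevalences.max())],
        "mean_rank_variance_by_metric": (
            variances.groupby("metric")["rank_variance"].mean()
            .sort_values().to_dict()),
        "auc_mean_rank_variance": auc_var,
        "variance_tests": tests,
        "negative_significant_slopes": int(
            ((slopes["slope"] < 0) & (slopes["p_value"] < 0.05)).sum()),
        "n_slopes": len(slopes),
    }
    (out / "summary.json").write_text(json.dumps(summary_json, indent=2))

    return StudyResult(series_summary=summary, drift=drift, evaluation=table,
                       ranks=ranks, variances=variances, variance_tests=tests,
                       aggregation_curves=curves, slopes=slopes, out_dir=out)
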