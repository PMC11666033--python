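"""Model evaluation across the sweep, rank tables and consistency measures.

The study's operational measure of a metric's consistency is the variance,
across datasets of different prevalence, of (a) the metric's value for each
model and (b) the rank it assigns each model within the candidate set.
Confusion-matrix metrics are computed at the 0.5 cutoff; AUC is computed
over all thresholds by construction.  Homogeneity of variance between
prevalence-sensitive and -insensitive metric groups is tested with an
F-test on the pooled groups and Bartlett/Levene tests on the metric-type x
model interaction cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .classifiers import (ClassifierSpec, Dataset, SplitSpec, fit_predict,
                          random_guess, split_train_test)
from .confusion import (MetricValue, ScoredPredictions, auc_rank,
                        confusion_at_threshold, get_metric_spec,
                        metric_from_confusion, STUDY_METRICS)
from .sweep import SweepSeries

__all__ = [
    "RANDOM_GUESS",
    "MetricGroups",
    "EvaluationTable",
    "score_series",
    "evaluate_predictions",
    "evaluate_grid",
    "rank_models",
    "rank_table",
    "ranking_variance",
    "variance_equality_tests",
]

log = logging.getLogger(__name__)

#: Model name reserved for the prevalence-matched random-guess baseline.
RANDOM_GUESS = "randomguess"

#: Metrics found to track prevalence almost monotonically.
DEFAULT_SENSITIVE = frozenset({"F1", "F0.5", "F2", "JI", "TPR", "TNR", "FM"})


@dataclass(frozen=True)
class MetricGroups:
    """Disjoint sensitive / insensitive metric-name groups for the tests.

    The sensitive set defaults to the metrics with a near-monotone
    prevalence relationship (the three F-scores, Jaccard, TPR, TNR,
    Fowlkes-Mallows); the insensitive set defaults to the remaining study
    metrics.  Both are overridable.
    """

    sensitive: frozenset[str] = DEFAULT_SENSITIVE
    insensitive: frozenset[str] = field(
        default=frozenset(STUDY_METRICS) - DEFAULT_SENSITIVE)

    def __post_init__(self) -> None:
        if self.sensitive & self.insensitive:
            raise ValueError("sensitive and insensitive groups must be disjoint")
        if not self.sensitive or not self.insensitive:
            raise ValueError("both groups must be non-empty")


@dataclass(frozen=True)
class EvaluationTable:
    """Metric value per (dataset, model, metric), long form.

    ``table`` columns: dataset (iteration id), prevalence (of the test
    set), model, metric, value (NaN when UNDEFINED), reason (zero-
    denominator tag or None).
    """

    table: pd.DataFrame

    def defined(self) -> pd.DataFrame:
        return self.table[self.table["value"].notna()]

    @property
    def n_undefined(self) -> int:
        return int(self.table["value"].isna().sum())

    def pivot(self, metric: str) -> pd.DataFrame:
        """dataset x model matrix of one metric's values."""
        sub = self.table[self.table["metric"] == metric]
        return sub.pivot(index="dataset", columns="model", values="value")

    @property
    def models(self) -> list[str]:
        return sorted(self.table["model"].unique())

    @property
    def metrics(self) -> list[str]:
        return list(dict.fromkeys(self.table["metric"]))


def _dataset_seed(base: int, dataset_id: int) -> int:
    # stable per-dataset derivation, kept within 2**31
    ss = np.random.SeedSequence([base, dataset_id + 10_000])
    return int(ss.generate_state(1)[0] % (2**31))


def score_series(
    series: SweepSeries | Sequence[Dataset],
    models: Mapping[str, ClassifierSpec | None],
    split: SplitSpec,
) -> dict[tuple[int, str], ScoredPredictions]:
    """Split, fit and score every (dataset, model) pair of the study.

    ``models`` maps a display name to a :class:`ClassifierSpec`, or to None
    for the random-guess baseline (conventionally named ``randomguess``),
    whose assignment prevalence is the realized test-set prevalence.
    Each dataset gets its own derived split seed so sweep iterations are
    split independently, reproducibly from ``split.seed``.
    """
    out: dict[tuple[int, str], ScoredPredictions] = {}
    for data in series:
        dseed = _dataset_seed(split.seed, data.id)
        train, test = split_train_test(
            data, SplitSpec(train_fraction=split.train_fraction, seed=dseed))
        phi_test = test.labels.mean()
        for name, spec in models.items():
            if spec is None:
                out[(data.id, name)] = random_guess(
                    test.labels, phi_test, seed=dseed + 1)
            else:
                out[(data.id, name)] = fit_predict(
                    ClassifierSpec(family=spec.family,
                                   hyperparameter_grid=spec.hyperparameter_grid,
                                   cv_folds=spec.cv_folds, seed=dseed),
                    train, test)
        log.info("dataset %d scored (test prevalence %.3f)", data.id, phi_test)
    return out


def evaluate_predictions(
    predictions: Mapping[tuple[int, str], ScoredPredictions],
    metrics: Sequence[str] = STUDY_METRICS,
    threshold: float = 0.5,
) -> EvaluationTable:
    """Compute every metric for every scored (dataset, model) pair.

    Confusion-matrix metrics use the single ``threshold`` cutoff; AUC uses
    the full score ranking (all thresholds).
    """
    rows = []
    for (dataset_id, model), preds in predictions.items():
        cm = confusion_at_threshold(preds, threshold)
        prevalence = preds.labels.mean()
        for metric in metrics:
            if get_metric_spec(metric).name == "AUC":
                mv = MetricValue.of(auc_rank(preds))
            else:
                mv = metric_from_confusion(metric, cm)
            rows.append({
                "dataset": dataset_id,
                "prevalence": prevalence,
                "model": model,
                "metric": metric,
                "value": mv.value if mv.defined else np.nan,
                "reason": mv.reason,
            })
    table = EvaluationTable(table=pd.DataFrame(rows))
    if table.n_undefined:
        log.info("evaluation grid: %d UNDEFINED cells", table.n_undefined)
    return table


def evaluate_grid(
    series: SweepSeries | Sequence[Dataset],
    models: Mapping[str, ClassifierSpec | None],
    metrics: Sequence[str] = STUDY_METRICS,
    split: SplitSpec = SplitSpec(),
) -> EvaluationTable:
    """End-to-end: fit + score every dataset, then evaluate every metric."""
    return evaluate_predictions(score_series(series, models, split), metrics)


def rank_models(values: Mapping[str, MetricValue | float],
                orientation: str = "higher-better") -> dict[str, float]:
    """Rank a set of models under one metric with average tie-breaking.

    Rank 1 is best under ``orientation``; tied values share the average of
    their positions; UNDEFINED values are ranked last (tied among
    themselves).  Raises if no value is defined.
    """
    if orientation not in ("higher-better", "lower-better"):
        raise ValueError(f"bad orientation {orientation!r}")
    names = list(values)
    raw = []
    for name in names:
        v = values[name]
        raw.append(v.value if isinstance(v, MetricValue) else
                   (float(v) if v is not None and not pd.isna(v) else None))
    if all(v is None for v in raw):
        raise ValueError("cannot rank: every value is UNDEFINED")
    sign = -1.0 if orientation == "higher-better" else 1.0
    keyed = np.array([sign * v if v is not None else np.inf for v in raw])
    ranks = st.rankdata(keyed, method="average")
    return dict(zip(names, ranks.tolist()))


def rank_table(table: EvaluationTable) -> pd.DataFrame:
    """Per (dataset, metric): ranks of all models, long form."""
    rows = []
    for (dataset, metric), sub in table.table.groupby(
            ["dataset", "metric"], sort=False):
        orientation = get_metric_spec(metric).orientation
        vals = dict(zip(sub["model"], sub["value"]))
        ranks = rank_models(vals, orientation)
        prevalence = sub["prevalence"].iloc[0]
        for model, rank in ranks.items():
            rows.append({"dataset": dataset, "prevalence": prevalence,
                         "metric": metric, "model": model, "rank": rank})
    return pd.DataFrame(rows)


def ranking_variance(table: EvaluationTable) -> pd.DataFrame:
    """Sample variance, across datasets, of each (metric, model)'s value and rank.

    UNDEFINED values are excluded pairwise from the value variance (the
    exclusion count is logged); ranks are always defined because UNDEFINED
    entries rank last.
    """
    ranks = rank_table(table)
    var_rank = (ranks.groupby(["metric", "model"])["rank"]
                .agg(rank_variance="var", n_rank="count").reset_index())
    vals = table.table
    excluded = int(vals["value"].isna().sum())
    if excluded:
        log.info("ranking_variance: %d UNDEFINED cells excluded from "
                 "value variances", excluded)
    var_val = (vals.groupby(["metric", "model"])["value"]
               .agg(value_variance="var", n_value="count").reset_index())
    return var_rank.merge(var_val, on=["metric", "model"])


def _interaction_groups(long: pd.DataFrame,
                        groups: MetricGroups,
                        value_col: str) -> tuple[list[np.ndarray], list[str]]:
    samples, labels = [], []
    for gname, metric_set in (("sensitive", groups.sensitive),
                              ("insensitive", groups.insensitive)):
        sub = long[long["metric"].isin(metric_set)]
        for model, cell in sub.groupby("model"):
            x = cell[value_col].dropna().to_numpy()
            if len(x) >= 2:
                samples.append(x)
                labels.append(f"{gname}:{model}")
    return samples, labels


def variance_equality_tests(
    long: EvaluationTable | pd.DataFrame,
    groups: MetricGroups = MetricGroups(),
    value_col: str | None = None,
) -> dict:
    """Test equality of variance between metric-type groups.

    The F-test compares the pooled sensitive-group variance with the pooled
    insensitive-group variance (two-sided); each metric-type x model
    interaction cell is mean-centered first, so the pooled variances measure
    dispersion across prevalence rather than level differences between
    models.  Bartlett and Levene tests run on the interaction cells
    directly (both are location-free within cells).  Accepts an
    :class:`EvaluationTable` (uses the ``value`` column) or any long frame
    with ``metric``, ``model`` and a value column (e.g. a rank table with
    ``rank``).
    """
    if isinstance(long, EvaluationTable):
        frame = long.table
        value_col = value_col or "value"
    else:
        frame = long
        if value_col is None:
            value_col = "rank" if "rank" in frame.columns else "value"

    centered = frame[value_col] - frame.groupby(["metric", "model"])[
        value_col].transform("mean")
    sens = centered[frame["metric"].isin(groups.sensitive)].dropna()
    insens = centered[frame["metric"].isin(groups.insensitive)].dropna()
    if len(sens) < 2 or len(insens) < 2:
        raise ValueError("each pooled group needs at least 2 defined values")

    v1, v2 = sens.var(ddof=1), insens.var(ddof=1)
    degenerate = [name for name, v in (("sensitive", v1), ("insensitive", v2))
                  if v == 0]
    if degenerate:
        log.warning("zero-variance pooled group(s): %s", degenerate)
    f_stat = v1 / v2 if v2 > 0 else np.inf
    df1, df2 = len(sens) - 1, len(insens) - 1
    cdf = st.f.cdf(f_stat, df1, df2)
    f_p = float(2 * min(cdf, 1 - cdf))

    samples, labels = _interaction_groups(frame, groups, value_col)
    zero_var_cells = [lab for lab, x in zip(labels, samples) if np.var(x) == 0]
    if zero_var_cells:
        log.warning("zero-variance interaction cells: %s", zero_var_cells)
    usable = [x for x in samples if np.var(x) > 0]
    if len(usable) >= 2:
        bart = st.bartlett(*usable)
        bart_res = {"statistic": float(bart.statistic),
                    "p_value": float(bart.pvalue)}
    else:
        log.warning("fewer than 2 non-degenerate cells; Bartlett undefined")
        bart_res = {"statistic": float("nan"), "p_value": float("nan")}
    lev = st.levene(*samples)

    return {
        "f_test": {"statistic": float(f_stat), "p_value": f_p,
                   "df": (df1, df2)},
        "bartlett": bart_res,
        "levene": {"statistic": float(lev.statistic),
                   "p_value": float(lev.pvalue)},
        "groups": labels,
        "degenerate_cells": zero_var_cells,
    }
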