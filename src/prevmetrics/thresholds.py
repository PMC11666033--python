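"""All-thresholds analysis: metric grids, incremental averaging, OLS slopes.

The hypothesis under test is that AUC evaluates consistently across
prevalence because it integrates over every decision threshold.  To probe
it, every confusion-matrix metric is evaluated on a grid of thresholds
ordered by distance from 0.5, metric values are averaged over growing
threshold prefixes, and the variance (across datasets of different
prevalence) of those averages is regressed on the number of thresholds
used.  A negative, significant slope means more thresholds buy more
consistency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .confusion import (ScoredPredictions, auc_rank, get_metric_spec,
                        STUDY_METRICS)

__all__ = [
    "ThresholdSet",
    "ThresholdGrid",
    "threshold_sequence",
    "metric_threshold_grid",
    "incremental_average",
    "ols_slope",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdSet:
    """Thresholds ordered by |t - 0.5| ascending, 0.5 first.

    Ties in distance are broken toward the smaller threshold, so the
    ordering is fully deterministic.
    """

    thresholds: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if t.ndim != 1 or len(t) == 0:
            raise ValueError("thresholds must be a non-empty 1-d sequence")
        if np.any((t < 0) | (t > 1)):
            raise ValueError("thresholds must lie in [0, 1]")
        order = np.lexsort((t, np.abs(t - 0.5)))
        object.__setattr__(self, "thresholds", t[order])

    def __len__(self) -> int:
        return len(self.thresholds)

    def __iter__(self):
        return iter(self.thresholds)


def threshold_sequence(preds: ScoredPredictions | np.ndarray,
                       mode: str = "unique-scores",
                       grid_size: int = 201) -> ThresholdSet:
    """Build the threshold ordering for one prediction set.

    ``unique-scores`` takes 0.5 plus every distinct predicted score (the
    all-possible-thresholds set); ``uniform-grid`` is an evenly spaced
    fallback of ``grid_size`` points for models emitting few distinct
    scores.
    """
    scores = preds.scores if isinstance(preds, ScoredPredictions) else np.asarray(preds)
    if mode == "unique-scores":
        t = np.union1d(np.unique(scores), [0.5])
    elif mode == "uniform-grid":
        t = np.union1d(np.linspace(0.0, 1.0, grid_size), [0.5])
    else:
        raise ValueError(f"mode must be 'unique-scores' or 'uniform-grid', got {mode!r}")
    return ThresholdSet(thresholds=t)


# ---------------------------------------------------------------------------
# Vectorized count-form metrics over threshold arrays
# ---------------------------------------------------------------------------

def _div(a, b):
    b = np.asarray(b, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.asarray(a, dtype=float) / b
    return np.where(b != 0, out, np.nan)


def metric_vector(name: str, tp, fn, tn, fp, beta: float | None = None):
    """One metric evaluated elementwise on arrays of confusion counts.

    Undefined cells (zero denominator) come back as NaN; agreement with the
    scalar :func:`~prevmetrics.confusion.metric_from_confusion` path is a
    tested invariant.
    """
    tp, fn, tn, fp = (np.asarray(x, dtype=float) for x in (tp, fn, tn, fp))
    n = tp + fn + tn + fp
    pos, neg = tp + fn, tn + fp
    tpr, tnr = _div(tp, pos), _div(tn, neg)
    ppv, npv = _div(tp, tp + fp), _div(tn, tn + fn)
    if name == "TP":
        return tp
    if name == "FN":
        return fn
    if name == "TN":
        return tn
    if name == "FP":
        return fp
    if name == "TPR":
        return tpr
    if name == "TNR":
        return tnr
    if name == "PPV":
        return ppv
    if name == "NPV":
        return npv
    if name == "FPR":
        return 1 - tnr
    if name == "FNR":
        return 1 - tpr
    if name == "FOR":
        return 1 - npv
    if name == "FDR":
        return 1 - ppv
    if name == "accuracy":
        return _div(tp + tn, n)
    if name == "BA":
        return (tpr + tnr) / 2
    if name == "BI":
        return tpr + tnr - 1
    if name == "MK":
        return ppv + npv - 1
    if name == "Gmean":
        return np.sqrt(tpr * tnr)
    if name == "JI":
        return _div(tp, tp + fn + fp)
    if name == "DOR":
        return _div(tpr * tnr, (1 - tpr) * (1 - tnr))
    if name == "FM":
        return np.sqrt(ppv * tpr)
    if name == "kappa":
        exp_acc = _div(pos * (tp + fp) + neg * (tn + fn), n ** 2)
        return _div(_div(tp + tn, n) - exp_acc, 1 - exp_acc)
    if name == "F1":
        return _div(2 * tp, 2 * tp + fp + fn)
    spec = get_metric_spec(name)
    if spec.formula_id == "Fbeta":
        b2 = (beta if beta is not None else spec.beta) ** 2
        return _div((1 + b2) * ppv * tpr, b2 * ppv + tpr)
    if name == "MCC":
        denom = np.sqrt((tp + fp) * pos * neg * (tn + fn))
        return _div(tp * tn - fp * fn, denom)
    raise KeyError(f"no vectorized form for metric {name!r}")


def _counts_at_thresholds(preds: ScoredPredictions, thresholds: np.ndarray):
    """Confusion counts at every threshold under the score >= t rule."""
    pos_scores = np.sort(preds.scores[preds.labels == 1])
    neg_scores = np.sort(preds.scores[preds.labels == 0])
    tp = len(pos_scores) - np.searchsorted(pos_scores, thresholds, side="left")
    fp = len(neg_scores) - np.searchsorted(neg_scores, thresholds, side="left")
    fn = len(pos_scores) - tp
    tn = len(neg_scores) - fp
    return tp, fn, tn, fp


@dataclass(frozen=True)
class ThresholdGrid:
    """Metric value per (threshold, dataset, metric, model).

    ``values[(metric, model)]`` is a (n_thresholds, n_datasets) array in
    the ThresholdSet ordering; UNDEFINED cells are NaN, never dropped.
    """

    thresholds: ThresholdSet
    dataset_ids: list[int]
    values: dict[tuple[str, str], np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (metric, model), arr in self.values.items():
            for ti, t in enumerate(self.thresholds.thresholds):
                for di, ds in enumerate(self.dataset_ids):
                    rows.append({"threshold": t, "dataset": ds,
                                 "metric": metric, "model": model,
                                 "value": arr[ti, di]})
        return pd.DataFrame(rows)


def metric_threshold_grid(
    predictions: Mapping[tuple[int, str], ScoredPredictions] | Mapping[int, ScoredPredictions],
    metrics: Sequence[str] = STUDY_METRICS,
    thresholds: ThresholdSet | None = None,
    mode: str = "unique-scores",
    max_thresholds: int = 1500,
) -> ThresholdGrid:
    """Evaluate every metric at every threshold for every prediction set.

    ``predictions`` is keyed by (dataset id, model name) — single-model
    mappings keyed by dataset id are wrapped under model ``"model"``.  When
    ``thresholds`` is omitted, the set is built from the union of all
    predicted scores (``mode="unique-scores"``) or a uniform grid.  AUC
    cells are constant across thresholds by construction.
    """
    preds: dict[tuple[int, str], ScoredPredictions] = {}
    for key, p in predictions.items():
        preds[key if isinstance(key, tuple) else (key, "model")] = p
    if not preds:
        raise ValueError("no predictions supplied")

    if thresholds is None:
        all_scores = np.concatenate([p.scores for p in preds.values()])
        thresholds = threshold_sequence(all_scores, mode=mode)
        if len(thresholds) > max_thresholds:
            # thin to evenly spaced quantiles of the pooled score set,
            # keeping 0.5; preserves the all-thresholds span at bounded cost
            t_sorted = np.sort(thresholds.thresholds)
            idx = np.unique(np.linspace(0, len(t_sorted) - 1,
                                        max_thresholds).round().astype(int))
            thresholds = ThresholdSet(np.union1d(t_sorted[idx], [0.5]))
            log.info("threshold set thinned to %d of %d candidates",
                     len(thresholds), len(t_sorted))
    tarr = thresholds.thresholds

    dataset_ids = sorted({d for d, _ in preds})
    model_names = sorted({m for _, m in preds})
    values: dict[tuple[str, str], np.ndarray] = {
        (metric, model): np.full((len(tarr), len(dataset_ids)), np.nan)
        for metric in metrics for model in model_names
    }
    for (ds, model), p in preds.items():
        di = dataset_ids.index(ds)
        tp, fn, tn, fp = _counts_at_thresholds(p, tarr)
        for metric in metrics:
            if get_metric_spec(metric).name == "AUC":
                values[(metric, model)][:, di] = auc_rank(p)
            else:
                values[(metric, model)][:, di] = metric_vector(
                    metric, tp, fn, tn, fp)
    return ThresholdGrid(thresholds=thresholds, dataset_ids=dataset_ids,
                         values=values)


def incremental_average(grid: ThresholdGrid) -> pd.DataFrame:
    """Variance across datasets of the threshold-prefix-averaged metric.

    For each prefix of the ThresholdSet ordering (0.5 first, then outward),
    each dataset's metric values over the included thresholds are averaged
    (UNDEFINED cells skipped), and the variance of those averages across
    datasets is recorded.  Returns a long frame with columns metric, model,
    num_thresholds, variance.
    """
    rows = []
    for (metric, model), arr in grid.values.items():
        finite = np.isfinite(arr)
        cum_sum = np.cumsum(np.where(finite, arr, 0.0), axis=0)
        cum_cnt = np.cumsum(finite, axis=0)
        with np.errstate(invalid="ignore"):
            prefix_means = np.where(cum_cnt > 0, cum_sum / cum_cnt, np.nan)
        all_empty = (cum_cnt == 0).all(axis=1)
        if all_empty.any():
            raise ValueError(
                f"{metric}/{model}: a threshold prefix is entirely UNDEFINED")
        for k in range(arr.shape[0]):
            m = prefix_means[k]
            valid = np.isfinite(m)
            if valid.sum() < arr.shape[1]:
                log.info("%s/%s prefix %d: %d dataset(s) all-UNDEFINED, excluded",
                         metric, model, k + 1, int((~valid).sum()))
            var = float(np.var(m[valid], ddof=1)) if valid.sum() >= 2 else np.nan
            rows.append({"metric": metric, "model": model,
                         "num_thresholds": k + 1, "variance": var})
    return pd.DataFrame(rows)


def ols_slope(curve: pd.DataFrame) -> pd.DataFrame:
    """OLS of variance on number of thresholds, per (metric, model).

    Returns slope, two-sided p-value and intercept for each curve.  Curves
    with fewer than 3 usable points or a constant predictor are rejected.
    """
    rows = []
    for (metric, model), sub in curve.groupby(["metric", "model"], sort=False):
        sub = sub.dropna(subset=["variance"])
        if len(sub) < 3:
            raise ValueError(f"{metric}/{model}: need >= 3 curve points")
        x = sub["num_thresholds"].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"{metric}/{model}: constant predictor")
        y = sub["variance"].to_numpy(dtype=float)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        rows.append({"metric": metric, "model": model,
                     "slope": float(fit.params[1]),
                     "p_value": float(fit.pvalues[1]),
                     "intercept": float(fit.params[0])})
    return pd.DataFrame(rows)
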