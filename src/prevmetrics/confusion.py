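"""Confusion-matrix algebra for binary classification.

This module defines the 2x2 confusion matrix, a catalogue of evaluation
metrics in two equivalent parameterizations — raw counts (TP, FN, TN, FP)
and the rate quadruple (n, prevalence phi, TPR, TNR) — and the rank-based
AUC statistic.  Metrics whose denominator vanishes (e.g. PPV when nothing
is predicted positive, DOR at a degenerate threshold) return a tagged
``MetricValue.undefined`` rather than NaN or infinity, so that downstream
aggregation can skip and count them explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ConfusionMatrix",
    "RatesParam",
    "MetricSpec",
    "MetricValue",
    "ScoredPredictions",
    "CATALOGUE",
    "STUDY_METRICS",
    "get_metric_spec",
    "metric_catalogue",
    "confusion_from_labels",
    "confusion_at_threshold",
    "metric_from_confusion",
    "metric_from_rates",
    "auc_rank",
    "roc_points",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """The four counts of a binary classification at one threshold."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    def to_rates(self) -> "RatesParam":
        """Convert to the (n, phi, TPR, TNR) parameterization.

        Requires both classes present (phi strictly inside (0, 1)).
        """
        if self.positives == 0 or self.negatives == 0:
            raise ValueError("rate parameterization requires both classes present")
        return RatesParam(
            n=self.n,
            phi=self.positives / self.n,
            tpr=self.tp / self.positives,
            tnr=self.tn / self.negatives,
        )


@dataclass(frozen=True)
class RatesParam:
    """Alternative coordinates (n, phi, TPR, TNR) for a confusion matrix.

    phi is the prevalence: the fraction of truly positive cases.  The two
    parameterizations are exactly interconvertible when phi*n, tpr*phi*n and
    tnr*(1-phi)*n are integers.
    """

    n: int
    phi: float
    tpr: float
    tnr: float

    def __post_init__(self) -> None:
        if not (0.0 < self.phi < 1.0):
            raise ValueError(f"phi must lie strictly in (0, 1), got {self.phi}")
        for name in ("tpr", "tnr"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n <= 0:
            raise ValueError("n must be positive")

    def to_confusion(self) -> ConfusionMatrix:
        """Round-trip to counts; exact when the products divide evenly."""
        pos = round(self.phi * self.n)
        neg = self.n - pos
        tp = round(self.tpr * pos)
        tn = round(self.tnr * neg)
        return ConfusionMatrix(tp=tp, fn=pos - tp, tn=tn, fp=neg - tn)


#: Metric names whose orientation is lower-is-better.
LOWER_BETTER = frozenset({"FN", "FP", "FPR", "FNR", "FOR", "FDR"})


@dataclass(frozen=True)
class MetricSpec:
    """One catalogue entry: name, orientation, range, optional Fbeta beta."""

    name: str
    orientation: str  # "higher-better" | "lower-better"
    range: tuple[float, float]
    beta: float | None = None
    formula_id: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in ("higher-better", "lower-better"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.beta is not None and self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass(frozen=True)
class MetricValue:
    """A metric result: either a real value or a tagged UNDEFINED."""

    value: float | None
    reason: str | None = None

    @classmethod
    def of(cls, value: float) -> "MetricValue":
        return cls(value=float(value), reason=None)

    @classmethod
    def undefined(cls, reason: str) -> "MetricValue":
        return cls(value=None, reason=reason)

    @property
    def defined(self) -> bool:
        return self.value is not None

    def unwrap(self) -> float:
        if self.value is None:
            raise ValueError(f"metric is UNDEFINED ({self.reason})")
        return self.value


@dataclass(frozen=True)
class ScoredPredictions:
    """True labels plus predicted positive-class probabilities."""

    labels: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        scores = np.asarray(self.scores, dtype=float)
        if labels.shape != scores.shape or labels.ndim != 1:
            raise ValueError("labels and scores must be 1-d and the same length")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if np.any((scores < 0) | (scores > 1)):
            raise ValueError("scores must lie in [0, 1]")
        object.__setattr__(self, "labels", labels.astype(np.int8))
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return len(self.labels) - self.n_pos

    @classmethod
    def from_csv(cls, path) -> "ScoredPredictions":
        """Read a two-column CSV with headers ``label`` and ``score``."""
        df = pd.read_csv(path)
        return cls(labels=df["label"].to_numpy(), scores=df["score"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"label": self.labels, "score": self.scores}).to_csv(
            path, index=False
        )


# ---------------------------------------------------------------------------
# Metric catalogue
# ---------------------------------------------------------------------------

def _spec(name: str, lo: float, hi: float, formula_id: str,
          beta: float | None = None) -> MetricSpec:
    orientation = "lower-better" if name in LOWER_BETTER else "higher-better"
    return MetricSpec(name=name, orientation=orientation, range=(lo, hi),
                      beta=beta, formula_id=formula_id)


INF = math.inf

CATALOGUE: dict[str, MetricSpec] = {
    s.name: s
    for s in [
        _spec("TP", 0, INF, "count"),
        _spec("FN", 0, INF, "count"),
        _spec("TN", 0, INF, "count"),
        _spec("FP", 0, INF, "count"),
        _spec("TPR", 0, 1, "tp/(tp+fn)"),
        _spec("TNR", 0, 1, "tn/(tn+fp)"),
        _spec("PPV", 0, 1, "tp/(tp+fp)"),
        _spec("NPV", 0, 1, "tn/(tn+fn)"),
        _spec("FPR", 0, 1, "1-TNR"),
        _spec("FNR", 0, 1, "1-TPR"),
        _spec("FOR", 0, 1, "1-NPV"),
        _spec("FDR", 0, 1, "1-PPV"),
        _spec("accuracy", 0, 1, "(tp+tn)/n"),
        _spec("BA", 0, 1, "(TPR+TNR)/2"),
        _spec("BI", -1, 1, "TPR+TNR-1"),
        _spec("MK", -1, 1, "PPV+NPV-1"),
        _spec("Gmean", 0, 1, "sqrt(TPR*TNR)"),
        _spec("JI", 0, 1, "tp/(tp+fn+fp)"),
        _spec("DOR", 0, INF, "(TPR*TNR)/(FPR*FNR)"),
        _spec("FM", 0, 1, "sqrt(PPV*TPR)"),
        _spec("kappa", -1, 1, "(acc-expAcc)/(1-expAcc)"),
        _spec("F1", 0, 1, "2tp/(2tp+fp+fn)"),
        _spec("F0.5", 0, 1, "Fbeta", beta=0.5),
        _spec("F2", 0, 1, "Fbeta", beta=2.0),
        _spec("MCC", -1, 1, "pearson(true,pred)"),
        _spec("AUC", 0, 1, "rank statistic"),
    ]
}

#: The 18 metrics whose consistency the study analyzes (Table-3 order).
STUDY_METRICS: tuple[str, ...] = (
    "TPR", "TNR", "PPV", "NPV", "accuracy", "BA", "BI", "F1", "MCC",
    "Gmean", "FM", "MK", "DOR", "JI", "kappa", "F0.5", "F2", "AUC",
)


def get_metric_spec(name: str | MetricSpec) -> MetricSpec:
    if isinstance(name, MetricSpec):
        return name
    try:
        return CATALOGUE[name]
    except KeyError:
        raise KeyError(
            f"unknown metric {name!r}; known: {sorted(CATALOGUE)}"
        ) from None


def metric_catalogue() -> pd.DataFrame:
    """The metric catalogue as a machine-readable table."""
    rows = [
        {
            "name": s.name,
            "orientation": s.orientation,
            "range_low": s.range[0],
            "range_high": s.range[1],
            "beta": s.beta,
            "formula_id": s.formula_id,
        }
        for s in CATALOGUE.values()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Building confusion matrices
# ---------------------------------------------------------------------------

def confusion_from_labels(true_labels: Sequence[int],
                          predicted_labels: Sequence[int]) -> ConfusionMatrix:
    """Tabulate the 2x2 confusion matrix from paired binary label vectors."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape or t.ndim != 1 or len(t) == 0:
        raise ValueError("label vectors must be 1-d, equal-length and non-empty")
    for arr, which in ((t, "true"), (p, "predicted")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{which} labels must be binary 0/1")
    tp = int(np.sum((t == 1) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == 0)))
    tn = int(np.sum((t == 0) & (p == 0)))
    fp = int(np.sum((t == 0) & (p == 1)))
    return ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp)


def confusion_at_threshold(preds: ScoredPredictions, t: float,
                           rule: str = "ge") -> ConfusionMatrix:
    """Threshold scores into labels and tabulate.

    The decision rule is predicted-positive iff ``score >= t`` (``rule="ge"``,
    the default, under which t=0 labels everything positive) or strictly
    ``score > t`` (``rule="gt"``).
    """
    if rule == "ge":
        pred = preds.scores >= t
    elif rule == "gt":
        pred = preds.scores > t
    else:
        raise ValueError(f"rule must be 'ge' or 'gt', got {rule!r}")
    return confusion_from_labels(preds.labels, pred.astype(int))


# ---------------------------------------------------------------------------
# Count-form metric formulas
# ---------------------------------------------------------------------------

def _count_tpr(cm: ConfusionMatrix) -> MetricValue:
    if cm.positives == 0:
        return MetricValue.undefined("no positive cases (tp+fn=0)")
    return MetricValue.of(cm.tp / cm.positives)


def _count_tnr(cm: ConfusionMatrix) -> MetricValue:
    if cm.negatives == 0:
        return MetricValue.undefined("no negative cases (tn+fp=0)")
    return MetricValue.of(cm.tn / cm.negatives)


def _count_ppv(cm: ConfusionMatrix) -> MetricValue:
    if cm.tp + cm.fp == 0:
        return MetricValue.undefined("nothing predicted positive (tp+fp=0)")
    return MetricValue.of(cm.tp / (cm.tp + cm.fp))


def _count_npv(cm: ConfusionMatrix) -> MetricValue:
    if cm.tn + cm.fn == 0:
        return MetricValue.undefined("nothing predicted negative (tn+fn=0)")
    return MetricValue.of(cm.tn / (cm.tn + cm.fn))


def _complement(f: Callable[[ConfusionMatrix], MetricValue]):
    def g(cm: ConfusionMatrix) -> MetricValue:
        v = f(cm)
        return MetricValue.of(1.0 - v.value) if v.defined else v
    return g


def _combine(parts: Iterable[MetricValue],
             fn: Callable[..., float]) -> MetricValue:
    vals = []
    for p in parts:
        if not p.defined:
            return p
        vals.append(p.value)
    return MetricValue.of(fn(*vals))


def _count_ba(cm):
    return _combine((_count_tpr(cm), _count_tnr(cm)), lambda a, b: (a + b) / 2)


def _count_bi(cm):
    return _combine((_count_tpr(cm), _count_tnr(cm)), lambda a, b: a + b - 1)


def _count_mk(cm):
    return _combine((_count_ppv(cm), _count_npv(cm)), lambda a, b: a + b - 1)


def _count_gmean(cm):
    return _combine((_count_tpr(cm), _count_tnr(cm)),
                    lambda a, b: math.sqrt(a * b))


def _count_ji(cm):
    d = cm.tp + cm.fn + cm.fp
    if d == 0:
        return MetricValue.undefined("tp+fn+fp=0")
    return MetricValue.of(cm.tp / d)


def _count_dor(cm):
    tpr, tnr = _count_tpr(cm), _count_tnr(cm)
    if not tpr.defined:
        return tpr
    if not tnr.defined:
        return tnr
    fpr, fnr = 1 - tnr.value, 1 - tpr.value
    if fpr * fnr == 0:
        return MetricValue.undefined("FPR*FNR=0")
    return MetricValue.of(tpr.value * tnr.value / (fpr * fnr))


def _count_fm(cm):
    return _combine((_count_ppv(cm), _count_tpr(cm)),
                    lambda a, b: math.sqrt(a * b))


def _count_kappa(cm):
    n = cm.n
    exp_acc = ((cm.tp + cm.fn) * (cm.tp + cm.fp)
               + (cm.tn + cm.fp) * (cm.tn + cm.fn)) / n ** 2
    if exp_acc == 1.0:
        return MetricValue.undefined("expected accuracy is 1")
    acc = (cm.tp + cm.tn) / n
    return MetricValue.of((acc - exp_acc) / (1 - exp_acc))


def _count_f1(cm):
    d = 2 * cm.tp + cm.fp + cm.fn
    if d == 0:
        return MetricValue.undefined("2tp+fp+fn=0")
    return MetricValue.of(2 * cm.tp / d)


def _count_fbeta(cm: ConfusionMatrix, beta: float) -> MetricValue:
    ppv, tpr = _count_ppv(cm), _count_tpr(cm)
    if not ppv.defined:
        return ppv
    if not tpr.defined:
        return tpr
    d = beta ** 2 * ppv.value + tpr.value
    if d == 0:
        return MetricValue.undefined("beta^2*PPV+TPR=0")
    return MetricValue.of((1 + beta ** 2) * ppv.value * tpr.value / d)


def _count_mcc(cm):
    factors = [cm.tp + cm.fp, cm.tp + cm.fn, cm.tn + cm.fp, cm.tn + cm.fn]
    if 0 in factors:
        return MetricValue.undefined("a marginal of the confusion matrix is 0")
    num = cm.tp * cm.tn - cm.fp * cm.fn
    return MetricValue.of(num / math.sqrt(math.prod(float(f) for f in factors)))


_COUNT_FORMULAS: dict[str, Callable[[ConfusionMatrix], MetricValue]] = {
    "TP": lambda cm: MetricValue.of(cm.tp),
    "FN": lambda cm: MetricValue.of(cm.fn),
    "TN": lambda cm: MetricValue.of(cm.tn),
    "FP": lambda cm: MetricValue.of(cm.fp),
    "TPR": _count_tpr,
    "TNR": _count_tnr,
    "PPV": _count_ppv,
    "NPV": _count_npv,
    "FPR": _complement(_count_tnr),
    "FNR": _complement(_count_tpr),
    "FOR": _complement(_count_npv),
    "FDR": _complement(_count_ppv),
    "accuracy": lambda cm: MetricValue.of((cm.tp + cm.tn) / cm.n),
    "BA": _count_ba,
    "BI": _count_bi,
    "MK": _count_mk,
    "Gmean": _count_gmean,
    "JI": _count_ji,
    "DOR": _count_dor,
    "FM": _count_fm,
    "kappa": _count_kappa,
    "F1": _count_f1,
    "MCC": _count_mcc,
}


def metric_from_confusion(spec: str | MetricSpec,
                          cm: ConfusionMatrix) -> MetricValue:
    """Evaluate a catalogue metric on a confusion matrix (count form)."""
    spec = get_metric_spec(spec)
    if spec.name == "AUC":
        raise ValueError("AUC is not a confusion-matrix metric; use auc_rank")
    if spec.formula_id == "Fbeta":
        return _count_fbeta(cm, spec.beta)
    return _COUNT_FORMULAS[spec.name](cm)


# ---------------------------------------------------------------------------
# Rate-form metric formulas (n, phi, TPR, TNR)
# ---------------------------------------------------------------------------

def _rates_ppv(rp: RatesParam) -> MetricValue:
    d = rp.tpr * rp.phi + (1 - rp.tnr) * (1 - rp.phi)
    if d == 0:
        return MetricValue.undefined("nothing predicted positive")
    return MetricValue.of(rp.tpr * rp.phi / d)


def _rates_npv(rp: RatesParam) -> MetricValue:
    d = rp.tnr * (1 - rp.phi) + (1 - rp.tpr) * rp.phi
    if d == 0:
        return MetricValue.undefined("nothing predicted negative")
    return MetricValue.of(rp.tnr * (1 - rp.phi) / d)


def _rates_f1(rp: RatesParam) -> MetricValue:
    d = 2 * rp.tpr * rp.phi + (1 - rp.tnr) * (1 - rp.phi) + (1 - rp.tpr) * rp.phi
    if d == 0:
        return MetricValue.undefined("2tp+fp+fn=0")
    return MetricValue.of(2 * rp.tpr * rp.phi / d)


def _rates_fbeta(rp: RatesParam, beta: float) -> MetricValue:
    ppv = _rates_ppv(rp)
    if not ppv.defined:
        return ppv
    d = beta ** 2 * ppv.value + rp.tpr
    if d == 0:
        return MetricValue.undefined("beta^2*PPV+TPR=0")
    return MetricValue.of((1 + beta ** 2) * ppv.value * rp.tpr / d)


def _rates_dor(rp: RatesParam) -> MetricValue:
    d = (1 - rp.tnr) * (1 - rp.tpr)
    if d == 0:
        return MetricValue.undefined("FPR*FNR=0")
    return MetricValue.of(rp.tpr * rp.tnr / d)


def _rates_mk(rp: RatesParam) -> MetricValue:
    return _combine((_rates_ppv(rp), _rates_npv(rp)), lambda a, b: a + b - 1)


def _rates_ji(rp: RatesParam) -> MetricValue:
    d = rp.phi + (1 - rp.tnr) * (1 - rp.phi)
    if d == 0:
        return MetricValue.undefined("tp+fn+fp=0")
    return MetricValue.of(rp.tpr * rp.phi / d)


def _rates_fm(rp: RatesParam) -> MetricValue:
    return _combine((_rates_ppv(rp), MetricValue.of(rp.tpr)),
                    lambda a, b: math.sqrt(a * b))


def _rates_kappa(rp: RatesParam) -> MetricValue:
    # expAccuracy in the phi^2 form, algebraically identical to the n^2
    # count form; no residual 1/n factor.
    phi, tpr, tnr = rp.phi, rp.tpr, rp.tnr
    exp_acc = (phi ** 2 * tpr
               + phi * (1 - phi) * (2 - tpr - tnr)
               + (1 - phi) ** 2 * tnr)
    if exp_acc == 1.0:
        return MetricValue.undefined("expected accuracy is 1")
    acc = tpr * phi + tnr * (1 - phi)
    return MetricValue.of((acc - exp_acc) / (1 - exp_acc))


def _rates_mcc(rp: RatesParam) -> MetricValue:
    phi, tpr, tnr = rp.phi, rp.tpr, rp.tnr
    a = tpr * phi / (1 - phi) + (1 - tnr)
    b = tnr * (1 - phi) / phi + (1 - tpr)
    if a * b == 0:
        return MetricValue.undefined("a marginal of the confusion matrix is 0")
    return MetricValue.of((tpr + tnr - 1) / math.sqrt(a * b))


_RATES_FORMULAS: dict[str, Callable[[RatesParam], MetricValue]] = {
    "TP": lambda rp: MetricValue.of(rp.tpr * rp.phi * rp.n),
    "FN": lambda rp: MetricValue.of((1 - rp.tpr) * rp.phi * rp.n),
    "TN": lambda rp: MetricValue.of(rp.tnr * (1 - rp.phi) * rp.n),
    "FP": lambda rp: MetricValue.of((1 - rp.tnr) * (1 - rp.phi) * rp.n),
    "TPR": lambda rp: MetricValue.of(rp.tpr),
    "TNR": lambda rp: MetricValue.of(rp.tnr),
    "FPR": lambda rp: MetricValue.of(1 - rp.tnr),
    "FNR": lambda rp: MetricValue.of(1 - rp.tpr),
    "PPV": _rates_ppv,
    "NPV": _rates_npv,
    "FOR": lambda rp: _combine((_rates_npv(rp),), lambda a: 1 - a),
    "FDR": lambda rp: _combine((_rates_ppv(rp),), lambda a: 1 - a),
    "accuracy": lambda rp: MetricValue.of(
        rp.tpr * rp.phi + rp.tnr * (1 - rp.phi)),
    "BA": lambda rp: MetricValue.of((rp.tpr + rp.tnr) / 2),
    "BI": lambda rp: MetricValue.of(rp.tpr + rp.tnr - 1),
    "Gmean": lambda rp: MetricValue.of(math.sqrt(rp.tpr * rp.tnr)),
    "MK": _rates_mk,
    "JI": _rates_ji,
    "DOR": _rates_dor,
    "FM": _rates_fm,
    "kappa": _rates_kappa,
    "F1": _rates_f1,
    "MCC": _rates_mcc,
}


def metric_from_rates(spec: str | MetricSpec, rp: RatesParam) -> MetricValue:
    """Evaluate a metric in the (n, phi, TPR, TNR) parameterization.

    Every confusion-matrix metric has such a form; AUC does not (it is not
    a single-threshold statistic) and is rejected.
    """
    spec = get_metric_spec(spec)
    if spec.name == "AUC":
        raise ValueError("AUC has no (n, phi, TPR, TNR) form; use auc_rank")
    if spec.formula_id == "Fbeta":
        return _rates_fbeta(rp, spec.beta)
    return _RATES_FORMULAS[spec.name](rp)


# ---------------------------------------------------------------------------
# AUC and the ROC curve
# ---------------------------------------------------------------------------

def auc_rank(preds: ScoredPredictions) -> float:
    """Area under the ROC curve as the normalized Mann-Whitney statistic.

    Equals the probability that a uniformly chosen positive case receives a
    higher score than a uniformly chosen negative case, with ties credited
    one half.  Invariant under strictly increasing transforms of the scores.
    """
    n_pos, n_neg = preds.n_pos, preds.n_neg
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires at least one case of each class")
    ranks = rankdata(preds.scores)  # average ranks handle ties at 0.5 credit
    rank_sum_pos = ranks[preds.labels == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_points(preds: ScoredPredictions) -> np.ndarray:
    """The ROC polygon: (FPR, TPR) at every distinct score plus anchors.

    Returned as an array of shape (k, 2), monotone nondecreasing in both
    coordinates, whose trapezoidal area equals :func:`auc_rank`.
    """
    from sklearn.metrics import roc_curve

    if preds.n_pos == 0 or preds.n_neg == 0:
        raise ValueError("ROC requires at least one case of each class")
    fpr, tpr, _ = roc_curve(preds.labels, preds.scores, drop_intermediate=False)
    return np.column_stack([fpr, tpr])
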