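"""Synthetic recidivism-style data with controlled prevalence, plus toy fixtures.

The generator emulates a seven-feature criminal-recidivism sample: gender,
age, three zero-heavy criminal-history counts, crime degree and a
categorical charge type, with a binary outcome drawn from a logistic model
over those features.  The intercept is calibrated so the population
prevalence hits a configurable target (default 0.452 at n = 6214), and the
default effect sizes place a tuned logistic model's test AUC in the
low-0.7 range — a deliberately moderate signal regime.

``toy_fixtures`` ships small worked examples (printed label vectors and
six reference confusion matrices with their published metric values) used
as exact oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .classifiers import Dataset
from .confusion import ConfusionMatrix

__all__ = [
    "GeneratorConfig",
    "ToyFixture",
    "calibrate_intercept",
    "generate_dataset",
    "toy_fixtures",
]

#: Marginal distributions of the seven features.
DEFAULT_FEATURE_SPECS: dict[str, dict] = {
    "gender": {"kind": "binary", "p": 0.81},  # 1 = male
    "age": {"kind": "truncnorm", "mean": 34.0, "sd": 11.0,
            "low": 18.0, "high": 70.0},
    "juvenile_misdemeanors": {"kind": "zip", "pi": 0.85, "lam": 1.2},
    "juvenile_felonies": {"kind": "zip", "pi": 0.90, "lam": 0.8},
    "prior_crimes": {"kind": "zip", "pi": 0.35, "lam": 4.0},
    "crime_degree": {"kind": "binary", "p": 0.65},  # 1 = felony
    "crime_charge": {"kind": "categorical",
                     "levels": ["drug", "theft", "assault", "other"],
                     "probs": [0.35, 0.25, 0.2, 0.2]},
}

#: Logistic effects on the log-odds of reoffending.  Age in years (younger
#: defendants reoffend more), counts per offense, charge levels as offsets.
DEFAULT_COEFFICIENTS: dict[str, float | dict[str, float]] = {
    "gender": 0.25,
    "age": -0.06,
    "juvenile_misdemeanors": 0.35,
    "juvenile_felonies": 0.40,
    "prior_crimes": 0.22,
    "crime_degree": 0.15,
    "crime_charge": {"drug": 0.0, "theft": 0.10, "assault": 0.20, "other": 0.05},
}


@dataclass(frozen=True)
class GeneratorConfig:
    n: int = 6214
    target_prevalence: float = 0.452
    coefficients: dict = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    feature_specs: dict = field(default_factory=lambda: dict(DEFAULT_FEATURE_SPECS))
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.target_prevalence < 1.0):
            raise ValueError("target_prevalence must lie strictly in (0, 1)")
        if self.n < 2:
            raise ValueError("n must be at least 2")


def _draw_features(specs: dict, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    for name, s in specs.items():
        kind = s["kind"]
        if kind == "binary":
            cols[name] = (rng.random(n) < s["p"]).astype(int)
        elif kind == "truncnorm":
            a = (s["low"] - s["mean"]) / s["sd"]
            b = (s["high"] - s["mean"]) / s["sd"]
            cols[name] = truncnorm.rvs(a, b, loc=s["mean"], scale=s["sd"],
                                       size=n, random_state=rng)
        elif kind == "zip":  # zero-inflated Poisson: criminal histories are zero-heavy
            nonzero = rng.random(n) >= s["pi"]
            counts = rng.poisson(s["lam"], size=n)
            cols[name] = np.where(nonzero, counts, 0)
        elif kind == "categorical":
            cols[name] = rng.choice(s["levels"], size=n, p=s["probs"])
        else:
            raise ValueError(f"unknown feature kind {kind!r}")
    return pd.DataFrame(cols)


def _linear_predictor(features: pd.DataFrame, coefficients: dict) -> np.ndarray:
    lp = np.zeros(len(features))
    for name, coef in coefficients.items():
        col = features[name]
        if isinstance(coef, dict):
            lp += col.map(coef).to_numpy(dtype=float)
        else:
            lp += coef * col.to_numpy(dtype=float)
    return lp


def calibrate_intercept(cfg: GeneratorConfig, calibration_n: int = 200_000,
                        tol: float = 0.005) -> float:
    """Intercept making the mean logistic probability hit the target prevalence.

    Solved by root-finding on a large feature sample drawn with a fixed
    internal seed, so the intercept depends only on the feature and
    coefficient configuration, not on ``cfg.seed``.
    """
    rng = np.random.default_rng(987654321)
    features = _draw_features(cfg.feature_specs, calibration_n, rng)
    lp = _linear_predictor(features, cfg.coefficients)

    def gap(b0: float) -> float:
        return float(expit(b0 + lp).mean() - cfg.target_prevalence)

    lo, hi = -30.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError("search bounds do not bracket the target prevalence")
    b0 = brentq(gap, lo, hi, xtol=1e-10)
    assert abs(gap(b0)) < tol
    return float(b0)


def generate_dataset(cfg: GeneratorConfig, intercept: float | None = None,
                     id: int = 0) -> Dataset:
    """Draw one synthetic dataset; same seed gives byte-identical output.

    The outcome is Bernoulli(logistic(intercept + sum(coef * feature))).
    Pass a precomputed ``intercept`` to skip recalibration when drawing
    many datasets from one configuration.
    """
    if intercept is None:
        intercept = calibrate_intercept(cfg)
    rng = np.random.default_rng(cfg.seed)
    features = _draw_features(cfg.feature_specs, cfg.n, rng)
    p = expit(intercept + _linear_predictor(features, cfg.coefficients))
    labels = (rng.random(cfg.n) < p).astype(int)
    return Dataset(features=features, labels=labels, id=id)


# ---------------------------------------------------------------------------
# Toy fixtures: printed worked examples used as exact oracles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyFixture:
    """A small reference case with published expected metric values.

    ``expected`` maps metric name -> (value, decimals); names listed in
    ``known_discrepant`` are published values that do NOT recompute from
    the confusion matrix with the catalogue formulas (kept for the record,
    excluded from exact oracles).  ``labels``/``predictions`` are present
    for the label-vector fixtures; ``confusion`` for the reference
    confusion matrices.
    """

    name: str
    expected: dict[str, tuple[float, int]]
    labels: tuple[int, ...] | None = None
    predictions: tuple[int, ...] | None = None
    confusion: ConfusionMatrix | None = None
    known_discrepant: frozenset[str] = frozenset()


_TRUE10 = (1, 0, 0, 0, 0, 1, 1, 0, 0, 1)

_REFERENCE_TABLE = {
    # model: (tp, fn, tn, fp), then the published metric rows
    "GBM": ((339, 223, 517, 164),
            {"TPR": 0.603, "TNR": 0.759, "PPV": 0.674, "NPV": 0.699,
             "accuracy": 0.689, "BA": 0.681, "BI": 0.362, "F1": 0.637,
             "MCC": 0.367, "Gmean": 0.677, "FM": 0.638, "MK": 0.373,
             "DOR": 4.792, "JI": 0.467, "kappa": 0.366,
             "F0.5": 0.352, "F2": 0.512, "AUC": 0.734}),
    "GLM": ((292, 270, 537, 144),
            {"TPR": 0.520, "TNR": 0.789, "PPV": 0.670, "NPV": 0.665,
             "accuracy": 0.667, "BA": 0.654, "BI": 0.308, "F1": 0.585,
             "MCC": 0.321, "Gmean": 0.640, "FM": 0.590, "MK": 0.335,
             "DOR": 4.033, "JI": 0.414, "kappa": 0.314,
             "F0.5": 0.321, "F2": 0.450, "AUC": 0.718}),
    "KNN": ((296, 266, 521, 160),
            {"TPR": 0.527, "TNR": 0.765, "PPV": 0.649, "NPV": 0.662,
             "accuracy": 0.657, "BA": 0.646, "BI": 0.292, "F1": 0.582,
             "MCC": 0.301, "Gmean": 0.635, "FM": 0.585, "MK": 0.311,
             "DOR": 3.623, "JI": 0.410, "kappa": 0.297,
             "F0.5": 0.319, "F2": 0.453, "AUC": 0.694}),
    "LDA": ((286, 276, 543, 138),
            {"TPR": 0.509, "TNR": 0.797, "PPV": 0.675, "NPV": 0.663,
             "accuracy": 0.667, "BA": 0.653, "BI": 0.306, "F1": 0.580,
             "MCC": 0.322, "Gmean": 0.637, "FM": 0.586, "MK": 0.338,
             "DOR": 4.077, "JI": 0.409, "kappa": 0.313,
             "F0.5": 0.317, "F2": 0.442, "AUC": 0.717}),
    "Random Forest": ((311, 251, 543, 138),
                      {"TPR": 0.553, "TNR": 0.797, "PPV": 0.693, "NPV": 0.684,
                       "accuracy": 0.687, "BA": 0.675, "BI": 0.351, "F1": 0.615,
                       "MCC": 0.363, "Gmean": 0.664, "FM": 0.619, "MK": 0.377,
                       "DOR": 4.875, "JI": 0.444, "kappa": 0.357,
                       "F0.5": 0.338, "F2": 0.477, "AUC": 0.727}),
    "randomguess": ((267, 295, 386, 295),
                    {"TPR": 0.475, "TNR": 0.567, "PPV": 0.475, "NPV": 0.567,
                     "accuracy": 0.525, "BA": 0.521, "BI": 0.042, "F1": 0.475,
                     "MCC": 0.042, "Gmean": 0.519, "FM": 0.475, "MK": 0.042,
                     "DOR": 1.184, "JI": 0.312, "kappa": 0.042,
                     "F0.5": 0.264, "F2": 0.396, "AUC": 0.524}),
}

# Published F-beta rows are inconsistent with the catalogue Fbeta formula
# applied to the published counts; AUC is not computable from counts alone.
_NOT_RECOMPUTABLE = frozenset({"F0.5", "F2", "AUC"})


def toy_fixtures() -> list[ToyFixture]:
    """The worked label-vector examples and the six reference confusion matrices."""
    fixtures = [
        ToyFixture(
            name="near_perfect",
            labels=_TRUE10,
            predictions=(1, 1, 0, 0, 0, 1, 1, 0, 0, 1),
            expected={"MCC": (0.82, 2), "accuracy": (0.9, 2)},
        ),
        ToyFixture(
            name="two_misses",
            labels=_TRUE10,
            predictions=(0, 0, 0, 0, 0, 1, 1, 0, 0, 0),
            expected={"MCC": (0.61, 2), "accuracy": (0.8, 2)},
        ),
        ToyFixture(
            name="three_misses",
            labels=_TRUE10,
            predictions=(0, 0, 1, 0, 0, 0, 1, 0, 0, 1),
            expected={"MCC": (0.36, 2), "accuracy": (0.70, 2)},
        ),
    ]
    for model, (counts, values) in _REFERENCE_TABLE.items():
        tp, fn, tn, fp = counts
        fixtures.append(ToyFixture(
            name=f"reference_{model}",
            confusion=ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp),
            expected={k: (v, 3) for k, v in values.items()},
            known_discrepant=_NOT_RECOMPUTABLE,
        ))
    return fixtures
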