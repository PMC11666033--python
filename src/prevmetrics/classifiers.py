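"""Probabilistic classifiers, the train/test protocol and the random-guess baseline.

Five model families are supported — logistic regression (GLM), random
forest (RF), k-nearest neighbors (KNN), linear discriminant analysis (LDA)
and gradient boosting (GBM) — each fit inside a preprocessing pipeline with
hyperparameters chosen by k-fold cross-validated AUC over a small grid.
A sixth, naive baseline assigns labels at random in proportion to the test
set's prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler

from .confusion import ScoredPredictions

__all__ = [
    "Dataset",
    "SplitSpec",
    "ClassifierSpec",
    "FAMILIES",
    "DEFAULT_GRIDS",
    "split_train_test",
    "fit_predict",
    "random_guess",
]


@dataclass(frozen=True)
class Dataset:
    """A feature table with a binary outcome column.

    ``features`` may mix numeric and categorical (object/category dtype)
    columns; ``labels`` is the 0/1 outcome.  ``id`` tags the dataset within
    a prevalence sweep (0 = original, negative = down-arm iteration,
    positive = up-arm iteration).
    """

    features: pd.DataFrame
    labels: np.ndarray
    id: int = 0

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if len(labels) != len(self.features):
            raise ValueError("features and labels must have the same length")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        object.__setattr__(self, "labels", labels.astype(np.int8))

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return len(self) - self.n_pos

    @property
    def prevalence(self) -> float:
        return self.n_pos / len(self)

    def take(self, idx: np.ndarray, id: int | None = None) -> "Dataset":
        """Row subset (positional indices), resetting the feature index."""
        return Dataset(
            features=self.features.iloc[idx].reset_index(drop=True),
            labels=self.labels[idx],
            id=self.id if id is None else id,
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.features.copy()
        out["label"] = self.labels
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_col: str = "label",
                   id: int = 0) -> "Dataset":
        return cls(features=df.drop(columns=[label_col]),
                   labels=df[label_col].to_numpy(), id=id)


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie strictly in (0, 1)")


#: Default cross-validation grids, deliberately small: the study's claims
#: concern metric behavior across prevalence, not hyperparameter tuning.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "GLM": {"model__C": [0.1, 1.0, 10.0]},
    "RF": {"model__n_estimators": [100, 300]},
    "KNN": {"model__n_neighbors": [5, 15, 31]},
    "LDA": {"model__solver": ["svd"]},
    "GBM": {"model__max_depth": [1, 3], "model__learning_rate": [0.1]},
}

FAMILIES = tuple(DEFAULT_GRIDS)

#: Families whose estimators are scale-sensitive and get standardized inputs.
_SCALED_FAMILIES = frozenset({"GLM", "LDA", "KNN"})


@dataclass(frozen=True)
class ClassifierSpec:
    family: str
    hyperparameter_grid: Mapping[str, list] | None = None
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unsupported family {self.family!r}; "
                             f"known: {FAMILIES}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        grid = self.hyperparameter_grid
        if grid is not None and len(grid) == 0:
            raise ValueError("hyperparameter grid must be non-empty")

    @property
    def grid(self) -> dict[str, list]:
        return dict(self.hyperparameter_grid or DEFAULT_GRIDS[self.family])


def split_train_test(data: Dataset, spec: SplitSpec) -> tuple[Dataset, Dataset]:
    """Random disjoint train/test row partition, reproducible by seed."""
    rng = np.random.default_rng(spec.seed)
    n = len(data)
    n_train = round(spec.train_fraction * n)
    perm = rng.permutation(n)
    return data.take(perm[:n_train]), data.take(perm[n_train:])


def _make_estimator(family: str, seed: int):
    if family == "GLM":
        return LogisticRegression(max_iter=2000)
    if family == "RF":
        # leaf-size floor keeps probability estimates smooth on tabular
        # data of this size; tree count stays in the CV grid
        return RandomForestClassifier(random_state=seed, min_samples_leaf=20)
    if family == "KNN":
        return KNeighborsClassifier()
    if family == "LDA":
        return LinearDiscriminantAnalysis()
    if family == "GBM":
        return GradientBoostingClassifier(random_state=seed)
    raise ValueError(f"unsupported family {family!r}")


def _make_pipeline(family: str, features: pd.DataFrame, seed: int) -> Pipeline:
    cat_cols = [c for c in features.columns
                if features[c].dtype == object
                or isinstance(features[c].dtype, pd.CategoricalDtype)]
    num_cols = [c for c in features.columns if c not in cat_cols]
    num_step = StandardScaler() if family in _SCALED_FAMILIES else "passthrough"
    pre = ColumnTransformer(
        [("num", num_step, num_cols),
         ("cat", OneHotEncoder(handle_unknown="ignore"), cat_cols)]
    )
    return Pipeline([("pre", pre), ("model", _make_estimator(family, seed))])


def fit_predict(spec: ClassifierSpec, train: Dataset,
                test: Dataset) -> ScoredPredictions:
    """Fit one family with CV-selected hyperparameters; score the test set.

    Hyperparameters are chosen by ``cv_folds``-fold cross-validated AUC over
    the grid, the winning model is refit on the full training data, and the
    returned scores are positive-class probabilities for the test rows.
    """
    if train.n_pos == 0 or train.n_neg == 0:
        raise ValueError("training data must contain both classes")
    pipe = _make_pipeline(spec.family, train.features, spec.seed)
    search = GridSearchCV(pipe, spec.grid, scoring="roc_auc",
                          cv=spec.cv_folds, refit=True, n_jobs=1)
    search.fit(train.features, train.labels)
    scores = search.predict_proba(test.features)[:, 1]
    return ScoredPredictions(labels=test.labels, scores=np.clip(scores, 0, 1))


def random_guess(test_labels: np.ndarray, phi: float,
                 seed: int | np.random.Generator = 0) -> ScoredPredictions:
    """Prevalence-matched random guessing.

    Exactly ``round(phi * n)`` rows, chosen by a random permutation, receive
    a positive predicted label with a score uniform on [0.51, 0.99]; the
    rest receive a score uniform on [0.01, 0.49].  Thresholding at 0.5 thus
    recovers the random label assignment.
    """
    if not (0.0 <= phi <= 1.0):
        raise ValueError("phi must lie in [0, 1]")
    labels = np.asarray(test_labels)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = len(labels)
    n_guess_pos = round(phi * n)
    scores = rng.uniform(0.01, 0.49, size=n)
    pos_rows = rng.permutation(n)[:n_guess_pos]
    scores[pos_rows] = rng.uniform(0.51, 0.99, size=n_guess_pos)
    return ScoredPredictions(labels=labels, scores=scores)
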