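"""Constant-n prevalence sweep by simultaneous down- and up-sampling.

Starting from one dataset, each step removes k uniformly sampled members of
the shrinking class and adds k members sampled with replacement from the
growing class, so the sample size never changes while prevalence walks down
(or up) an exact arithmetic schedule: after i downward steps the positive
count is pos0 - k*i.  Because rows are exchanged at random, the pairwise
correlations among features and outcome stay approximately constant across
the whole series — the property that lets the study attribute metric
drift to prevalence alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifiers import Dataset

__all__ = [
    "SweepConfig",
    "SweepSeries",
    "swap_step",
    "run_sweep",
    "correlation_drift",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SweepConfig:
    """Sweep schedule: swap size, arm lengths, pool mode.

    Defaults reproduce the study design: k=30 swapped per iteration,
    76 downward and 79 upward iterations, 156 datasets in total.
    ``pool`` controls where added rows are drawn from: the original
    dataset's class pool ("original", default — limits duplication
    cascades) or the current iterate's ("current").
    """

    k: int = 30
    down_iters: int = 76
    up_iters: int = 79
    seed: int = 0
    pool: str = "original"

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be nonnegative")
        if self.down_iters < 0 or self.up_iters < 0:
            raise ValueError("iteration counts must be nonnegative")
        if self.pool not in ("original", "current"):
            raise ValueError("pool must be 'original' or 'current'")

    def validate_against(self, data: Dataset) -> None:
        if self.k * self.down_iters >= data.n_pos:
            raise ValueError(
                f"downward arm exhausts the positive class: "
                f"{self.k}*{self.down_iters} >= {data.n_pos}")
        if self.k * self.up_iters >= data.n_neg:
            raise ValueError(
                f"upward arm exhausts the negative class: "
                f"{self.k}*{self.up_iters} >= {data.n_neg}")


@dataclass(frozen=True)
class SweepSeries:
    """The ordered family of rebalanced datasets, down-arm end first.

    ``datasets[j]`` has iteration id in [-down_iters, +up_iters]; id 0 is
    the original data.  All datasets share the same n.
    """

    datasets: list[Dataset]

    def __post_init__(self) -> None:
        sizes = {len(d) for d in self.datasets}
        if len(sizes) > 1:
            raise ValueError(f"sweep datasets differ in size: {sizes}")

    def __len__(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)

    def __getitem__(self, j: int) -> Dataset:
        return self.datasets[j]

    @property
    def prevalences(self) -> np.ndarray:
        return np.array([d.prevalence for d in self.datasets])

    @property
    def original(self) -> Dataset:
        for d in self.datasets:
            if d.id == 0:
                return d
        raise ValueError("series does not contain the original dataset")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": [d.id for d in self.datasets],
            "n": [len(d) for d in self.datasets],
            "n_pos": [d.n_pos for d in self.datasets],
            "n_neg": [d.n_neg for d in self.datasets],
            "prevalence": self.prevalences,
        })


def swap_step(data: Dataset, direction: str, k: int,
              rng: np.random.Generator, pool: Dataset | None = None,
              id: int | None = None) -> Dataset:
    """One rebalancing step: drop k of one class, duplicate k of the other.

    ``direction="down"`` shrinks the positive class (prevalence falls);
    ``"up"`` shrinks the negative class.  Removed rows are sampled without
    replacement from ``data``; added rows are sampled with replacement from
    the growing class of ``pool`` (defaults to ``data`` itself).
    """
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    if pool is None:
        pool = data
    shrink_label = 1 if direction == "down" else 0
    shrink_idx = np.flatnonzero(data.labels == shrink_label)
    keep_other = np.flatnonzero(data.labels != shrink_label)
    if len(shrink_idx) <= k:
        raise ValueError(
            f"cannot drop {k} rows from a class of {len(shrink_idx)}")
    grow_pool = np.flatnonzero(pool.labels != shrink_label)

    dropped = rng.choice(shrink_idx, size=k, replace=False)
    kept_shrink = np.setdiff1d(shrink_idx, dropped)
    added = rng.choice(grow_pool, size=k, replace=True)

    features = pd.concat(
        [data.features.iloc[np.sort(np.concatenate([kept_shrink, keep_other]))],
         pool.features.iloc[added]],
        ignore_index=True,
    )
    labels = np.concatenate([
        data.labels[np.sort(np.concatenate([kept_shrink, keep_other]))],
        pool.labels[added],
    ])
    return Dataset(features=features, labels=labels,
                   id=data.id if id is None else id)


def run_sweep(data: Dataset, cfg: SweepConfig) -> SweepSeries:
    """Chain swap steps cumulatively in both directions from the original.

    Returns down_iters + up_iters + 1 datasets ordered by iteration id from
    -down_iters to +up_iters.  The class-count schedule is deterministic
    (pos0 -/+ k*i); which rows move is governed by the seed.
    """
    cfg.validate_against(data)
    rng = np.random.default_rng(cfg.seed)
    original = Dataset(features=data.features.reset_index(drop=True),
                       labels=data.labels, id=0)
    pool = original if cfg.pool == "original" else None

    down: list[Dataset] = []
    current = original
    for i in range(1, cfg.down_iters + 1):
        current = swap_step(current, "down", cfg.k, rng,
                            pool=pool or current, id=-i)
        down.append(current)

    up: list[Dataset] = []
    current = original
    for i in range(1, cfg.up_iters + 1):
        current = swap_step(current, "up", cfg.k, rng,
                            pool=pool or current, id=i)
        up.append(current)

    return SweepSeries(datasets=list(reversed(down)) + [original] + up)


def _numeric_encode(features: pd.DataFrame) -> pd.DataFrame:
    """Code categoricals as integer levels so correlations are computable."""
    out = {}
    for c in features.columns:
        col = features[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            out[c] = pd.Categorical(col).codes.astype(float)
        else:
            out[c] = col.astype(float)
    return pd.DataFrame(out)


def correlation_drift(series: SweepSeries) -> pd.DataFrame:
    """Max absolute change of any pairwise correlation vs the original.

    Correlations are taken over all numeric-encoded features plus the
    outcome.  Entries undefined in either matrix (constant columns) are
    excluded pairwise; the per-dataset exclusion count is reported.
    """
    def corr(d: Dataset) -> np.ndarray:
        frame = _numeric_encode(d.features)
        frame["label"] = d.labels.astype(float)
        return frame.corr().to_numpy()

    base = corr(series.original)
    rows = []
    for d in series:
        c = corr(d)
        diff = np.abs(c - base)
        valid = ~(np.isnan(c) | np.isnan(base))
        np.fill_diagonal(valid, False)
        excluded = int((~valid).sum() - valid.shape[0]) // 2
        drift = float(np.nanmax(diff[valid])) if valid.any() else np.nan
        if excluded:
            log.info("dataset %d: %d correlation pairs undefined", d.id, excluded)
        rows.append({"iteration": d.id, "prevalence": d.prevalence,
                     "max_abs_drift": drift, "excluded_pairs": excluded})
    return pd.DataFrame(rows)
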