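import decimal

import numpy as np
import pandas as pd
import pytest

from prevmetrics import (Dataset, GeneratorConfig, SplitSpec, StudyConfig,
                         SweepConfig, run_study, toy_fixtures)


def round_half_up(x: float, nd: int) -> float:
    """Round-half-up to nd decimals, as printed tables conventionally are."""
    q = decimal.Decimal(10) ** -nd
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@pytest.fixture(scope="session")
def fixtures_by_name():
    return {f.name: f for f in toy_fixtures()}


@pytest.fixture(scope="session")
def broward_counts_dataset():
    """A dataset with the reference class counts (2775 positive / 3439 negative)."""
    rng = np.random.default_rng(0)
    n, n_pos = 6214, 2775
    features = pd.DataFrame({"x": rng.normal(size=n), "y": rng.normal(size=n)})
    labels = np.concatenate([np.ones(n_pos, int), np.zeros(n - n_pos, int)])
    return Dataset(features=features, labels=labels)


#: Scaled-down study conditions for the stochastic end-to-end checks:
#: same prevalence span (~0.09-0.83) and design as the full protocol at
#: n=3000 with 33 sweep datasets and 3-fold CV.
REDUCED_STUDY = dict(
    generator=GeneratorConfig(n=3000),
    sweep=SweepConfig(k=70, down_iters=16, up_iters=16),
    cv_folds=3,
)


@pytest.fixture(scope="session")
def reduced_study(tmp_path_factory):
    """One full (scaled-down) study run shared by the end-to-end tests."""
    out = tmp_path_factory.mktemp("study")
    cfg = StudyConfig(out_dir=str(out), **REDUCED_STUDY).with_seed(1)
    return run_study(cfg)
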