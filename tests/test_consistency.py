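"""Tests for ranking, variance and variance-homogeneity analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from prevmetrics import (Dataset, EvaluationTable, MetricGroups, MetricValue,
                         SplitSpec, SweepSeries, evaluate_grid, rank_models,
                         rank_table, ranking_variance, variance_equality_tests)

MODELS = ["GBM", "GLM", "KNN", "LDA", "Random Forest", "randomguess"]


class TestRankModels:
    def test_reference_accuracy_row(self):
        """The published accuracy values produce the published ranks."""
        values = dict(zip(MODELS, [0.689, 0.667, 0.657, 0.667, 0.687, 0.525]))
        ranks = rank_models(values, "higher-better")
        assert ranks == dict(zip(MODELS, [1, 3.5, 5, 3.5, 2, 6]))

    def test_reference_false_negatives_row(self):
        values = dict(zip(MODELS, [223, 270, 266, 276, 251, 295]))
        ranks = rank_models(values, "lower-better")
        assert ranks == dict(zip(MODELS, [1, 4, 3, 5, 2, 6]))

    def test_all_tied(self):
        ranks = rank_models({m: 0.5 for m in MODELS}, "higher-better")
        assert all(r == 3.5 for r in ranks.values())

    def test_undefined_ranked_last_with_average_ties(self):
        values = {"a": MetricValue.of(0.9), "b": MetricValue.undefined("x"),
                  "c": MetricValue.of(0.4), "d": MetricValue.undefined("x")}
        ranks = rank_models(values, "higher-better")
        assert ranks["a"] == 1 and ranks["c"] == 2
        assert ranks["b"] == ranks["d"] == 3.5

    def test_all_undefined_rejected(self):
        with pytest.raises(ValueError):
            rank_models({"a": MetricValue.undefined("x")}, "higher-better")

    @settings(derandomize=True, max_examples=100)
    @given(vals=st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=8))
    def test_rank_sum_invariant(self, vals):
        m = len(vals)
        ranks = rank_models({f"m{i}": v for i, v in enumerate(vals)})
        assert sum(ranks.values()) == pytest.approx(m * (m + 1) / 2)

    @settings(derandomize=True, max_examples=100)
    @given(vals=st.lists(st.floats(0, 1, allow_nan=False), min_size=2,
                         max_size=8, unique=True))
    def test_orientation_reversal_reverses_ranks(self, vals):
        names = [f"m{i}" for i in range(len(vals))]
        hi = rank_models(dict(zip(names, vals)), "higher-better")
        lo = rank_models(dict(zip(names, vals)), "lower-better")
        m = len(vals)
        for name in names:
            assert hi[name] + lo[name] == pytest.approx(m + 1)


def _toy_table():
    """Two datasets, two models, one metric, fully defined."""
    rows = []
    for ds, prev, vals in [(0, 0.4, {"A": 0.9, "B": 0.5}),
                           (1, 0.5, {"A": 0.5, "B": 0.9})]:
        for model, v in vals.items():
            rows.append({"dataset": ds, "prevalence": prev, "model": model,
                         "metric": "accuracy", "value": v, "reason": None})
    return EvaluationTable(table=pd.DataFrame(rows))


class TestRankingVariance:
    def test_two_dataset_closed_form(self):
        out = ranking_variance(_toy_table())
        # ranks flip 1<->2 across the two datasets: sample variance 0.5
        assert np.allclose(out["rank_variance"], 0.5)

    def test_constant_ranks_zero_variance(self):
        t = _toy_table().table.copy()
        t.loc[t["dataset"] == 1, "value"] = t.loc[t["dataset"] == 0, "value"].values
        out = ranking_variance(EvaluationTable(table=t))
        assert np.allclose(out["rank_variance"], 0.0)

    def test_invariant_to_dataset_order(self):
        t = _toy_table().table
        shuffled = EvaluationTable(table=t.iloc[::-1].reset_index(drop=True))
        a = ranking_variance(_toy_table()).sort_values(["metric", "model"])
        b = ranking_variance(shuffled).sort_values(["metric", "model"])
        assert np.allclose(a["rank_variance"].values, b["rank_variance"].values)

    def test_undefined_excluded_from_value_variance(self):
        t = _toy_table().table.copy()
        t.loc[0, "value"] = np.nan
        out = ranking_variance(EvaluationTable(table=t))
        row = out[(out.model == "A")].iloc[0]
        assert row["n_value"] == 1
        assert row["n_rank"] == 2  # undefined entries still rank (last)


class TestVarianceEqualityTests:
    def _frame(self, sens_sd, insens_sd, n=200, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for metric, sd in [("TPR", sens_sd), ("AUC", insens_sd)]:
            for model in ("m1", "m2"):
                for i, v in enumerate(rng.normal(0, sd, n)):
                    rows.append({"dataset": i, "metric": metric,
                                 "model": model, "value": v})
        return pd.DataFrame(rows)

    def test_identical_variances_not_rejected(self):
        frame = self._frame(1.0, 1.0)
        res = variance_equality_tests(frame, MetricGroups(), value_col="value")
        assert res["levene"]["p_value"] > 0.05
        assert res["f_test"]["p_value"] > 0.05

    def test_ninefold_variance_ratio_rejected_by_all_three(self):
        frame = self._frame(1.0, 3.0)
        res = variance_equality_tests(frame, MetricGroups(), value_col="value")
        for test in ("f_test", "bartlett", "levene"):
            assert res[test]["p_value"] < 0.05, test

    def test_degenerate_cells_flagged(self):
        frame = self._frame(1.0, 0.0)
        res = variance_equality_tests(frame, MetricGroups(), value_col="value")
        assert any("insensitive" in c for c in res["degenerate_cells"])

    def test_group_overlap_rejected(self):
        with pytest.raises(ValueError):
            MetricGroups(sensitive=frozenset({"TPR"}),
                         insensitive=frozenset({"TPR", "AUC"}))


class TestEvaluateGrid:
    def _dataset(self, n=80, seed=0, separable=False):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        noise = np.zeros(n) if separable else rng.normal(scale=2.0, size=n)
        labels = (x + noise > 0).astype(int)
        return Dataset(features=pd.DataFrame({"x": x}), labels=labels)

    def test_random_guess_only_single_metric(self):
        series = SweepSeries(datasets=[self._dataset()])
        table = evaluate_grid(series, {"randomguess": None},
                              metrics=("accuracy",), split=SplitSpec(seed=0))
        assert len(table.table) == 1
        assert 0 <= table.table["value"].iloc[0] <= 1

    def test_separable_data_auc_is_one(self):
        from prevmetrics import ClassifierSpec
        series = SweepSeries(datasets=[self._dataset(n=200, separable=True)])
        table = evaluate_grid(
            series, {"GLM": ClassifierSpec("GLM", cv_folds=3)},
            metrics=("AUC",), split=SplitSpec(seed=0))
        assert table.table["value"].iloc[0] == pytest.approx(1.0, abs=0.02)

    def test_grid_is_complete(self):
        from prevmetrics import ClassifierSpec
        series = SweepSeries(datasets=[self._dataset(seed=i, n=120)
                                       for i in range(2)])
        # give the two datasets distinct ids
        series = SweepSeries(datasets=[
            Dataset(features=d.features, labels=d.labels, id=i)
            for i, d in enumerate(series)])
        table = evaluate_grid(
            series, {"GLM": ClassifierSpec("GLM", cv_folds=2), "randomguess": None},
            metrics=("accuracy", "TPR", "AUC"), split=SplitSpec(seed=1))
        assert len(table.table) == 2 * 2 * 3
        ranks = rank_table(table)
        assert len(ranks) == 2 * 2 * 3
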