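"""Unit and property tests for the confusion-matrix metric algebra."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prevmetrics import (CATALOGUE, ConfusionMatrix, RatesParam,
                         ScoredPredictions, auc_rank, confusion_at_threshold,
                         confusion_from_labels, get_metric_spec,
                         metric_catalogue, metric_from_confusion,
                         metric_from_rates, roc_points)
from prevmetrics.confusion import LOWER_BETTER, STUDY_METRICS

from conftest import round_half_up

TRUE10 = (1, 0, 0, 0, 0, 1, 1, 0, 0, 1)


# ---------------------------------------------------------------------------
# Building confusion matrices
# ---------------------------------------------------------------------------

class TestConfusionFromLabels:
    @pytest.mark.parametrize("pred, expected", [
        ((1, 1, 0, 0, 0, 1, 1, 0, 0, 1), (4, 0, 5, 1)),
        ((0, 0, 0, 0, 0, 1, 1, 0, 0, 0), (2, 2, 6, 0)),
        ((0, 0, 1, 0, 0, 0, 1, 0, 0, 1), (2, 2, 5, 1)),
    ])
    def test_worked_examples(self, pred, expected):
        cm = confusion_from_labels(TRUE10, pred)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == expected

    def test_perfect_and_all_miss(self):
        cm = confusion_from_labels((1, 0), (1, 0))
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 0, 1, 0)
        cm = confusion_from_labels((1, 1), (0, 0))
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (0, 2, 0, 0)

    def test_counts_partition_sample(self):
        rng = np.random.default_rng(0)
        t, p = rng.integers(0, 2, 50), rng.integers(0, 2, 50)
        cm = confusion_from_labels(t, p)
        assert cm.n == 50
        assert cm.positives == t.sum()

    def test_errors(self):
        with pytest.raises(ValueError):
            confusion_from_labels((1, 0), (1,))
        with pytest.raises(ValueError):
            confusion_from_labels((1, 2), (1, 0))
        with pytest.raises(ValueError):
            confusion_from_labels((), ())


class TestConfusionAtThreshold:
    def test_basic(self):
        p = ScoredPredictions(labels=np.array([1, 0]), scores=np.array([0.9, 0.1]))
        cm = confusion_at_threshold(p, 0.5)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 0, 1, 0)

    def test_zero_threshold_all_positive(self):
        p = ScoredPredictions(labels=np.array([1, 0, 1, 0]),
                              scores=np.array([0.2, 0.8, 0.0, 0.4]))
        cm = confusion_at_threshold(p, 0.0)
        assert cm.fn == 0 and cm.tn == 0

    def test_tie_rule_score_equal_threshold_is_positive(self):
        p = ScoredPredictions(labels=np.array([1, 0]), scores=np.array([0.5, 0.5]))
        cm = confusion_at_threshold(p, 0.5)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 0, 0, 1)
        cm = confusion_at_threshold(p, 0.5, rule="gt")
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (0, 1, 1, 0)


# ---------------------------------------------------------------------------
# Metric formulas: exact worked values
# ---------------------------------------------------------------------------

class TestCountFormulas:
    @pytest.mark.parametrize("pred, mcc, acc", [
        ((1, 1, 0, 0, 0, 1, 1, 0, 0, 1), 0.82, 0.9),
        ((0, 0, 0, 0, 0, 1, 1, 0, 0, 0), 0.61, 0.8),
        ((0, 0, 1, 0, 0, 0, 1, 0, 0, 1), 0.36, 0.7),
    ])
    def test_mcc_worked_examples(self, pred, mcc, acc):
        cm = confusion_from_labels(TRUE10, pred)
        assert round_half_up(metric_from_confusion("MCC", cm).unwrap(), 2) == mcc
        assert round_half_up(metric_from_confusion("accuracy", cm).unwrap(), 2) == acc

    def test_reference_table_reproduces(self, fixtures_by_name):
        """Every published metric row recomputes from its confusion counts."""
        checked = 0
        for fx in fixtures_by_name.values():
            if fx.confusion is None:
                continue
            for metric, (published, nd) in fx.expected.items():
                if metric in fx.known_discrepant:
                    continue
                got = metric_from_confusion(metric, fx.confusion).unwrap()
                assert round_half_up(got, nd) == published, (fx.name, metric)
                checked += 1
        assert checked == 6 * 15

    def test_fbeta_rows_are_known_discrepant(self, fixtures_by_name):
        """The published F-beta rows do not recompute from the counts."""
        fx = fixtures_by_name["reference_GBM"]
        for metric in ("F0.5", "F2"):
            got = metric_from_confusion(metric, fx.confusion).unwrap()
            assert abs(got - fx.expected[metric][0]) > 0.05

    @pytest.mark.parametrize("metric, counts, reason_part", [
        ("PPV", (0, 5, 5, 0), "predicted positive"),
        ("TPR", (0, 0, 5, 5), "positive cases"),
        ("DOR", (5, 0, 5, 0), "FPR*FNR"),
        ("MCC", (5, 0, 0, 5), "marginal"),
    ])
    def test_zero_denominators_are_tagged(self, metric, counts, reason_part):
        mv = metric_from_confusion(metric, ConfusionMatrix(*counts))
        assert not mv.defined
        assert reason_part in mv.reason
        with pytest.raises(ValueError):
            mv.unwrap()

    def test_unknown_metric_rejected(self):
        with pytest.raises(KeyError):
            metric_from_confusion("bogus", ConfusionMatrix(1, 1, 1, 1))

    def test_catalogue_table(self):
        cat = metric_catalogue()
        assert set(STUDY_METRICS) <= set(cat["name"])
        lower = set(cat[cat.orientation == "lower-better"]["name"])
        assert lower == set(LOWER_BETTER)


class TestRatesFormulas:
    GBM_RATES = RatesParam(n=1243, phi=562 / 1243, tpr=339 / 562, tnr=517 / 681)

    @pytest.mark.parametrize("metric, expected", [
        ("accuracy", 0.689), ("MCC", 0.367), ("F1", 0.637), ("kappa", 0.366),
    ])
    def test_reference_values(self, metric, expected):
        got = metric_from_rates(metric, self.GBM_RATES).unwrap()
        assert round_half_up(got, 3) == expected

    def test_auc_rejected(self):
        with pytest.raises(ValueError, match="AUC"):
            metric_from_rates("AUC", self.GBM_RATES)

    def test_rates_roundtrip_exact_when_divisible(self):
        cm = ConfusionMatrix(30, 10, 45, 15)
        assert cm.to_rates().to_confusion() == cm

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            RatesParam(n=10, phi=0.0, tpr=0.5, tnr=0.5)
        with pytest.raises(ValueError):
            RatesParam(n=10, phi=0.5, tpr=1.5, tnr=0.5)


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------

confusion_matrices = st.tuples(
    st.integers(0, 200), st.integers(0, 200),
    st.integers(0, 200), st.integers(0, 200),
).filter(lambda c: c[0] + c[1] > 0 and c[2] + c[3] > 0).map(
    lambda c: ConfusionMatrix(*c))

RATE_FORM_METRICS = [m for m in STUDY_METRICS if m != "AUC"]


@settings(derandomize=True, max_examples=300)
@given(cm=confusion_matrices)
def test_parameterization_equivalence(cm):
    """Count-form and rate-form formulas agree on every valid matrix."""
    rp = cm.to_rates()
    for metric in RATE_FORM_METRICS:
        a = metric_from_confusion(metric, cm)
        b = metric_from_rates(metric, rp)
        assert a.defined == b.defined, metric
        if a.defined:
            assert abs(a.value - b.value) < 1e-10, metric


@settings(derandomize=True, max_examples=300)
@given(cm=confusion_matrices)
def test_metric_ranges(cm):
    for metric in RATE_FORM_METRICS:
        mv = metric_from_confusion(metric, cm)
        if mv.defined:
            lo, hi = get_metric_spec(metric).range
            assert lo - 1e-12 <= mv.value <= hi + 1e-12, metric


@settings(derandomize=True, max_examples=200)
@given(labels=st.lists(st.sampled_from([0, 1]), min_size=2, max_size=12),
       preds=st.lists(st.sampled_from([0, 1]), min_size=2, max_size=12))
def test_mcc_equals_pearson_correlation(labels, preds):
    """MCC is the Pearson correlation of the two binary label vectors."""
    n = min(len(labels), len(preds))
    t, p = np.array(labels[:n]), np.array(preds[:n])
    cm = confusion_from_labels(t, p)
    mv = metric_from_confusion("MCC", cm)
    if t.std() == 0 or p.std() == 0:
        assert not mv.defined
    else:
        expected = np.corrcoef(t, p)[0, 1]
        assert mv.value == pytest.approx(expected, abs=1e-12)


def _auc_brute_force(labels, scores):
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p, q in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


@settings(derandomize=True, max_examples=200)
@given(data=st.lists(
    st.tuples(st.sampled_from([0, 1]),
              st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.5, 0.75, 0.9, 1.0])),
    min_size=2, max_size=20).filter(
        lambda d: 0 < sum(l for l, _ in d) < len(d)))
def test_auc_equals_brute_force_pair_statistic(data):
    labels = np.array([l for l, _ in data])
    scores = np.array([s for _, s in data])
    preds = ScoredPredictions(labels=labels, scores=scores)
    assert auc_rank(preds) == pytest.approx(
        _auc_brute_force(labels, scores), abs=1e-12)


class TestAuc:
    def test_perfect_separation(self):
        p = ScoredPredictions(labels=np.array([1, 1, 0, 0]),
                              scores=np.array([0.9, 0.8, 0.2, 0.1]))
        assert auc_rank(p) == 1.0

    def test_all_ties(self):
        p = ScoredPredictions(labels=np.array([1, 0, 1, 0]),
                              scores=np.full(4, 0.3))
        assert auc_rank(p) == 0.5

    def test_five_point_example(self):
        labels = np.array([1, 0, 1, 0, 0])
        scores = np.array([0.7, 0.6, 0.5, 0.5, 0.1])
        p = ScoredPredictions(labels=labels, scores=scores)
        assert auc_rank(p) == pytest.approx(_auc_brute_force(labels, scores))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        scores = rng.random(40)
        p1 = ScoredPredictions(labels=labels, scores=scores)
        p2 = ScoredPredictions(labels=labels, scores=scores ** 3)
        assert auc_rank(p1) == pytest.approx(auc_rank(p2), abs=1e-12)

    def test_single_class_rejected(self):
        p = ScoredPredictions(labels=np.ones(3, int), scores=np.full(3, 0.5))
        with pytest.raises(ValueError):
            auc_rank(p)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(11)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], 100)
        p = ScoredPredictions(labels=labels, scores=scores)
        assert auc_rank(p) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)


class TestRocPoints:
    def test_perfect_separation_hits_corner(self):
        p = ScoredPredictions(labels=np.array([1, 0]), scores=np.array([0.9, 0.1]))
        pts = roc_points(p)
        assert any(np.allclose(pt, (0, 1)) for pt in pts)

    def test_constant_scores_diagonal(self):
        p = ScoredPredictions(labels=np.array([1, 0]), scores=np.full(2, 0.4))
        pts = roc_points(p)
        assert np.allclose(pts[0], (0, 0)) and np.allclose(pts[-1], (1, 1))
        assert np.trapezoid(pts[:, 1], pts[:, 0]) == pytest.approx(0.5)

    def test_area_equals_rank_auc(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        scores = rng.choice(np.linspace(0, 1, 9), 60)
        p = ScoredPredictions(labels=labels, scores=scores)
        pts = roc_points(p)
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)
        area = np.trapezoid(pts[:, 1], pts[:, 0])
        assert area == pytest.approx(auc_rank(p), abs=1e-12)


@pytest.mark.parametrize("tpr, tnr", [(0.7, 0.6), (0.9, 0.2), (0.5, 0.5)])
def test_f1_strictly_increasing_in_prevalence(tpr, tnr):
    """With TPR and TNR fixed, F1 rises strictly with prevalence."""
    phis = np.linspace(0.02, 0.98, 40)
    vals = [metric_from_rates("F1", RatesParam(n=1000, phi=p, tpr=tpr, tnr=tnr)).unwrap()
            for p in phis]
    assert np.all(np.diff(vals) > 0)


@settings(derandomize=True, max_examples=200)
@given(cm=confusion_matrices)
def test_accuracy_is_convex_combination_of_tpr_tnr(cm):
    rp = cm.to_rates()
    acc = metric_from_rates("accuracy", rp).unwrap()
    assert min(rp.tpr, rp.tnr) - 1e-12 <= acc <= max(rp.tpr, rp.tnr) + 1e-12


def test_scored_predictions_csv_roundtrip(tmp_path):
    p = ScoredPredictions(labels=np.array([1, 0, 1]),
                          scores=np.array([0.9, 0.2, 0.6]))
    path = tmp_path / "preds.csv"
    p.to_csv(path)
    q = ScoredPredictions.from_csv(path)
    assert np.array_equal(p.labels, q.labels)
    assert np.allclose(p.scores, q.scores)
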