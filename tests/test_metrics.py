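import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from sdmeval import PredictionSet, confusion_counts, evaluate_all, kappa, maximize_over_thresholds, tjur_r2, tss
from sdmeval.metrics import (
    ConfusionCounts,
    accuracy_sensitivity_specificity,
    auc,
    transform_auc,
    transform_tjur,
)


def brute_force_auc(y, p, tie_policy):
    """O(n^2) double sum straight from the defining formula."""
    y = np.asarray(y)
    p = np.asarray(p)
    num, den = 0.0, 0
    for i in np.flatnonzero(y == 1):
        for j in np.flatnonzero(y == 0):
            den += 1
            if p[i] > p[j]:
                num += 1
            elif p[i] == p[j] and tie_policy == "half":
                num += 0.5
    return num / den


def grid_max(ps, statistic, n_grid=4001):
    """Dense threshold sweep used as the independent maximization oracle."""
    best, best_t = -np.inf, None
    for t in np.linspace(0, 1, n_grid):
        cc = confusion_counts(ps, t)
        val = tss(cc) if statistic == "tss" else kappa(cc)
        if not math.isnan(val) and val > best:
            best, best_t = val, t
    return best, best_t


class TestConfusionMatrix:
    def test_micro_example_at_half(self, micro_ps):
        cc = confusion_counts(micro_ps, 0.5)
        assert (cc.a, cc.b, cc.c, cc.d) == (1, 1, 1, 1)
        assert accuracy_sensitivity_specificity(cc) == (0.5, 0.5, 0.5)
        assert tss(cc) == pytest.approx(0.0)
        assert kappa(cc) == pytest.approx(0.0)

    def test_perfect_predictor(self):
        ps = PredictionSet(np.array([1, 0, 1, 0]), np.array([1.0, 0.0, 1.0, 0.0]))
        cc = confusion_counts(ps, 0.5)
        assert cc.b == cc.c == 0
        assert accuracy_sensitivity_specificity(cc) == (1.0, 1.0, 1.0)
        assert tss(cc) == 1.0 and kappa(cc) == 1.0

    def test_zero_threshold_predicts_everything_present(self, micro_ps):
        cc = confusion_counts(micro_ps, 0.0)
        assert cc.c == cc.d == 0

    def test_boundary_inclusive(self):
        # p == t counts as a predicted presence
        ps = PredictionSet(np.array([1, 0]), np.array([0.5, 0.2]))
        assert confusion_counts(ps, 0.5).a == 1

    def test_undefined_ratios_are_nan_not_errors(self):
        ps = PredictionSet(np.array([0, 0]), np.array([0.2, 0.9]))
        _, sens, spec = accuracy_sensitivity_specificity(confusion_counts(ps, 0.5))
        assert math.isnan(sens) and not math.isnan(spec)

    def test_kappa_expanded_chance_formula(self):
        cc = ConfusionCounts(a=40, b=5, c=10, d=45, threshold=0.5)
        assert kappa(cc) == pytest.approx(0.7)

    def test_inverted_predictions_hit_minus_one(self):
        ps = PredictionSet(np.array([1, 1, 0, 0]), np.array([0.0, 0.0, 1.0, 1.0]))
        assert tss(confusion_counts(ps, 0.5)) == pytest.approx(-1.0)


class TestAUCAndTjur:
    def test_micro_example(self, micro_ps):
        assert auc(micro_ps, "half") == pytest.approx(0.75)
        assert auc(micro_ps, "strict") == pytest.approx(0.75)
        assert tjur_r2(micro_ps) == pytest.approx(0.10)

    def test_perfect_and_constant(self):
        perfect = PredictionSet(np.array([1, 0]), np.array([1.0, 0.0]))
        assert auc(perfect) == 1.0 and tjur_r2(perfect) == 1.0
        const = PredictionSet(np.array([1, 1, 0]), np.array([0.4, 0.4, 0.4]))
        assert auc(const, "half") == 0.5
        assert auc(const, "strict") == 0.0
        assert tjur_r2(const) == pytest.approx(0.0)

    def test_single_class_is_missing(self):
        ps = PredictionSet(np.array([1, 1]), np.array([0.2, 0.9]))
        assert math.isnan(auc(ps)) and math.isnan(tjur_r2(ps))

    @pytest.mark.parametrize("tie_policy", ["half", "strict"])
    def test_matches_double_sum_with_ties(self, tie_policy):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n = rng.integers(4, 60)
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            p = rng.choice([0.0, 0.1, 0.25, 0.5, 0.9], size=n)  # force ties
            ps = PredictionSet(y, p)
            assert auc(ps, tie_policy) == pytest.approx(
                brute_force_auc(y, p, tie_policy), abs=1e-12)

    def test_agrees_with_sklearn_oracle(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 300)
        p = rng.random(300)
        ps = PredictionSet(y, p)
        assert auc(ps, "half") == pytest.approx(roc_auc_score(y, p), abs=1e-12)

    def test_auc_invariant_under_increasing_transform_tjur_not(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 100)
        p = rng.random(100) * 0.9 + 0.05
        a1 = auc(PredictionSet(y, p))
        a2 = auc(PredictionSet(y, p**2))
        assert a1 == pytest.approx(a2, abs=1e-12)
        assert tjur_r2(PredictionSet(y, p)) != pytest.approx(tjur_r2(PredictionSet(y, p**2)), abs=1e-6)

    def test_tjur_invariant_under_reindexing(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 50)
        p = rng.random(50)
        perm = rng.permutation(50)
        assert tjur_r2(PredictionSet(y, p)) == pytest.approx(tjur_r2(PredictionSet(y[perm], p[perm])))


class TestThresholdMaximization:
    def test_micro_example_value_and_smallest_threshold(self, micro_ps):
        val, thr = maximize_over_thresholds(micro_ps, "tss")
        assert val == pytest.approx(0.5)
        assert 0.1 < thr <= 0.2

    def test_perfect_predictor(self):
        ps = PredictionSet(np.array([1, 0]), np.array([1.0, 0.0]))
        assert maximize_over_thresholds(ps, "tss")[0] == 1.0
        assert maximize_over_thresholds(ps, "kappa")[0] == 1.0

    def test_constant_predictor_maxes_at_zero(self):
        ps = PredictionSet(np.array([1, 0, 1]), np.array([0.3, 0.3, 0.3]))
        assert maximize_over_thresholds(ps, "tss")[0] == pytest.approx(0.0)

    def test_single_class_missing(self):
        ps = PredictionSet(np.array([1, 1]), np.array([0.1, 0.9]))
        assert math.isnan(maximize_over_thresholds(ps, "tss")[0])

    @pytest.mark.parametrize("statistic", ["tss", "kappa"])
    def test_equals_dense_grid_oracle(self, statistic):
        # p on a 0.001 lattice so every step of the statistic is wider than
        # the 4001-point grid spacing and the oracle is exact
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = rng.integers(5, 80)
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            p = rng.integers(0, 1001, n) / 1000.0
            ps = PredictionSet(y, p)
            got, _ = maximize_over_thresholds(ps, statistic)
            ref, _ = grid_max(ps, statistic)
            assert got == pytest.approx(ref, abs=1e-12)

    @pytest.mark.parametrize("statistic, fn", [("tss", tss), ("kappa", kappa)])
    def test_dominates_any_fixed_threshold(self, statistic, fn):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 60)
        p = rng.random(60)
        ps = PredictionSet(y, p)
        best, _ = maximize_over_thresholds(ps, statistic)
        for t in rng.random(25):
            val = fn(confusion_counts(ps, t))
            if not math.isnan(val):
                assert best >= val - 1e-12


class TestTransformsAndEvaluateAll:
    @pytest.mark.parametrize("raw, expected", [(0.75, 0.5), (0.5, 0.0), (1.0, 1.0)])
    def test_auc_transform(self, raw, expected):
        assert transform_auc(raw) == pytest.approx(expected)

    def test_tjur_signed_root(self):
        assert transform_tjur(0.04) == pytest.approx(0.2)
        assert transform_tjur(-0.04) == pytest.approx(-0.2)
        assert math.isnan(transform_tjur(float("nan")))

    def test_evaluate_all_micro(self, micro_ps):
        ms = evaluate_all(micro_ps)
        assert ms.auc == pytest.approx(0.75)
        assert ms.tjur_r2 == pytest.approx(0.10)
        assert ms.max_tss == pytest.approx(0.5)
        assert ms.transformed_auc == pytest.approx(0.5)
        assert ms.n_presences == 2 and ms.n_absences == 2

    def test_evaluate_all_single_class_all_missing(self):
        ms = evaluate_all(PredictionSet(np.array([1, 1, 1]), np.array([0.1, 0.5, 0.9])))
        assert all(math.isnan(v) for v in (ms.auc, ms.tjur_r2, ms.max_kappa, ms.max_tss))

    def test_evaluate_all_perfect(self):
        ms = evaluate_all(PredictionSet(np.array([1, 0, 1, 0]), np.array([1.0, 0.0, 1.0, 0.0])))
        assert (ms.auc, ms.tjur_r2, ms.max_kappa, ms.max_tss) == (1.0, 1.0, 1.0, 1.0)


@given(
    y=st.lists(st.integers(0, 1), min_size=2, max_size=60),
    seed=st.integers(0, 10_000),
)
@settings(max_examples=150, deadline=None)
def test_metrics_stay_in_their_ranges(y, seed):
    """Fuzzed inputs never push a metric outside its documented range."""
    y = np.array(y)
    p = np.random.default_rng(seed).random(len(y))
    ms = evaluate_all(PredictionSet(y, p))
    if 0 < y.sum() < len(y):
        assert 0.0 <= ms.auc <= 1.0
        assert -1.0 <= ms.tjur_r2 <= 1.0
        assert -1.0 <= ms.max_kappa <= 1.0
        assert -1.0 <= ms.max_tss <= 1.0
    else:
        assert math.isnan(ms.auc)
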