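import math

import numpy as np
import pandas as pd
import pytest

from plasmabm.errors import CohortValidationError
from plasmabm.stats import (compare_groups, fit_survival, median_split,
                            roc_optimal_cutoff, stratify_two_factor)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def auc_by_pair_counting(values, labels):
    """AUC as the Mann-Whitney statistic U / (n1 * n0), by brute force."""
    pos = [v for v, l in zip(values, labels) if l]
    neg = [v for v, l in zip(values, labels) if not l]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def product_limit_oracle(times, events):
    """Kaplan-Meier by direct product over event times."""
    order = np.argsort(times, kind="stable")
    times = np.asarray(times, float)[order]
    events = np.asarray(events, bool)[order]
    surv = {}
    s = 1.0
    for t in np.unique(times):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & events)
        if d > 0:
            s *= 1.0 - d / at_risk
        surv[float(t)] = s
    return surv


def fisher_oracle(table):
    """Two-sided Fisher p by full enumeration of tables with fixed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


# ---------------------------------------------------------------------------

class TestRocCutoff:
    def test_perfect_separation(self):
        res = roc_optimal_cutoff([1, 2, 3, 4], [True, True, False, False])
        assert res.auc == pytest.approx(1.0)
        assert 2 < res.cutoff < 3
        assert res.orientation == "high_unfavorable"
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_identical_distributions(self):
        res = roc_optimal_cutoff([1, 2, 1, 2], [True, True, False, False])
        assert res.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(CohortValidationError):
            roc_optimal_cutoff([1, 2, 3], [True, True, True])

    def test_auc_matches_pair_counting_on_random_cohorts(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(10, 201))
            labels = rng.random(n) < 0.3
            if labels.all() or not labels.any():
                continue
            values = rng.normal(0, 1, n) - 0.8 * labels
            values = np.round(values, 1)  # force ties
            res = roc_optimal_cutoff(values, labels)
            oracle = auc_by_pair_counting(values, labels)
            assert res.auc == pytest.approx(max(oracle, 1 - oracle), abs=1e-12)
            assert 0.5 <= res.auc <= 1.0


class TestMedianSplit:
    def test_even_split(self):
        cutoff, high = median_split([1, 2, 3, 4])
        assert cutoff == 2.5
        assert high.sum() == 2

    def test_all_equal_everyone_high(self):
        cutoff, high = median_split([5, 5, 5])
        assert high.all()

    def test_ties_at_median_make_high_group_larger(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.uniform(0, 11, 30), [11.5] * 6,
                                 rng.uniform(12, 30, 28)])
        cutoff, high = median_split(values)
        assert cutoff == pytest.approx(11.5)
        # direct count oracle: values >= median
        assert high.sum() == int(np.sum(values >= cutoff))
        assert high.sum() > (~high).sum()


class TestCompareGroups:
    def test_fisher_identical_margins_no_association(self):
        res = compare_groups(table=[[5, 5], [5, 5]])
        assert res.method == "fisher_exact"
        assert res.p_value == pytest.approx(1.0)

    def test_fisher_matches_enumeration_oracle(self):
        table = [[3, 34], [3, 24]]
        res = compare_groups(table=table)
        assert res.p_value == pytest.approx(fisher_oracle(table), rel=1e-9)

    def test_mannwhitney_detects_large_shift(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 60)
        y = rng.normal(1.2, 1, 60)
        assert compare_groups(x, y).p_value < 0.05

    def test_exact_method_for_tiny_samples(self):
        res = compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.method == "mannwhitney_exact"

    def test_empty_group_rejected(self):
        with pytest.raises(CohortValidationError):
            compare_groups([], [1.0])


class TestFitSurvival:
    def test_product_limit_uncensored_hand_case(self):
        fit = fit_survival([1, 2, 3, 4], [True] * 4)
        surv = dict(zip(fit.km["time"], fit.km["survival"]))
        assert surv[1.0] == pytest.approx(0.75)
        assert surv[2.0] == pytest.approx(0.50)
        assert surv[4.0] == pytest.approx(0.0)
        assert 2.0 <= fit.median_months <= 3.0

    def test_all_censored_median_not_reached(self):
        fit = fit_survival([5, 6, 7], [False, False, False])
        assert fit.median_months is None
        assert not fit.median_reached

    def test_cox_refused_without_events(self):
        with pytest.raises(CohortValidationError, match="censored"):
            fit_survival([1, 2, 3], [False] * 3,
                         covariates=pd.DataFrame({"x": [0, 1, 0]}))

    def test_km_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(3, 51))
            times = np.round(rng.exponential(5, n), 1) + 0.1
            events = rng.random(n) < 0.7
            if not events.any():
                continue
            fit = fit_survival(times, events)
            oracle = product_limit_oracle(times, events)
            got = dict(zip(fit.km["time"], fit.km["survival"]))
            for t, s in oracle.items():
                assert got[t] == pytest.approx(s, abs=1e-12)

    def test_survival_curve_non_increasing(self):
        rng = np.random.default_rng(3)
        fit = fit_survival(rng.exponential(5, 80), rng.random(80) < 0.6)
        assert (np.diff(fit.km["survival"]) <= 1e-12).all()

    def test_km_and_cox_agree_on_worse_group(self):
        """With no censoring, the lower KM curve must carry log-HR > 0."""
        rng = np.random.default_rng(5)
        group = np.repeat([0, 1], 100)
        times = rng.exponential(np.where(group == 1, 2.0, 8.0))
        fit0 = fit_survival(times[group == 0], np.ones(100, bool))
        fit1 = fit_survival(times[group == 1], np.ones(100, bool))
        cox = fit_survival(times, np.ones(200, bool),
                           covariates=pd.DataFrame({"g": group})).cox
        assert cox.loc["g", "hr"] > 1.0
        assert fit1.median_months < fit0.median_months


class TestStratifyTwoFactor:
    def test_risk_factor_counts(self):
        labels = stratify_two_factor([True, False, True, None],
                                     [True, False, False, True])
        assert labels == [2, 0, 1, None]
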