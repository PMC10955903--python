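"""Prevalence ratios, Fisher exact, Wilson intervals, agreement, survival."""

import math
from itertools import product

import numpy as np
import pytest

from sasurv.stats import (evaluate_ppv, fisher_exact_2x2, km_logrank,
                          prevalence_ratio, specific_agreement,
                          wilson_interval)


def oracle_fisher(a, b, c, d):
    """Exact two-sided Fisher p by enumeration over all tables with the
    observed margins, using exact integer comparison of hypergeometric
    weights C(r1,k)*C(r2,c1-k)."""
    r1, r2, c1 = a + b, c + d, a + c
    w_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = 0
    num = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        total += w
        if w <= w_obs:
            num += w
    return num / total


class TestFisher:
    def test_identical_rows_give_p_one(self):
        assert fisher_exact_2x2([[10, 90], [10, 90]]) == pytest.approx(1.0)

    def test_zero_margin_convention(self):
        assert fisher_exact_2x2([[0, 0], [5, 7]]) == 1.0

    def test_negative_or_misshapen_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -2], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])

    def test_matches_enumeration_oracle_small_margins(self):
        """Probability-mass two-sided rule vs exhaustive enumeration for
        every table with row sums <= 12, plus random tables with margins
        up to 30."""
        for a, b, c, d in product(range(5), repeat=4):
            if (a + b) and (c + d) and (a + c) and (b + d):
                assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
                    oracle_fisher(a, b, c, d), abs=1e-9), (a, b, c, d)
        rng = np.random.default_rng(0)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 16, size=4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
                oracle_fisher(int(a), int(b), int(c), int(d)), abs=1e-9)

    def test_strong_association_highly_significant(self):
        assert fisher_exact_2x2([[360, 5594], [639, 7430]]) < 0.0001


class TestPrevalenceRatio:
    @pytest.mark.parametrize("a1,n1,a2,n2,pr,lo,hi", [
        (360, 5954, 639, 8069, 1.3, 1.16, 1.48),   # domestic violence
        (244, 5954, 567, 8069, 1.7, 1.48, 1.98),   # sexual violence
        (2160, 5954, 3199, 8069, 1.1, 1.05, 1.14),  # SA history
    ])
    def test_reference_contingency_rows(self, a1, n1, a2, n2, pr, lo, hi):
        cmp = prevalence_ratio(a1, n1, a2, n2)
        assert round(cmp.pr, 1) == pr
        assert round(cmp.ci[0], 2) == lo
        assert round(cmp.ci[1], 2) == hi
        assert cmp.fisher_p < 0.0001

    def test_identity_table(self):
        cmp = prevalence_ratio(10, 100, 10, 100)
        assert cmp.pr == pytest.approx(1.0)
        assert cmp.fisher_p == pytest.approx(1.0)
        assert cmp.ci[0] < 1.0 < cmp.ci[1]

    def test_symmetric_inversion(self):
        fwd = prevalence_ratio(25, 400, 60, 500)
        rev = prevalence_ratio(60, 500, 25, 400)
        assert fwd.pr == pytest.approx(1 / rev.pr)
        assert fwd.ci[0] == pytest.approx(1 / rev.ci[1])
        assert fwd.ci[1] == pytest.approx(1 / rev.ci[0])
        assert fwd.fisher_p == pytest.approx(rev.fisher_p)

    def test_zero_pre_positives_undefined(self):
        cmp = prevalence_ratio(0, 100, 5, 100)
        assert cmp.pr is None and cmp.ci is None
        assert 0 < cmp.fisher_p < 1

    def test_ci_contains_point_estimate(self):
        cmp = prevalence_ratio(15, 300, 40, 350)
        assert cmp.ci[0] < cmp.pr < cmp.ci[1]

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            prevalence_ratio(5, 4, 1, 10)


class TestWilson:
    @pytest.mark.parametrize("k,n,lo,hi", [
        (72, 85, 0.76, 0.91),  # hybrid SA detector, pre-pandemic sample
        (22, 23, 0.79, 0.99),  # risk-factor detector sample
    ])
    def test_reference_chart_review_intervals(self, k, n, lo, hi):
        w = wilson_interval(k, n)
        assert round(w[0], 2) == lo and round(w[1], 2) == hi

    def test_zero_successes_lower_bound_zero(self):
        lo, hi = wilson_interval(0, 10)
        assert lo == pytest.approx(0.0) and hi > 0

    def test_bounds_bracket_estimate(self):
        for k, n in [(1, 10), (5, 10), (10, 10), (85, 100)]:
            lo, hi = wilson_interval(k, n)
            tol = 1e-12
            assert 0 <= lo <= k / n + tol and k / n - tol <= hi <= 1 + tol

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            wilson_interval(5, 0)
        with pytest.raises(ValueError):
            wilson_interval(11, 10)

    def test_coverage_near_nominal(self):
        """95% coverage of p=0.85 at n=85 over 10,000 binomial draws."""
        rng = np.random.default_rng(1)
        ks = rng.binomial(85, 0.85, size=10_000)
        covered = 0
        for k in np.unique(ks):
            lo, hi = wilson_interval(int(k), 85)
            if lo <= 0.85 <= hi:
                covered += int((ks == k).sum())
        assert 0.93 <= covered / 10_000 <= 0.97

    def test_ppv_evaluation_wraps_interval(self):
        ev = evaluate_ppv(72, 85)
        assert ev.ppv == pytest.approx(72 / 85)
        assert ev.ci == wilson_interval(72, 85)


class TestSpecificAgreement:
    def test_mixed_concordance(self):
        pa, na = specific_agreement(12, 1, 1, 1)
        assert round(pa, 2) == 0.92 and na == pytest.approx(0.5)

    def test_perfect_agreement(self):
        assert specific_agreement(5, 0, 0, 5) == (1.0, 1.0)

    def test_no_negatives_observable(self):
        pa, na = specific_agreement(5, 0, 0, 0)
        assert pa == 1.0 and na is None

    def test_all_zero(self):
        assert specific_agreement(0, 0, 0, 0) == (None, None)

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            specific_agreement(-1, 0, 0, 0)


class TestSurvival:
    def test_identical_groups_null_result(self):
        d = np.arange(1.0, 41.0)
        e = np.ones(40, bool)
        res = km_logrank({"pre": (d, e), "post": (d.copy(), e.copy())})
        assert res.logrank_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_km_curves_monotone_from_one(self):
        rng = np.random.default_rng(3)
        groups = {
            "a": (rng.exponential(5, 200) + 0.1, rng.random(200) < 0.8),
            "b": (rng.exponential(9, 200) + 0.1, rng.random(200) < 0.8),
        }
        res = km_logrank(groups)
        for curve in res.curves.values():
            surv = curve["survival"].to_numpy()
            assert surv[0] == pytest.approx(1.0)
            assert (np.diff(surv) <= 1e-12).all()

    def test_rate_ratio_two_detected(self):
        rng = np.random.default_rng(4)
        groups = {
            "fast": (rng.exponential(5, 500), np.ones(500, bool)),
            "slow": (rng.exponential(10, 500), np.ones(500, bool)),
        }
        assert km_logrank(groups).p_value < 0.001

    def test_all_censored_flat_curves_p_one(self):
        d = np.full(30, 10.0)
        e = np.zeros(30, bool)
        res = km_logrank({"a": (d, e), "b": (d.copy(), e.copy())})
        assert res.p_value == 1.0
        for curve in res.curves.values():
            assert (curve["survival"] == 1.0).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank({"a": (np.array([]), np.array([])),
                        "b": (np.ones(3), np.ones(3, bool))})

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank({"a": (np.ones(3), np.ones(3, bool))})

    def test_logrank_type_one_error_near_nominal(self):
        """Null rejection rate ~5%: replicate two-group tests on identical
        exponential populations (Monte-Carlo band for 1,500 replicates)."""
        rng = np.random.default_rng(9)
        n = 40
        rejections = 0
        reps = 1500
        for _ in range(reps):
            g1 = rng.exponential(7, n)
            g2 = rng.exponential(7, n)
            e = np.ones(n, bool)
            if km_logrank({"a": (g1, e), "b": (g2, e)}).p_value <= 0.05:
                rejections += 1
        rate = rejections / reps
        band = 3 * math.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < band + 0.01
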