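"""Contingency tests, rank correlation, Kaplan-Meier and log-rank."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from taavet.clinical_stats import (
    association_battery,
    chi_squared_test,
    fisher_exact_2x2,
    km_curve,
    logrank_test,
    spearman_rho,
)
from taavet.expression_filter import ValidationError


def fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p by integer enumeration (common denominator).

    With margins fixed, the point probability of top-left count x is
    proportional to C(r1, x) * C(n - r1, c1 - x); comparing those integers
    is exact, so no floating tolerance is needed.
    """
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    weights = {x: math.comb(r1, x) * math.comb(n - r1, c1 - x) for x in range(lo, hi + 1)}
    w_obs = weights[a]
    return sum(w for w in weights.values() if w <= w_obs) / math.comb(n, c1)


class TestFisherExact:
    def test_diagonal_table_full_enumeration(self):
        # [[0, 5], [5, 0]]: 6 admissible tables with these margins
        p = fisher_exact_2x2([[0, 5], [5, 0]])
        assert p == pytest.approx(fisher_oracle(0, 5, 5, 0), abs=1e-12)

    def test_identical_rows_no_association(self):
        assert fisher_exact_2x2([[4, 7], [4, 7]]) == 1.0

    def test_worked_table_matches_oracle(self):
        p = fisher_exact_2x2([[1, 9], [11, 3]])
        assert p == pytest.approx(fisher_oracle(1, 9, 11, 3), abs=1e-12)

    def test_zero_margin_convention(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0
        assert fisher_exact_2x2([[0, 3], [0, 4]]) == 1.0

    def test_scipy_cross_check_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            t = rng.integers(0, 15, size=(2, 2))
            if t.sum() == 0:
                continue
            assert fisher_exact_2x2(t) == pytest.approx(
                stats.fisher_exact(t)[1], rel=1e-9
            )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[1.5, 2], [3, 4]])
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[-1, 2], [3, 4]])


class TestChiSquared:
    def test_independence_gives_zero_statistic(self):
        stat, p, df = chi_squared_test([[10, 20], [20, 40]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        table = np.array([[12, 5], [7, 10]])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        by_hand = ((table - expected) ** 2 / expected).sum()
        stat, p, df = chi_squared_test(table)
        assert stat == pytest.approx(by_hand, abs=1e-12)
        assert df == 1

    def test_df_for_3x2(self):
        assert chi_squared_test([[5, 6], [7, 8], [9, 10]])[2] == 2

    def test_zero_expected_cell_advises_exact(self):
        with pytest.raises(ValidationError, match="exact"):
            chi_squared_test([[0, 0], [3, 4]])


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3, 5], [10, 20, 21, 99])[0] == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3, 5], [99, 21, 20, 10])[0] == pytest.approx(-1.0)

    def test_ties_match_exhaustive_rank_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        rho, _ = spearman_rho(x, y)
        # oracle: average ranks by brute-force position counting + Pearson
        def brute_ranks(v):
            return [
                1 + sum(1 for w in v if w < u) + (sum(1 for w in v if w == u) - 1) / 2
                for u in v
            ]
        ref = np.corrcoef(brute_ranks(x), brute_ranks(y))[0, 1]
        assert rho == pytest.approx(ref, abs=1e-12)

    def test_exact_permutation_p_small_n(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        rho, p = spearman_rho(x, y)
        # independent oracle: count permutations with |rho| at least as extreme
        rx = stats.rankdata(x)
        count = 0
        perms = list(itertools.permutations(stats.rankdata(y)))
        for perm in perms:
            r = np.corrcoef(rx, perm)[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        assert p == pytest.approx(count / len(perms), abs=1e-12)

    def test_constant_input_undefined(self):
        with pytest.raises(ValidationError):
            spearman_rho([1, 1, 1], [2, 3, 4])


class TestKaplanMeier:
    def test_no_censoring_matches_empirical_survival(self):
        times = list(range(1, 11))
        curve = km_curve(times, [True] * 10)
        for t in times:
            assert curve.survival_at(t) == pytest.approx(1 - t / 10, abs=1e-12)
        assert curve.median == 5  # smallest event time with S <= 0.5

    def test_all_censored_flat_curve(self):
        curve = km_curve([3, 5, 8], [False, False, False])
        assert np.all(curve.survival == 1.0)
        assert curve.median is None

    def test_censoring_reduces_risk_set_without_step(self):
        # event at 3 among 3 subjects, others censored later: S(3) = 2/3
        curve = km_curve([3, 6, 9], [True, False, False])
        assert curve.survival_at(3) == pytest.approx(2 / 3)
        assert curve.survival_at(7) == pytest.approx(2 / 3)

    def test_monotone_nonincreasing_and_bounded(self):
        rng = np.random.default_rng(5)
        curve = km_curve(rng.exponential(10, 50), rng.random(50) < 0.7)
        s = curve.survival
        assert s[0] <= 1.0 and (np.diff(s) <= 1e-12).all()
        assert ((0 <= s) & (s <= 1)).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            km_curve([], [])


def logrank_oracle(ta, ea, tb, eb):
    """Hand O-E log-rank: chi-squared = (O_A - E_A)^2 / Var."""
    events = sorted({t for t, e in zip(ta, ea) if e} | {t for t, e in zip(tb, eb) if e})
    o_minus_e, var = 0.0, 0.0
    for t in events:
        n1 = sum(1 for x in ta if x >= t)
        n2 = sum(1 for x in tb if x >= t)
        d1 = sum(1 for x, e in zip(ta, ea) if e and x == t)
        d2 = sum(1 for x, e in zip(tb, eb) if e and x == t)
        n, d = n1 + n2, d1 + d2
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogRank:
    def test_identical_groups_uninformative(self):
        stat, p = logrank_test(([1, 2, 3], [1, 1, 1]), ([1, 2, 3], [1, 1, 1]))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_no_events_warns(self):
        with pytest.warns(UserWarning):
            stat, p = logrank_test(([1, 2], [0, 0]), ([3, 4], [0, 0]))
        assert (stat, p) == (0.0, 1.0)

    def test_tiny_worked_dataset_matches_hand_o_minus_e(self):
        ta, ea = [1.0, 2.0], [True, True]
        tb, eb = [3.0, 4.0], [True, True]
        stat, _ = logrank_test((ta, ea), (tb, eb))
        assert stat == pytest.approx(logrank_oracle(ta, ea, tb, eb), rel=1e-9)

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(11)
        a = (rng.exponential(10, 30), rng.random(30) < 0.8)
        b = (rng.exponential(20, 25), rng.random(25) < 0.8)
        assert logrank_test(a, b) == pytest.approx(logrank_test(b, a))

    def test_planted_hazard_ratio_detected(self):
        rng = np.random.default_rng(2)
        ta = rng.exponential(10.0, 100)
        tb = rng.exponential(30.0, 100)
        _, p = logrank_test((ta, [True] * 100), (tb, [True] * 100))
        assert p < 1e-6


class TestAssociationBattery:
    def test_long_format_and_pvalue_bounds(self, tma_cohort):
        samples, _ = tma_cohort
        df = association_battery(samples)
        assert set(df.columns) == {"antigen", "grouping", "covariate", "test", "statistic", "p"}
        assert set(df["grouping"]) == {"intensity-dichotomy", "q-bin"}
        assert ((df["p"] > 0) & (df["p"] <= 1)).all()
        assert (df[df["covariate"] == "pfs"]["test"] == "logrank").all()

    def test_bonferroni_option(self, tma_cohort):
        samples, _ = tma_cohort
        df = association_battery(samples, bonferroni=True)
        assert (df["p_bonferroni"] >= df["p"] - 1e-12).all()
        assert (df["p_bonferroni"] <= 1.0).all()

    def test_fisher_policy_forced(self, tma_cohort):
        samples, _ = tma_cohort
        df = association_battery(samples, test_policy="chi2")
        assert "fisher_exact" not in set(df["test"])
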