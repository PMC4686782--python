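"""Contracts of the statistical comparisons, checked against enumeration."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from exonproj.stats_tests import (
    bonferroni,
    chi2_binned,
    chi2_contingency,
    mann_whitney_u,
    wilcoxon_signed_rank,
)


def enum_mann_whitney_p(a, b):
    """Exact two-sided p by enumerating all rank assignments."""

    def u_stat(x, y):
        return sum((u > v) + 0.5 * (u == v) for u in x for v in y)

    pooled = list(a) + list(b)
    n1, n = len(a), len(a) + len(b)
    mu = n1 * (n - n1) / 2
    obs = u_stat(a, b)
    count = total = 0
    for idx in itertools.combinations(range(n), n1):
        s = set(idx)
        aa = [pooled[i] for i in idx]
        bb = [pooled[i] for i in range(n) if i not in s]
        total += 1
        if abs(u_stat(aa, bb) - mu) >= abs(obs - mu) - 1e-12:
            count += 1
    return count / total


def enum_wilcoxon_p(a, b):
    """Exact two-sided p by enumerating all 2^n sign assignments."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    n = d.size
    mu = n * (n + 1) / 4
    obs = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product([1, -1], repeat=n):
        tplus = sum(r for r, s in zip(ranks, signs) if s > 0)
        if abs(tplus - mu) >= abs(obs - mu) - 1e-12:
            count += 1
    return count / 2**n


class TestChi2Contingency:
    def test_independent_table_gives_zero(self):
        res = chi2_contingency([[10, 10], [10, 10]])
        assert res.statistic_value == 0.0
        assert res.p_value == 1.0

    def test_closed_form_2x2(self):
        # n(ad-bc)^2 / (r1 r2 c1 c2) = 60*(400-100)^2/30^4 = 6.667
        res = chi2_contingency([[20, 10], [10, 20]])
        assert res.statistic_value == pytest.approx(6.667, abs=5e-4)
        assert res.df == 1

    def test_invariant_under_row_and_column_swaps(self):
        base = chi2_contingency([[12, 7, 3], [5, 9, 14]])
        swapped = chi2_contingency([[5, 9, 14], [12, 7, 3]])
        cols = chi2_contingency([[3, 7, 12], [14, 9, 5]])
        assert swapped.statistic_value == pytest.approx(base.statistic_value)
        assert cols.statistic_value == pytest.approx(base.statistic_value)

    def test_zero_marginal_raises(self):
        with pytest.raises(ValueError):
            chi2_contingency([[0, 0], [5, 3]])
        with pytest.raises(ValueError):
            chi2_contingency([[0, 5], [0, 3]])


class TestChi2Binned:
    def test_identical_samples_give_zero(self):
        a = [10, 13, 13, 16, 19, 19, 22, 25] * 5
        res = chi2_binned(a, list(a))
        assert res.statistic_value == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_distributions_are_separated(self):
        rng = np.random.default_rng(1)
        a = rng.integers(10, 40, size=200)
        b = rng.integers(200, 230, size=200)
        res = chi2_binned(a, b)
        assert res.p_value < 1e-10

    def test_matches_hand_computed_merged_histogram(self):
        # bin width 10, min_expected 2: bins [0,10) and [10,20) survive
        a = [1, 2, 3, 4, 11, 12]
        b = [2, 3, 13, 14, 15, 16]
        res = chi2_binned(a, b, bin_width=10, min_expected=2)
        table = np.array([[4, 2], [2, 4]], dtype=float)
        expected = sps.chi2_contingency(table, correction=False)
        assert res.statistic_value == pytest.approx(expected.statistic)
        assert res.df == 1

    def test_expected_counts_reach_threshold_after_merging(self):
        rng = np.random.default_rng(2)
        a = np.rint(rng.lognormal(np.log(120), 0.6, size=300))
        b = np.rint(rng.lognormal(np.log(110), 0.6, size=300))
        res = chi2_binned(a, b, bin_width=3, min_expected=5)
        assert res.df == res.extra["n_bins"] - 1
        assert res.extra["n_bins"] >= 2

    def test_no_spread_raises(self):
        with pytest.raises(ValueError, match="insufficient spread"):
            chi2_binned([5, 5, 5], [5, 5, 5], bin_width=3)


class TestMannWhitney:
    def test_identical_samples_give_half_product(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney_u(a, list(a))
        assert res.statistic_value == pytest.approx(len(a) ** 2 / 2)

    def test_first_sample_all_smaller_gives_zero_u(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic_value == 0.0

    @pytest.mark.parametrize("a, b", [
        ([1.2, 3.4, 2.2], [0.5, 2.9, 3.1, 4.0]),
        ([5.0, 7.1, 6.3, 8.8], [4.2, 6.9, 5.5]),
        ([0.1, 0.9, 2.5, 3.3, 1.7], [0.4, 2.1, 2.9, 3.8, 4.4]),
    ])
    def test_p_matches_exhaustive_enumeration(self, a, b):
        res = mann_whitney_u(a, b)
        assert res.p_value == pytest.approx(enum_mann_whitney_p(a, b), abs=1e-12)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestWilcoxon:
    def test_all_zero_differences_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_constant_positive_shift_is_extreme(self):
        a = np.arange(1.0, 11.0)
        res = wilcoxon_signed_rank(a + 2.0, a)
        # every difference positive: the negative-rank sum is zero
        assert min(res.statistic_value,
                   res.n1 * (res.n1 + 1) / 2 - res.statistic_value) == 0.0
        assert res.extra["z"] != 0.0

    @pytest.mark.parametrize("a, b", [
        ([10.1, 12.3, 9.8, 14.2, 11.0, 13.5, 10.9, 12.8],
         [9.5, 11.8, 10.2, 12.9, 10.1, 12.2, 11.4, 11.9]),
        ([1.0, 2.5, 3.1, 0.2, 4.4, 2.2], [0.7, 2.9, 2.0, 0.9, 3.1, 1.0]),
    ])
    def test_p_matches_sign_enumeration(self, a, b):
        res = wilcoxon_signed_rank(a, b)
        assert res.p_value == pytest.approx(enum_wilcoxon_p(a, b), abs=1e-12)

    def test_zero_differences_are_dropped(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [1.0, 2.0, 2.5, 4.5, 4.0]
        res = wilcoxon_signed_rank(a, b)
        assert res.extra["n_zero_dropped"] == 2
        assert res.n1 == 3


class TestBonferroni:
    def test_scales_by_family_size(self):
        assert bonferroni([0.01], m=3) == [pytest.approx(0.03)]

    def test_caps_at_one(self):
        assert bonferroni([0.5], m=10) == [1.0]

    def test_default_family_is_input_length(self):
        assert bonferroni([0.01, 0.02]) == [pytest.approx(0.02), pytest.approx(0.04)]

    def test_monotone(self):
        p = [0.001, 0.2, 0.7, 1.0]
        adj = bonferroni(p)
        assert all(x >= y for x, y in zip(adj, p))

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            bonferroni([1.5])


def test_type_i_error_is_nominal_under_null():
    """Each test's rejection rate at alpha=0.05 stays near 5% when both
    samples come from the same distribution."""
    rng = np.random.default_rng(99)
    alpha, n_sim = 0.05, 400
    rej_mw = rej_wx = 0
    for _ in range(n_sim):
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        if mann_whitney_u(a, b).p_value < alpha:
            rej_mw += 1
        if wilcoxon_signed_rank(a, b).p_value < alpha:
            rej_wx += 1
    for rej in (rej_mw, rej_wx):
        # 99% binomial band around 0.05 for 400 simulations
        assert 0.02 <= rej / n_sim <= 0.08
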