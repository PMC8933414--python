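"""Unit and property tests for the statistical primitives."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from rescuepop.stats import (
    chisq_sf,
    empirical_pvalue,
    fishers_method,
    mww_test,
    percentile_bootstrap,
    poisson_two_sided,
)


def mww_enumeration_oracle(x, y, alternative="two-sided"):
    """Brute-force MWW p by enumerating group assignments, counting U as
    (#x>y pairs) + (#ties)/2 directly."""
    pooled = np.concatenate([x, y])
    n_x = len(x)

    def u_stat(xs, ys):
        xs, ys = np.asarray(xs), np.asarray(ys)
        return ((xs[:, None] > ys[None, :]).sum()
                + 0.5 * (xs[:, None] == ys[None, :]).sum())

    u_obs = u_stat(x, y)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n_x):
        rest = [i for i in range(len(pooled)) if i not in comb]
        us.append(u_stat(pooled[list(comb)], pooled[rest]))
    us = np.array(us)
    p_ge = np.mean(us >= u_obs - 1e-9)
    p_le = np.mean(us <= u_obs + 1e-9)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


class TestMww:
    def test_identical_samples_give_p_one(self):
        assert mww_test([1, 2], [1, 2]).p_value == 1.0

    def test_frozen_small_sample_examples(self):
        res = mww_test([1, 2], [3, 4])
        assert res.W == 0 and res.p_value == pytest.approx(2 / 6)
        res = mww_test([1, 2, 3], [4, 5, 6])
        assert res.W == 0 and res.p_value == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_matches_enumeration_all_small_partitions(self, seed):
        """Exact p equals full enumeration for every split with n_x+n_y <= 8,
        including tied data."""
        rng = np.random.default_rng(seed)
        total = int(rng.integers(2, 9))
        n_x = int(rng.integers(1, total))
        vals = rng.integers(0, 4, size=total).astype(float)  # forces ties
        x, y = vals[:n_x], vals[n_x:]
        for alt in ("two-sided", "less", "greater"):
            res = mww_test(x, y, alternative=alt)
            assert res.method == "exact-enumeration"
            assert res.p_value == pytest.approx(
                mww_enumeration_oracle(x, y, alt), abs=1e-12)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(0)
        res = mww_test(rng.normal(0, 1, 15), rng.normal(0.5, 1, 15))
        assert res.method == "normal-approximation"
        assert 0 < res.p_value <= 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mww_test([], [1.0])


class TestChisqSf:
    @pytest.mark.parametrize("df", [2, 4, 6, 8])
    def test_matches_chi_square_distribution(self, df):
        """Closed-form even-df series agrees with the chi-square survival
        function (independent scipy implementation) to 1e-10."""
        for x in [0.0, 0.5, 1.0, 3.7, 11.983, 30.0, 67.187]:
            assert chisq_sf(x, df) == pytest.approx(sps.chi2.sf(x, df),
                                                    abs=1e-10, rel=1e-9)

    def test_zero_statistic_gives_one(self):
        assert chisq_sf(0.0, 6) == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            chisq_sf(-1.0, 2)
        with pytest.raises(ValueError):
            chisq_sf(1.0, 3)


class TestFishersMethod:
    def test_all_ones(self):
        res = fishers_method([1, 1, 1])
        assert res.S == 0 and res.p_value == 1.0 and res.df == 6

    def test_two_equal_pvalues(self):
        # oracle: S = -2*2*ln(.05) = 11.9829...; p = e^{-S/2}(1+S/2)
        res = fishers_method([0.05, 0.05])
        s = -4 * math.log(0.05)
        assert res.S == pytest.approx(s)
        assert res.p_value == pytest.approx(math.exp(-s / 2) * (1 + s / 2))

    def test_transgression_scale_statistic(self):
        """S = 67.187 over three crosses yields p = 1.54e-12."""
        res = fishers_method(np.exp(-np.array([20.0, 20.0, 27.187]) / 2))
        assert res.S == pytest.approx(67.187)
        assert res.df == 6
        assert res.p_value == pytest.approx(1.54e-12, rel=5e-3)

    def test_out_of_range_pvalues_rejected(self):
        for bad in ([0.0], [1.5], []):
            with pytest.raises(ValueError):
                fishers_method(bad)


class TestEmpiricalP:
    def test_formula_cases(self):
        assert empirical_pvalue(100, 100).p_value == 1.0
        assert empirical_pvalue(0, 2000).p_value == pytest.approx(1 / 2001)
        assert empirical_pvalue(4, 99).p_value == pytest.approx(0.05)

    @given(st.integers(1, 500), st.data())
    @settings(max_examples=50, deadline=None)
    def test_never_zero_and_monotone(self, n, data):
        r = data.draw(st.integers(0, n))
        p = empirical_pvalue(r, n).p_value
        assert 1 / (n + 1) <= p <= 1
        if r < n:
            assert empirical_pvalue(r + 1, n).p_value > p

    def test_r_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalue(5, 4)


def poisson_two_sided_oracle(k, lam):
    """Direct summation over all outcomes at most as probable as k."""
    hi = int(max(lam, k) + 60 * math.sqrt(lam) + 60)
    ks = np.arange(0, hi + 1)
    pmf = sps.poisson.pmf(ks, lam)
    return float(pmf[pmf <= pmf[k] * (1 + 1e-7)].sum())


class TestPoissonTwoSided:
    def test_modal_outcome_gives_one(self):
        assert poisson_two_sided(3, 3.0) == 1.0
        assert poisson_two_sided(7, 7.0) == 1.0

    @pytest.mark.parametrize("k,lam", [
        (5, 1.0), (0, 10.0), (2, 8.5), (20, 4.0), (100, 80.0), (1, 0.3),
        (7, 0.0843), (0, 0.5),
    ])
    def test_matches_direct_summation(self, k, lam):
        assert poisson_two_sided(k, lam) == pytest.approx(
            poisson_two_sided_oracle(k, lam), abs=1e-12)

    @pytest.mark.parametrize("k,lam", [(9, 3.0), (1, 6.0), (15, 5.5)])
    def test_at_least_one_sided_tail(self, k, lam):
        p = poisson_two_sided(k, lam)
        one_sided = (sps.poisson.sf(k - 1, lam) if k > lam
                     else sps.poisson.cdf(k, lam))
        assert p >= one_sided - 1e-12

    def test_invalid_lambda(self):
        with pytest.raises(ValueError):
            poisson_two_sided(1, 0.0)


class TestPercentileBootstrap:
    def test_constant_vector_collapses(self):
        res = percentile_bootstrap([2.0] * 10, np.mean, reps=100, seed=1)
        assert res.lower == res.upper == 2.0

    def test_same_seed_is_deterministic(self):
        a = percentile_bootstrap([1, 2, 3, 4.0], np.mean, reps=200, seed=42)
        b = percentile_bootstrap([1, 2, 3, 4.0], np.mean, reps=200, seed=42)
        assert np.array_equal(a.replicates, b.replicates)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_mean_ci_brackets_truth(self):
        rng = np.random.default_rng(5)
        vals = rng.integers(0, 2, size=400).astype(float)
        res = percentile_bootstrap(vals, np.mean, reps=2000, seed=9)
        assert res.lower < 0.5 < res.upper

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            percentile_bootstrap([], np.mean, reps=10, seed=0)
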