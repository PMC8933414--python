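"""F2 segregation, transgression and the bulked-segregant scan."""

import numpy as np
import pytest
from scipy import stats as sps

from rescuepop.crosses import (
    CrossPhenotypes,
    SplitFailureError,
    bsa_scan,
    segregation_ratio_test,
    transgression_test,
)


class TestSegregation:
    def test_exact_one_to_three_ratio_gives_p_one(self):
        f2 = np.concatenate([np.full(122, 30.0), np.full(366, 60.0)])
        early, late, p = segregation_ratio_test(f2, split=45.0)
        assert (early, late) == (122, 366)
        assert p == pytest.approx(1.0)

    def test_one_to_one_ratio_strongly_rejected(self):
        f2 = np.concatenate([np.full(244, 30.0), np.full(244, 60.0)])
        _, _, p = segregation_ratio_test(f2, split=45.0)
        # continuity-corrected chi-square 1-df oracle
        stat = (abs(244 - 122) - 0.5) ** 2 / 122 + (abs(244 - 366) - 0.5) ** 2 / 366
        assert p == pytest.approx(sps.chi2.sf(stat, 1))
        assert p < 1e-30

    def test_mixture_split_finds_the_valley(self):
        rng = np.random.default_rng(0)
        f2 = np.concatenate([rng.normal(30, 2, 120), rng.normal(60, 2, 368)])
        early, late, p = segregation_ratio_test(f2, split="mixture")
        assert early == 120 and late == 368

    def test_unimodal_distribution_fails_split(self):
        rng = np.random.default_rng(1)
        with pytest.raises(SplitFailureError):
            segregation_ratio_test(rng.normal(45, 1, 100), split="mixture")

    def test_simulated_recessive_locus_rarely_rejected(self):
        """A true single-locus recessive 1:3 segregation is not rejected in
        the vast majority of replicates."""
        rng = np.random.default_rng(2)
        rejections = 0
        for _ in range(200):
            n_early = rng.binomial(488, 0.25)
            f2 = np.concatenate([np.full(n_early, 30.0),
                                 np.full(488 - n_early, 60.0)])
            _, _, p = segregation_ratio_test(f2, split=45.0)
            rejections += p < 0.05
        assert rejections / 200 <= 0.06

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError):
            segregation_ratio_test(np.arange(10.0), split=5.0)


class TestTransgression:
    def test_f2_identical_to_parents_not_significant(self):
        rng = np.random.default_rng(3)
        cross = CrossPhenotypes("c1", rng.normal(45, 3, 12),
                                rng.normal(45, 3, 12), rng.normal(45, 3, 200))
        pvals, comb = transgression_test([cross], seed=1, draws=5000)
        assert pvals[0] > 0.05
        assert comb.p_value > 0.05

    def test_planted_transgressive_tail_detected(self):
        rng = np.random.default_rng(4)
        crosses = []
        for i in range(3):
            f2 = np.concatenate([rng.normal(30, 2, 120),
                                 rng.normal(60, 2, 368)])
            crosses.append(CrossPhenotypes(
                f"c{i}", rng.normal(30, 2, 12), rng.normal(33, 2, 12), f2))
        pvals, comb = transgression_test(crosses, seed=2, draws=20000)
        assert comb.p_value < 1e-6

    def test_combined_statistic_recomputes_from_per_cross_pvalues(self):
        rng = np.random.default_rng(5)
        crosses = [CrossPhenotypes("c", rng.normal(40, 3, 12),
                                   rng.normal(50, 3, 12),
                                   rng.normal(45, 5, 100))
                   for _ in range(2)]
        pvals, comb = transgression_test(crosses, seed=3, draws=5000)
        assert comb.S == pytest.approx(-2 * np.sum(np.log(pvals)))

    def test_degenerate_two_group_case_matches_t_test(self):
        """Whole-F2 vs a single parent reduces to a two-sample t-test."""
        rng = np.random.default_rng(6)
        parent = rng.normal(45, 3, 12)
        f2 = rng.normal(47, 3, 60)
        cross = CrossPhenotypes("c", parent, np.array([]), f2)
        pvals, _ = transgression_test([cross], seed=4, tail=None, draws=200000)
        t_p = sps.ttest_ind(f2, parent, equal_var=True).pvalue
        assert pvals[0] == pytest.approx(t_p, abs=0.005)


class TestBsaScan:
    def test_bulk_fixed_everywhere_flags_every_window(self):
        pos = np.arange(1, 201) * 50
        res = bsa_scan(np.full(200, 50), np.full(200, 50), pos,
                       window=20, step=5)
        assert res.windows["flagged"].all()

    def test_flag_set_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        pos = np.arange(1, 301) * 40
        focal = rng.binomial(50, 0.9, 300)
        flags = []
        for thr in (0.80, 0.88, 0.95):
            res = bsa_scan(focal, np.full(300, 50), pos, window=20, step=5,
                           threshold=thr)
            flags.append(len(res.flagged))
        assert flags[0] >= flags[1] >= flags[2]

    def test_sparse_window_reported_na(self):
        pos = np.array([10, 20, 30])
        res = bsa_scan(np.array([5, 5, 5]), np.array([10, 10, 10]), pos,
                       window=10, step=5, min_informative=5)
        assert res.windows["median_freq"].isna().all()
        assert len(res.flagged) == 0

    def test_binomial_null_produces_no_flags(self):
        rng = np.random.default_rng(8)
        false_runs = 0
        for _ in range(60):
            pos = np.sort(rng.choice(200_000, 400, replace=False)) + 1
            focal = rng.binomial(50, 0.5, 400)
            res = bsa_scan(focal, np.full(400, 50), pos, window=20, step=5)
            false_runs += len(res.flagged) > 0
        assert false_runs == 0

    def test_recessive_bulk_expectations_noise_free(self):
        """Expected focal frequency is 1 at the causal site and 1/2 at
        unlinked sites in an early bulk of a recessive model."""
        from rescuepop.simulate import simulate_f2
        rng = np.random.default_rng(9)
        n_half = 300
        chroms = np.repeat(["1", "2"], n_half)
        pos = np.concatenate(
            [np.sort(rng.choice(250_000, n_half, replace=False)) + 1] * 2)
        pa = np.zeros(2 * n_half, dtype=np.int8)
        pb = np.ones(2 * n_half, dtype=np.int8)
        causal = 450
        _, dosage, bulk, truth = simulate_f2(
            pa, pb, pos, chroms, {"1": 0.5, "2": 0.5}, 800, causal,
            noise_sd=0.0, depth=4000, seed=10)
        freq = bulk["focal_count"] / bulk["total_count"]
        assert freq[causal] == pytest.approx(1.0, abs=0.01)
        unlinked = freq[chroms == "1"]  # causal sits on chromosome 2
        assert unlinked.mean() == pytest.approx(0.5, abs=0.05)
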