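"""Polarization, spectra, theta estimators and private/shared partitions."""

import numpy as np
import pandas as pd
import pytest

from rescuepop.io import MISSING, GenotypeMatrix, PopulationPanel
from rescuepop.spectra import (
    ALT_ANCESTRAL,
    REF_ANCESTRAL,
    UNASSIGNED,
    diversity_estimates,
    joint_sfs,
    polarize_sites,
    private_shared_summary,
    sfs_1d,
    watterson_a,
)


def build(calls, pops):
    calls = np.asarray(calls, dtype=np.int8)
    n_samp, n_sites = calls.shape
    sites = pd.DataFrame({"chrom": ["1"] * n_sites,
                          "pos": np.arange(1, n_sites + 1) * 10,
                          "ref": ["A"] * n_sites, "alt": ["T"] * n_sites})
    ids = [f"s{i}" for i in range(n_samp)]
    return (GenotypeMatrix(sample_ids=ids, sites=sites, calls=calls),
            PopulationPanel(dict(zip(ids, pops))))


class TestPolarization:
    def test_reference_population_rules(self):
        # sites: morocco ref-only / alt-only / both / all-missing
        calls = np.array([
            [0, 1, 0, MISSING],   # Morocco
            [0, 1, 1, MISSING],   # Morocco
            [1, 0, 1, 1],         # island
            [1, 0, 0, 1],         # island
        ])
        m, panel = build(calls, ["Morocco", "Morocco", "SA", "SA"])
        a = polarize_sites(m, panel, "reference-population", "Morocco")
        assert a.state.tolist() == [REF_ANCESTRAL, ALT_ANCESTRAL,
                                    UNASSIGNED, UNASSIGNED]
        assert a.n_unassigned == 2

    def test_outgroup_rules(self):
        calls = np.array([
            [0, 1, 0, MISSING],   # outgroup hap 1
            [0, 1, 1, 0],         # outgroup hap 2
            [1, 0, 1, 1],
        ])
        m, panel = build(calls, ["Out", "Out", "SA"])
        a = polarize_sites(m, panel, "outgroup", "Out")
        # polymorphic outgroup and missing-outgroup sites -> unassigned
        assert a.state.tolist() == [REF_ANCESTRAL, ALT_ANCESTRAL,
                                    UNASSIGNED, UNASSIGNED]

    def test_allele_relabeling_flips_assignment(self):
        calls = np.array([[0, 1], [0, 1], [1, 0]])
        m, panel = build(calls, ["Morocco", "Morocco", "SA"])
        a = polarize_sites(m, panel, "reference-population", "Morocco")
        m2, panel2 = build(1 - calls, ["Morocco", "Morocco", "SA"])
        b = polarize_sites(m2, panel2, "reference-population", "Morocco")
        flip = {REF_ANCESTRAL: ALT_ANCESTRAL, ALT_ANCESTRAL: REF_ANCESTRAL,
                UNASSIGNED: UNASSIGNED}
        assert [flip[s] for s in a.state] == b.state.tolist()

    def test_unknown_population_rejected(self):
        m, panel = build(np.zeros((2, 1)), ["A", "A"])
        with pytest.raises(ValueError):
            polarize_sites(m, panel, "reference-population", "nope")


class TestSfs:
    def test_monomorphic_matrix_gives_empty_spectrum(self):
        calls = np.zeros((5, 4), dtype=np.int8)
        m, panel = build(calls, ["P"] * 5)
        spec = sfs_1d(m, panel, "P")
        assert spec.counts.sum() == 0

    def test_singleton_site_counted_once(self):
        calls = np.zeros((4, 1), dtype=np.int8)
        calls[0, 0] = 1
        m, panel = build(calls, ["P"] * 4)
        spec = sfs_1d(m, panel, "P")  # folded
        assert spec.counts.tolist() == [1, 0]

    def test_neutral_spectrum_follows_one_over_i(self, small_scenario):
        """The mainland sample's folded spectrum tracks the 1/i + 1/(n-i)
        neutral expectation."""
        _, matrix, panel, _ = small_scenario
        spec = sfs_1d(matrix, panel, "Morocco")
        n = spec.n[0]
        i = np.arange(1, len(spec.counts) + 1)
        expect = 1.0 / i + 1.0 / (n - i)
        expect[i == n - i] /= 2
        expect = expect / expect.sum() * spec.counts.sum()
        # chi-square-ish distance on a handful of aggregated classes
        obs_head, exp_head = spec.counts[:5], expect[:5]
        assert np.all(np.abs(obs_head - exp_head) < 5 * np.sqrt(exp_head) + 5)

    def test_subsample_larger_than_pop_rejected(self):
        calls = np.zeros((3, 2), dtype=np.int8)
        m, panel = build(calls, ["P"] * 3)
        with pytest.raises(ValueError):
            sfs_1d(m, panel, "P", subsample_n=5, seed=0)


class TestJointSfs:
    def test_disjoint_private_variants_sit_on_axes(self):
        calls = np.array([
            [0, 0, 1, 0],
            [0, 0, 1, 0],
            [1, 0, 0, 0],
            [0, 1, 0, 0],
        ])
        m, panel = build(calls, ["Mor", "Mor", "A", "B"])
        # add second member to each island pop
        calls2 = np.vstack([calls, [[1, 0, 0, 0], [0, 1, 0, 0]]])
        m, panel = build(calls2, ["Mor", "Mor", "A", "B", "A", "B"])
        a = polarize_sites(m, panel, "reference-population", "Mor")
        spec = joint_sfs(m, panel, "A", "B", a, subsample_n=None)
        nz = np.argwhere(spec.counts > 0)
        assert all((i == 0) or (j == 0) for i, j in nz)

    def test_marginals_match_direct_recount(self, small_scenario):
        _, matrix, panel, _ = small_scenario
        a = polarize_sites(matrix, panel, "reference-population", "Morocco")
        spec = joint_sfs(matrix, panel, "SantoAntao", "Fogo", a,
                         subsample_n=40, seed=5)
        n_a, n_b = spec.n
        assert spec.counts.shape == (n_a + 1, n_b + 1)
        assert spec.counts.sum() + spec.corner_low + spec.corner_high >= spec.counts.sum()
        # row/col marginals are one-dimensional spectra over the same sites
        row = spec.counts.sum(axis=1)
        col = spec.counts.sum(axis=0)
        assert row.sum() == col.sum() == spec.counts.sum()

    def test_identical_populations_sit_on_diagonal(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 2, size=(3, 6)).astype(np.int8)
        calls = np.vstack([np.zeros((2, 6), np.int8), base, base])
        pops = ["Mor"] * 2 + ["A"] * 3 + ["B"] * 3
        m, panel = build(calls, pops)
        a = polarize_sites(m, panel, "reference-population", "Mor")
        spec = joint_sfs(m, panel, "A", "B", a, subsample_n=None)
        nz = np.argwhere(spec.counts > 0)
        assert all(i == j for i, j in nz)


class TestDiversity:
    def test_two_haplotypes_hand_case(self):
        calls = np.zeros((2, 10), dtype=np.int8)
        calls[0, [2, 7]] = 1
        m, panel = build(calls, ["P", "P"])
        est = diversity_estimates(m, panel, "P", L=10)
        assert est.theta_pi == pytest.approx(0.2)
        assert est.theta_w == pytest.approx(0.2)   # a_1 = 1

    def test_watterson_formula(self):
        calls = np.zeros((2, 5), dtype=np.int8)
        calls[0, :] = 1
        m, panel = build(calls, ["P", "P"])
        est = diversity_estimates(m, panel, "P", L=1000)
        assert est.S == 5
        assert est.theta_w == pytest.approx(0.005)

    def test_theta_consistency_on_neutral_sample(self, small_scenario):
        """theta_W ~ theta_pi on the neutral mainland sample."""
        cfg, matrix, panel, _ = small_scenario
        est = diversity_estimates(matrix, panel, "Morocco", L=cfg.genome_length)
        assert est.theta_w == pytest.approx(cfg.mainland_theta, rel=0.15)
        assert est.theta_pi == pytest.approx(est.theta_w, rel=0.15)

    def test_zero_length_rejected(self):
        calls = np.zeros((2, 1), dtype=np.int8)
        m, panel = build(calls, ["P", "P"])
        with pytest.raises(ValueError):
            diversity_estimates(m, panel, "P", L=0)


class TestPrivateShared:
    def test_hand_built_two_population_tally(self):
        calls = np.array([
            #        site: 0  1  2  3  4  5
            [1, 0, 1, 0, 1, 0],   # A
            [1, 0, 0, 0, 1, 0],   # A
            [0, 0, 1, 1, 1, 0],   # B
            [0, 1, 0, 1, 1, 0],   # B
        ])
        m, panel = build(calls, ["A", "A", "B", "B"])
        df = private_shared_summary(m, panel, ["A", "B"]).set_index("population")
        # A carries alt at sites 0,2,4: 0 private fixed, 2 shared, 1 private seg
        assert df.loc["A", "n_variants"] == 3
        assert df.loc["A", "private_fixed"] == pytest.approx(1 / 3)   # site 0
        assert df.loc["A", "private_segregating"] == 0
        assert df.loc["A", "shared"] == pytest.approx(2 / 3)          # 2, 4
        # B carries alt at sites 1,2,3,4: site 3 private fixed, site 1
        # private segregating, sites 2 and 4 shared with A
        assert df.loc["B", "n_variants"] == 4
        assert df.loc["B", "private_fixed"] == pytest.approx(1 / 4)
        assert df.loc["B", "private_segregating"] == pytest.approx(1 / 4)
        assert df.loc["B", "shared"] == pytest.approx(1 / 2)

    def test_scenario_island_private_fraction_matches_truth(self, small_scenario):
        """Variants segregating in an island are overwhelmingly private to
        it, and the fraction equals the generator's de novo share."""
        _, matrix, panel, truth = small_scenario
        df = private_shared_summary(
            matrix, panel, ["SantoAntao", "Fogo", "Morocco"]
        ).set_index("population")
        for isl in ("SantoAntao", "Fogo"):
            frac = df.loc[isl, "private_of_segregating"]
            assert frac == pytest.approx(truth.island_private_fraction[isl])
            assert frac > 0.9


def test_watterson_normalizer():
    assert watterson_a(2) == 1.0
    assert watterson_a(5) == pytest.approx(1 + 1 / 2 + 1 / 3 + 1 / 4)
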