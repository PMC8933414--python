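"""The synthetic colonization generator: determinism, truth consistency,
degenerate limits and the F2/bulk machinery."""

import numpy as np
import pytest

from rescuepop.io import read_genotypes
from rescuepop.simulate import (
    PlantedVariant,
    ScenarioConfig,
    simulate_colonization,
    simulate_f2,
    simulate_phenotypes,
    write_fixture,
)


def tiny_config(**kw):
    base = dict(
        seed=5,
        chrom_lengths={"1": 40_000, "2": 40_000},
        mainland_samples=24,
        mainland_theta=2e-3,
        founders=(12, 12),
        island_samples=(16, 16),
        bottleneck_generations=150,
        growth_generations=150,
        total_generations=600,
        final_size=600,
        planted=[PlantedVariant(island="Fogo", chrom="2", pos=20_000,
                                s=0.09273, arise_generation=200,
                                target="fixed")],
    )
    base.update(kw)
    return ScenarioConfig(**base)


class TestColonization:
    def test_same_seed_reproduces_byte_identical_output(self):
        m1, _, t1 = simulate_colonization(tiny_config())
        m2, _, t2 = simulate_colonization(tiny_config())
        assert np.array_equal(m1.calls, m2.calls)
        assert m1.sites.equals(m2.sites)
        assert t1.origin == t2.origin

    def test_zero_generations_with_all_founders_copies_mainland(self):
        cfg = tiny_config(founders=(24, 24), island_samples=(24, 24),
                          total_generations=0, bottleneck_generations=0,
                          growth_generations=0, planted=[])
        m, panel, truth = simulate_colonization(cfg)
        main = m.calls[panel.indices(m, "Morocco"), :]
        for isl in ("SantoAntao", "Fogo"):
            isl_calls = m.calls[panel.indices(m, isl), :]
            assert sorted(map(tuple, isl_calls)) == sorted(map(tuple, main))

    def test_default_scenario_is_dominated_by_de_novo_variation(
            self, default_scenario):
        """Under the default study conditions, >95% of variants segregating
        on each island arose after colonization."""
        _, _, _, truth = default_scenario
        for isl, frac in truth.island_private_fraction.items():
            assert frac > 0.95

    def test_planted_variants_respect_targets(self, default_scenario):
        _, matrix, panel, truth = default_scenario
        for j, meta in truth.planted_sites.items():
            idx = panel.indices(matrix, meta["island"])
            calls = matrix.calls[idx, int(j)]
            freq = (calls == 1).mean()
            if meta["target"] == "fixed":
                assert freq == 1.0
            else:
                assert 0.0 < freq < 1.0

    def test_more_founders_share_more_variation(self):
        """Island/mainland sharing increases with founder count."""
        shared = []
        for founders in (4, 20):
            sh = []
            for seed in (1, 2, 3):
                cfg = tiny_config(seed=seed, founders=(founders, founders),
                                  planted=[])
                m, panel, truth = simulate_colonization(cfg)
                origin = np.array(truth.origin)
                present_isl = (m.calls[panel.indices(m, "SantoAntao"), :] == 1
                               ).any(axis=0)
                sh.append((present_isl & (origin == "mainland")).sum())
            shared.append(np.mean(sh))
        assert shared[0] < shared[1]

    def test_emitted_files_reread_consistently(self, tmp_path):
        cfg = tiny_config()
        paths = write_fixture(tmp_path / "fx", cfg)
        matrix, _, truth = simulate_colonization(cfg)
        back = read_genotypes(paths["vcf"])
        assert np.array_equal(back.calls, matrix.calls)
        import json
        truth_json = json.load(open(paths["truth"]))
        assert truth_json["origin"] == list(truth.origin)


class TestPhenotypes:
    def test_zero_noise_effect_is_exact(self, default_scenario):
        cfg, matrix, panel, truth = default_scenario
        import dataclasses
        quiet = dataclasses.replace(cfg, flowering_sd=0.0, censor_day=1000.0)
        ph = simulate_phenotypes(matrix, panel, truth, quiet, seed=1)
        j, meta = next((j, m) for j, m in truth.planted_sites.items()
                       if m["island"] == "SantoAntao")
        carrier = matrix.calls[:, int(j)] == 1
        other = [int(k) for k in truth.planted_sites if int(k) != int(j)]
        clean = ~np.any(matrix.calls[:, other] == 1, axis=1)
        fl = ph["flowering_days"].to_numpy()
        delta = (fl[carrier & clean].mean() - fl[~carrier & clean
                                                 & (np.array(ph.population) == "SantoAntao")].mean())
        assert delta == pytest.approx(meta["effect_days"], abs=1e-9)

    def test_flowering_fitness_association_is_strongly_negative(
            self, default_scenario):
        from scipy.stats import spearmanr
        cfg, matrix, panel, truth = default_scenario
        ph = simulate_phenotypes(matrix, panel, truth, cfg)
        isl = ph[ph["population"] != "Morocco"]
        rho = spearmanr(isl["flowering_days"], isl["seeds"]).statistic
        assert rho < -0.6


class TestF2:
    @staticmethod
    def make_parents(seed=0, n_half=400):
        rng = np.random.default_rng(seed)
        chroms = np.repeat(["1", "2"], n_half)
        pos = np.concatenate(
            [np.sort(rng.choice(250_000, n_half, replace=False)) + 1] * 2)
        pa = np.zeros(2 * n_half, dtype=np.int8)
        pb = np.ones(2 * n_half, dtype=np.int8)
        return pa, pb, pos, chroms

    def test_recessive_early_fraction_near_one_quarter(self):
        pa, pb, pos, chroms = self.make_parents()
        _, _, _, truth = simulate_f2(pa, pb, pos, chroms,
                                     {"1": 0.5, "2": 0.5}, 2000, 600,
                                     noise_sd=0.0, seed=1)
        assert truth["early_fraction"] == pytest.approx(0.25, abs=0.03)

    def test_identical_parents_at_causal_rejected(self):
        pa, pb, pos, chroms = self.make_parents()
        pb2 = pb.copy()
        pb2[600] = pa[600]
        with pytest.raises(ValueError):
            simulate_f2(pa, pb2, pos, chroms, {"1": 0.5, "2": 0.5}, 100, 600,
                        seed=2)

    def test_bulk_scan_recovers_planted_locus(self):
        from rescuepop.crosses import bsa_scan
        pa, pb, pos, chroms = self.make_parents(seed=3, n_half=500)
        _, _, bulk, truth = simulate_f2(pa, pb, pos, chroms,
                                        {"1": 0.5, "2": 0.5}, 488, 750,
                                        seed=3)
        res = bsa_scan(bulk["focal_count"], bulk["total_count"], bulk["pos"],
                       bulk["chrom"], window=20, step=5)
        hit = ((res.flagged["chrom"] == truth["causal_chrom"])
               & (res.flagged["start"] <= truth["causal_pos"])
               & (res.flagged["end"] > truth["causal_pos"])).any()
        assert hit
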