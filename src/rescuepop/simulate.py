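"""Synthetic colonization scenarios with known truth.

Emulates the statistical structure the analyses assume: a diverse
mainland population, two island populations founded by a few dozen
individuals that lose nearly all standing variation through the
bottleneck, island-private de novo mutations (including planted
large-effect loss-of-function alleles under positive selection),
flowering-time/fitness phenotypes with a strong negative association,
and inter-island F2 crosses segregating 1:3 for a recessive early
allele, with a sequenced early-flowering bulk.

Highly selfing lines are modelled as haploid lineages throughout (the
same coding the analysis modules use); crosses are the one place where
diploid genetics (F1 heterozygosity, recombination, recessivity) enters.
All randomness flows from a single root seed through numpy SeedSequence
spawning, so every artifact is reproducible from the config alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .crosses import CrossPhenotypes
from .io import GenotypeMatrix, PopulationPanel, write_genotypes

__all__ = [
    "PlantedVariant",
    "ScenarioConfig",
    "TruthRecord",
    "simulate_colonization",
    "simulate_phenotypes",
    "simulate_f2",
    "write_fixture",
]

NUCS = np.array(list("ACGT"))


@dataclass
class PlantedVariant:
    """A planted island mutation with a phenotype effect.

    ``target`` conditions the forward stage on the realized history the
    scenario describes: "fixed" retries until the allele fixes on its
    island, "segregating" until it ends at intermediate frequency.
    """

    island: str
    chrom: str
    pos: int
    effect_days: float = -30.0
    s: float = 0.09273
    arise_generation: int = 350
    kind: str = "functional-LOF"
    target: str = "fixed"  # "fixed" | "segregating"


@dataclass
class ScenarioConfig:
    """Study conditions of the synthetic colonization scenario.

    Defaults: founder counts 40 (Santo Antao) and 48 (Fogo), per-site
    mutation rate 7.1e-9, mainland diversity theta_W = 5.56e-3 per site,
    selfing 95% (represented by haploid-lineage dynamics).  The island
    forward stage runs 1700 generations on a 500 kb two-chromosome
    genome: a 400-generation bottleneck at founder size, exponential
    growth to 2000 over the next 400 generations, then constant size.
    """

    seed: int = 0
    chrom_lengths: dict = field(default_factory=lambda: {"1": 250_000, "2": 250_000})
    mainland_samples: int = 64
    mainland_theta: float = 5.56e-3
    founders: tuple = (40, 48)
    island_samples: tuple = (60, 60)
    bottleneck_generations: int = 400
    growth_generations: int = 400
    total_generations: int = 1700
    final_size: int = 2000
    mutation_rate: float = 7.1e-9
    selfing_rate: float = 0.95
    planted: list = field(default_factory=lambda: [
        PlantedVariant(island="SantoAntao", chrom="1", pos=100_000,
                       effect_days=-34.0, s=0.0456, arise_generation=1550,
                       target="segregating"),
        PlantedVariant(island="Fogo", chrom="2", pos=120_000,
                       effect_days=-27.0, s=0.09273, arise_generation=350,
                       target="fixed"),
    ])
    # phenotype model
    flowering_baseline: float = 62.0
    flowering_sd: float = 3.0
    censor_day: float = 65.0
    fitness_max: float = 400.0   # mean seed count at 30 days to flowering
    fitness_decay: float = 0.08  # per day of delay
    fitness_dispersion: float = 2.0
    mainland_label: str = "Morocco"
    island_labels: tuple = ("SantoAntao", "Fogo")

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def trajectory(self, founder_count: int) -> np.ndarray:
        """Per-generation island population size N(t)."""
        if self.total_generations < self.bottleneck_generations + self.growth_generations:
            raise ValueError("total_generations too short for the schedule")
        t = np.arange(self.total_generations + 1)
        n = np.empty_like(t, dtype=float)
        n[: self.bottleneck_generations] = founder_count
        g = self.growth_generations
        ramp = np.clip((t - self.bottleneck_generations) / max(g, 1), 0, 1)
        n = np.where(
            t < self.bottleneck_generations,
            founder_count,
            founder_count * (self.final_size / founder_count) ** ramp,
        )
        return np.maximum(np.round(n).astype(int), 2)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "planted" in raw:
            raw["planted"] = [PlantedVariant(**p) for p in raw["planted"]]
        if "founders" in raw:
            raw["founders"] = tuple(raw["founders"])
        if "island_samples" in raw:
            raw["island_samples"] = tuple(raw["island_samples"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["planted"] = [asdict(p) for p in self.planted]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class TruthRecord:
    """Ground truth emitted alongside the genotype data."""

    origin: list          # per site: "mainland" | "de_novo_<island>" | "planted_<island>"
    true_freq: dict       # population label -> per-site end-point frequency list
    planted_sites: dict   # site index -> PlantedVariant metadata
    island_private_fraction: dict  # island -> de novo share of segregating variants

    def to_json(self, path) -> None:
        payload = {
            "origin": list(self.origin),
            "true_freq": {k: list(map(float, v)) for k, v in self.true_freq.items()},
            "planted_sites": {str(k): v for k, v in self.planted_sites.items()},
            "island_private_fraction": self.island_private_fraction,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _neutral_sample_counts(rng, n: int, theta: float, length: int) -> np.ndarray:
    """Allele counts (1..n-1) of segregating sites in a neutral sample.

    S ~ Poisson(theta * L * a_{n-1}); counts follow the neutral 1/i law.
    """
    a_n = np.sum(1.0 / np.arange(1, n))
    s = rng.poisson(theta * length * a_n)
    weights = 1.0 / np.arange(1, n)
    weights /= weights.sum()
    return rng.choice(np.arange(1, n), size=s, p=weights)


def _drift_island(rng, founder_counts: np.ndarray, traj: np.ndarray,
                  mu: float, length: int):
    """Forward neutral drift of founder variants plus de novo influx.

    Returns (founder variant end counts, de novo end counts) at the final
    generation; absorbed de novo variants are dropped along the way,
    founder variants keep their site alignment (0 or N = absorbed).
    """
    fc = founder_counts.astype(np.int64)
    dn = np.zeros(0, dtype=np.int64)
    n_fixed_dn = 0
    n_prev = traj[0]
    for t in range(1, traj.size):
        n_now = traj[t]
        seg = (fc > 0) & (fc < n_prev)
        if seg.any():
            fc = np.where(seg, rng.binomial(n_now, np.clip(fc, 0, n_prev) / n_prev),
                          np.where(fc > 0, n_now, 0))
        else:
            fc = np.where(fc > 0, n_now, 0)
        if dn.size:
            dn = rng.binomial(n_now, dn / n_prev)
            n_fixed_dn += int((dn == n_now).sum())
            dn = dn[(dn > 0) & (dn < n_now)]
        n_new = rng.poisson(n_now * mu * length)
        if n_new:
            dn = np.concatenate([dn, np.ones(n_new, dtype=np.int64)])
        n_prev = n_now
    if n_fixed_dn:
        dn = np.concatenate([dn, np.full(n_fixed_dn, traj[-1], dtype=np.int64)])
    return fc, dn


def _plant_variant(rng, traj: np.ndarray, pv: PlantedVariant,
                   max_retries: int = 500) -> int:
    """Forward trajectory of a planted selected allele, conditioned on
    reaching its target state (the scenario describes a realized history)."""
    for _ in range(max_retries):
        c = 1
        n_prev = traj[min(pv.arise_generation, traj.size - 1)]
        for t in range(pv.arise_generation + 1, traj.size):
            n_now = traj[t]
            p = c / n_prev
            p_sel = p * (1 + pv.s) / (1 + p * pv.s)
            c = rng.binomial(n_now, p_sel)
            n_prev = n_now
            if c == 0:
                break
            if c == n_now and pv.target == "fixed":
                # fixed: remains fixed for the rest of the run
                return int(traj[-1])
        if pv.target == "fixed" and c == n_prev:
            return int(traj[-1])
        if pv.target == "segregating" and 0 < c < n_prev:
            freq = c / n_prev
            if 0.2 <= freq <= 0.95:
                return int(c)
    raise RuntimeError(f"planted variant failed to reach target "
                       f"{pv.target!r} in {max_retries} retries")


def simulate_colonization(config: ScenarioConfig):
    """Generate mainland + two-island genotype data with known truth.

    Returns (GenotypeMatrix, PopulationPanel, TruthRecord).
    """
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(6)
    rng_main, rng_sa, rng_fo, rng_plant, rng_pos, rng_assign = (
        np.random.default_rng(s) for s in streams)

    n_main = config.mainland_samples
    L = config.genome_length
    main_counts = _neutral_sample_counts(rng_main, n_main, config.mainland_theta, L)
    s_main = main_counts.size

    # mainland haplotype matrix: exact per-site carrier counts
    main_calls = np.zeros((n_main, s_main), dtype=np.int8)
    for j, c in enumerate(main_counts):
        main_calls[rng_main.choice(n_main, size=c, replace=False), j] = 1

    islands = {}
    for label, founders, n_samp, rng in zip(
            config.island_labels, config.founders, config.island_samples,
            (rng_sa, rng_fo)):
        if founders > n_main:
            raise ValueError("founder count exceeds mainland sample size")
        traj = config.trajectory(founders)
        founder_rows = rng.choice(n_main, size=founders, replace=False)
        founder_counts = main_calls[founder_rows, :].sum(axis=0)
        if config.total_generations == 0:
            islands[label] = {
                "calls": main_calls[founder_rows, :][:n_samp, :],
                "fc": founder_counts, "dn": np.zeros(0, dtype=np.int64),
                "n_final": founders, "zero_gen": True,
            }
            continue
        fc, dn = _drift_island(rng, founder_counts, traj,
                               config.mutation_rate, L)
        islands[label] = {"fc": fc, "dn": dn, "n_final": int(traj[-1]),
                          "zero_gen": False}

    # planted variants
    planted_end = []
    for pv in config.planted:
        traj = config.trajectory(
            config.founders[list(config.island_labels).index(pv.island)])
        if config.total_generations == 0:
            raise ValueError("planted variants need a forward stage")
        planted_end.append(_plant_variant(rng_plant, traj, pv))

    # assemble the site list: mainland sites, per-island de novo, planted
    blocks = [("mainland", s_main)]
    for label in config.island_labels:
        blocks.append((f"de_novo_{label}", islands[label]["dn"].size))
    origin = []
    for name, size in blocks:
        origin.extend([name] * size)
    for pv in config.planted:
        origin.append(f"planted_{pv.island}")
    n_sites = len(origin)

    # sample island individuals (hypergeometric at end-point counts)
    all_samples = (
        [f"MOR_{i:03d}" for i in range(n_main)]
        + [f"SA_{i:03d}" for i in range(config.island_samples[0])]
        + [f"FO_{i:03d}" for i in range(config.island_samples[1])]
    )
    panel = PopulationPanel(
        {s: (config.mainland_label if s.startswith("MOR")
             else config.island_labels[0] if s.startswith("SA")
             else config.island_labels[1]) for s in all_samples})
    calls = np.zeros((len(all_samples), n_sites), dtype=np.int8)
    calls[:n_main, :s_main] = main_calls

    true_freq = {config.mainland_label: np.zeros(n_sites),
                 config.island_labels[0]: np.zeros(n_sites),
                 config.island_labels[1]: np.zeros(n_sites)}
    true_freq[config.mainland_label][:s_main] = main_counts / n_main

    row0 = n_main
    col0 = s_main
    dn_offsets = {}
    for label, n_samp in zip(config.island_labels, config.island_samples):
        isl = islands[label]
        n_final = isl["n_final"]
        dn_offsets[label] = col0
        if isl["zero_gen"]:
            calls[row0:row0 + n_samp, :s_main] = isl["calls"]
            true_freq[label][:s_main] = isl["fc"] / max(isl["n_final"], 1)
        else:
            rng = rng_assign
            # founder-derived sites share mainland columns
            end_counts = np.concatenate([isl["fc"], isl["dn"]])
            cols = np.concatenate([np.arange(s_main),
                                   np.arange(col0, col0 + isl["dn"].size)])
            freqs = end_counts / n_final
            true_freq[label][cols] = freqs
            samp = rng.hypergeometric(
                np.maximum(end_counts, 0),
                np.maximum(n_final - end_counts, 0),
                n_samp)
            for j, c in zip(cols[samp > 0], samp[samp > 0]):
                rows = rng.choice(n_samp, size=c, replace=False) + row0
                calls[rows, j] = 1
        col0 += isl["dn"].size
        row0 += n_samp

    # planted columns
    planted_sites = {}
    for pv, end_count in zip(config.planted, planted_end):
        j = col0
        label = pv.island
        i_isl = list(config.island_labels).index(label)
        n_final = islands[label]["n_final"]
        n_samp = config.island_samples[i_isl]
        r0 = n_main + sum(config.island_samples[:i_isl])
        freq = end_count / n_final
        true_freq[label][j] = freq
        c = rng_assign.hypergeometric(end_count, n_final - end_count, n_samp)
        if pv.target == "segregating":
            c = min(max(c, 1), n_samp - 1)  # keep the planted allele observable
        rows = rng_assign.choice(n_samp, size=c, replace=False) + r0
        calls[rows, j] = 1
        planted_sites[j] = {"island": label, "chrom": pv.chrom, "pos": pv.pos,
                            "effect_days": pv.effect_days, "s": pv.s,
                            "kind": pv.kind, "target": pv.target,
                            "true_freq": float(freq)}
        col0 += 1

    # positions: distinct, uniform over the genome; planted keep theirs
    chrom_names = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chrom_names])
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    reserved = {(pv.chrom, pv.pos) for pv in config.planted}
    n_free = n_sites - len(planted_sites)
    flat = rng_pos.choice(L, size=min(n_free * 2 + 100, L), replace=False)
    coords = []
    for f in flat:
        ci = int(np.searchsorted(bounds, f, side="right") - 1)
        coord = (chrom_names[ci], int(f - bounds[ci]) + 1)
        if coord not in reserved:
            coords.append(coord)
        if len(coords) == n_free:
            break
    it = iter(coords)
    site_coords = []
    for j in range(n_sites):
        if j in planted_sites:
            site_coords.append((planted_sites[j]["chrom"], planted_sites[j]["pos"]))
        else:
            site_coords.append(next(it))

    refs = rng_pos.choice(NUCS, size=n_sites)
    shift = rng_pos.integers(1, 4, size=n_sites)
    alts = NUCS[(np.searchsorted(NUCS, refs) + shift) % 4]

    sites = pd.DataFrame({
        "chrom": [c for c, _ in site_coords],
        "pos": [p for _, p in site_coords],
        "ref": refs, "alt": alts,
    })
    order = np.lexsort((sites["pos"].to_numpy(),
                        sites["chrom"].to_numpy().astype(str)))
    sites = sites.iloc[order].reset_index(drop=True)
    calls = calls[:, order]
    origin = [origin[i] for i in order]
    for k in true_freq:
        true_freq[k] = true_freq[k][order]
    planted_sites = {int(np.flatnonzero(order == j)[0]): v
                     for j, v in planted_sites.items()}

    matrix = GenotypeMatrix(sample_ids=all_samples, sites=sites, calls=calls)

    island_private = {}
    for label in config.island_labels:
        idx = panel.indices(matrix, label)
        sub = calls[idx, :]
        seg = (sub == 1).any(axis=0) & (sub == 0).any(axis=0)
        if seg.sum():
            de_novo = np.array([o != "mainland" for o in origin])
            island_private[label] = float((seg & de_novo).sum() / seg.sum())
        else:
            island_private[label] = float("nan")

    truth = TruthRecord(origin=origin, true_freq=true_freq,
                        planted_sites=planted_sites,
                        island_private_fraction=island_private)
    return matrix, panel, truth


def simulate_phenotypes(matrix: GenotypeMatrix, panel: PopulationPanel,
                        truth: TruthRecord, config: ScenarioConfig,
                        seed: int | None = None) -> pd.DataFrame:
    """Flowering-time and seed-count phenotypes from the planted effects.

    Flowering = baseline + sum of carried planted effects + Gaussian noise,
    right-censored at the scoring horizon; fitness (seed count) is
    negative-binomial with log-mean decreasing in flowering time, which
    induces the strong negative flowering-fitness association the
    scenario emulates.
    """
    rng = np.random.default_rng(config.seed + 104729 if seed is None else seed)
    n = matrix.n_samples
    flowering = np.full(n, config.flowering_baseline)
    for j, meta in truth.planted_sites.items():
        carriers = matrix.calls[:, int(j)] == 1
        flowering = flowering + carriers * meta["effect_days"]
    if config.flowering_sd > 0:
        flowering = flowering + rng.normal(0, config.flowering_sd, size=n)
    flowering = np.minimum(flowering, config.censor_day)
    flowering = np.maximum(flowering, 1.0)

    mean_seeds = config.fitness_max * np.exp(
        -config.fitness_decay * (flowering - 30.0))
    k = config.fitness_dispersion
    seeds = rng.negative_binomial(k, k / (k + mean_seeds))
    return pd.DataFrame({
        "sample_id": matrix.sample_ids,
        "population": [panel.mapping[s] for s in matrix.sample_ids],
        "flowering_days": flowering,
        "seeds": seeds,
    })


def simulate_f2(parent_a: np.ndarray, parent_b: np.ndarray, positions, chroms,
                chrom_morgans: dict, n_f2: int, causal_index: int,
                effect_days: float = -27.0, parent_a_mean: float = 38.0,
                parent_b_mean: float = 30.0, late_mean: float = 60.0,
                noise_sd: float = 2.0, n_parent_reps: int = 12,
                bulk_tail: float = 0.25, depth: int = 50, seed: int = 0):
    """An inter-island F2 with one recessive early-flowering locus and a bulk.

    The F1 (parent_a x parent_b) is selfed; each F2 receives two
    recombinant gametes (Haldane map, crossovers Poisson along each
    chromosome).  F2 individuals homozygous for the parent-B allele at
    the causal locus flower early (parent_b_mean); all others are late
    (late_mean), beyond both parents - the transgressive 3/4.  The bulk
    is the early ``bulk_tail`` fraction; per-site focal-parent (B) allele
    counts are binomial at the given read depth.

    Returns (CrossPhenotypes, f2_genotypes as B-allele dosage 0/1/2,
    bulk DataFrame, truth dict).
    """
    parent_a = np.asarray(parent_a, dtype=np.int8)
    parent_b = np.asarray(parent_b, dtype=np.int8)
    positions = np.asarray(positions)
    chroms = np.asarray(chroms)
    if parent_a[causal_index] == parent_b[causal_index]:
        raise ValueError("parents must differ at the causal locus")
    rng = np.random.default_rng(seed)
    n_sites = positions.size

    # gamete inheritance: per chromosome, a Markov walk between parents
    gametes = np.empty((2 * n_f2, n_sites), dtype=np.int8)  # 1 = from parent B
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        pos_c = positions[sel].astype(float)
        morgans = chrom_morgans[str(chrom)]
        span = max(pos_c.max() - pos_c.min(), 1.0)
        d = np.diff(pos_c) / span * morgans
        r = 0.5 * (1.0 - np.exp(-2.0 * d))  # Haldane map function
        state = rng.integers(0, 2, size=(2 * n_f2, 1)).astype(np.int8)
        flips = (rng.random((2 * n_f2, r.size)) < r[None, :]).astype(np.int8)
        walk = np.concatenate([state, flips], axis=1)
        gametes[:, sel] = np.cumsum(walk, axis=1) % 2

    # B-strand dosage = focal-parent allele dosage at parent-informative sites
    dosage = gametes[0::2, :] + gametes[1::2, :]

    early = dosage[:, causal_index] == 2
    pheno = np.where(early, parent_b_mean, late_mean) + rng.normal(
        0, noise_sd, size=n_f2)

    cross = CrossPhenotypes(
        cross_id="SAxFO",
        parent_a=np.maximum(parent_a_mean + rng.normal(0, noise_sd, n_parent_reps), 0),
        parent_b=np.maximum(parent_b_mean + rng.normal(0, noise_sd, n_parent_reps), 0),
        f2=np.maximum(pheno, 0),
    )

    # bulk the early tail, but never past the phenotypic gap into the late
    # mode (the protocol pools plants that actually flowered early)
    split = 0.5 * (parent_b_mean + late_mean)
    n_bulk = max(1, min(int(round(bulk_tail * n_f2)), int((pheno < split).sum())))
    bulk_rows = np.argsort(pheno)[:n_bulk]
    bulk_freq = dosage[bulk_rows, :].sum(axis=0) / (2.0 * n_bulk)
    focal = rng.binomial(depth, bulk_freq)
    bulk = pd.DataFrame({
        "chrom": chroms, "pos": positions,
        "focal_count": focal,
        "total_count": np.full(n_sites, depth),
    })
    truth = {"causal_index": int(causal_index),
             "causal_chrom": str(chroms[causal_index]),
             "causal_pos": int(positions[causal_index]),
             "bulk_rows": bulk_rows, "early_fraction": float(early.mean())}
    return cross, dosage, bulk, truth


def write_fixture(outdir, config: ScenarioConfig) -> dict:
    """Emit a full scenario bundle: VCF, panel TSV, phenotypes TSV,
    category BED, truth JSON and a YAML echo of the config."""
    import os

    os.makedirs(outdir, exist_ok=True)
    matrix, panel, truth = simulate_colonization(config)
    pheno = simulate_phenotypes(matrix, panel, truth, config)
    paths = {
        "vcf": os.path.join(outdir, "genotypes.vcf"),
        "panel": os.path.join(outdir, "panel.tsv"),
        "phenotypes": os.path.join(outdir, "phenotypes.tsv"),
        "categories": os.path.join(outdir, "categories.bed"),
        "truth": os.path.join(outdir, "truth.json"),
        "config": os.path.join(outdir, "scenario.yaml"),
    }
    write_genotypes(matrix, paths["vcf"])
    panel.to_tsv(paths["panel"])
    pheno.to_csv(paths["phenotypes"], sep="\t", index=False)
    with open(paths["categories"], "w") as fh:
        for j, meta in truth.planted_sites.items():
            fh.write(f"{meta['chrom']}\t{meta['pos'] - 1}\t{meta['pos']}\t"
                     f"functional-variant\n")
    truth.to_json(paths["truth"])
    config.to_yaml(paths["config"])
    return paths
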