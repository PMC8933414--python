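"""Shared fixtures: a scaled-down colonization scenario, a toy annotated
genome, and a small F2 cross.  Everything is generated at test time."""

import itertools

import numpy as np
import pytest

from rescuepop.simulate import PlantedVariant, ScenarioConfig, simulate_colonization


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced colonization scenario shared across tests (fast)."""
    cfg = ScenarioConfig(
        seed=11,
        chrom_lengths={"1": 80_000, "2": 80_000},
        mainland_samples=44,
        mainland_theta=3e-3,
        founders=(20, 24),
        island_samples=(44, 44),
        bottleneck_generations=250,
        growth_generations=250,
        total_generations=1000,
        final_size=1200,
        planted=[
            # segregating LOF on island 1, fixed LOF on island 2
            PlantedVariant(island="SantoAntao", chrom="1", pos=40_000,
                           effect_days=-34.0, s=0.0456, arise_generation=850,
                           target="segregating"),
            PlantedVariant(island="Fogo", chrom="2", pos=60_000,
                           effect_days=-27.0, s=0.09273, arise_generation=300,
                           target="fixed"),
        ],
    )
    matrix, panel, truth = simulate_colonization(cfg)
    return cfg, matrix, panel, truth


@pytest.fixture(scope="session")
def default_scenario():
    """The full default scenario (the study conditions)."""
    cfg = ScenarioConfig(seed=3)
    matrix, panel, truth = simulate_colonization(cfg)
    return cfg, matrix, panel, truth


@pytest.fixture(scope="session")
def toy_gene(tmp_path_factory):
    """A 2 kb reference with one clean 300 bp CDS, plus its GFF3.

    Returns (fasta path, gff path, cds sequence, cds 1-based interval).
    """
    outdir = tmp_path_factory.mktemp("toygene")
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), 2000))
    stops = {"TAA", "TAG", "TGA"}
    codons = [c for c in map("".join, itertools.product("ACGT", repeat=3))
              if c not in stops]
    cds = "ATG" + "".join(rng.choice(codons, 98)) + "TAA"
    seq = seq[:100] + cds + seq[400:]
    fasta = outdir / "ref.fa"
    fasta.write_text(">1\n" + seq + "\n")
    gff = outdir / "genes.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "1\ttest\tgene\t101\t400\t.\t+\t.\tID=g1\n"
        "1\ttest\tmRNA\t101\t400\t.\t+\t.\tID=m1;Parent=g1\n"
        "1\ttest\tCDS\t101\t400\t.\t+\t0\tID=c1;Parent=m1\n"
    )
    return fasta, gff, cds, (101, 400)
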