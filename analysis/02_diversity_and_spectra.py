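#!/usr/bin/env python
"""Diversity, spectra and private/shared structure of the scenario.

Reads the fixture emitted by 01_simulate_scenario.py, polarizes island
variation against the mainland, and writes theta estimates, 1-D spectra,
the inter-island joint SFS and the private/shared partition.  The
colonization bottleneck should leave island diversity orders of
magnitude below the mainland and nearly all island segregating variants
private to their island.
"""

import json
import os

import numpy as np

from rescuepop.io import read_genotypes, read_panel
from rescuepop.simulate import ScenarioConfig
from rescuepop.spectra import (
    diversity_estimates,
    joint_sfs,
    polarize_sites,
    private_shared_summary,
    sfs_1d,
)

POPS = ["SantoAntao", "Fogo", "Morocco"]


def main() -> None:
    cfg = ScenarioConfig.from_yaml("scratch/scenario/scenario.yaml")
    matrix = read_genotypes("scratch/scenario/genotypes.vcf")
    panel = read_panel("scratch/scenario/panel.tsv")
    os.makedirs("results", exist_ok=True)

    theta = {}
    for pop in POPS:
        est = diversity_estimates(matrix, panel, pop, L=cfg.genome_length)
        theta[pop] = {"theta_w": est.theta_w, "theta_pi": est.theta_pi,
                      "S": est.S, "n": est.n}
    folds = {isl: theta["Morocco"]["theta_w"] / theta[isl]["theta_w"]
             for isl in ("SantoAntao", "Fogo")}

    assign = polarize_sites(matrix, panel, "reference-population", "Morocco")
    spectra = {}
    for isl in ("SantoAntao", "Fogo"):
        spec = sfs_1d(matrix, panel, isl, assign, subsample_n=40, seed=cfg.seed)
        spectra[isl] = spec.counts.tolist()
    jsfs = joint_sfs(matrix, panel, "SantoAntao", "Fogo", assign,
                     subsample_n=40, seed=cfg.seed)
    np.savetxt("results/02_jsfs_islands.tsv", jsfs.counts, fmt="%d",
               delimiter="\t")

    summary = private_shared_summary(matrix, panel, POPS)
    summary.to_csv("results/02_private_shared.tsv", sep="\t", index=False)

    with open("results/02_diversity.json", "w") as fh:
        json.dump({"theta": theta, "fold_reduction": folds,
                   "unassigned_sites": assign.n_unassigned,
                   "island_sfs": spectra}, fh, indent=1)

    print("theta_W per site:",
          {p: f"{v['theta_w']:.3g}" for p, v in theta.items()})
    print("island diversity fold reduction vs mainland:",
          {k: round(v, 1) for k, v in folds.items()})
    priv = summary.set_index("population")["private_of_segregating"]
    print("private share of island segregating variants:",
          {isl: round(float(priv[isl]), 4) for isl in ("SantoAntao", "Fogo")})
    print("joint SFS off-diagonal mass:",
          int(jsfs.counts.sum() - np.trace(jsfs.counts)))


if __name__ == "__main__":
    main()
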