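"""Polarization, site frequency spectra and diversity estimators.

Ancestral states are assigned either from variation in a reference
population (an allele seen anywhere there is ancestral; both alleles
present means no assignment) or from a non-polymorphic outgroup.  Spectra
are complete-case per site over the (optionally subsampled) individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, PopulationPanel

__all__ = [
    "AncestralAssignment",
    "SpectrumResult",
    "DiversityEstimate",
    "polarize_sites",
    "derived_counts",
    "sfs_1d",
    "joint_sfs",
    "diversity_estimates",
    "private_shared_summary",
    "watterson_a",
]

REF_ANCESTRAL = 0
ALT_ANCESTRAL = 1
UNASSIGNED = -1


@dataclass
class AncestralAssignment:
    """Per-site ancestral state: ref-ancestral, alt-ancestral or unassigned."""

    state: np.ndarray  # int8: REF_ANCESTRAL / ALT_ANCESTRAL / UNASSIGNED
    mode: str
    n_unassigned: int

    def assigned(self) -> np.ndarray:
        return self.state != UNASSIGNED


@dataclass
class SpectrumResult:
    """1-D SFS or 2-D joint SFS of derived-allele counts.

    For the 1-D case ``counts[i]`` (i = 1..n-1) is the number of sites
    with i derived copies among the n sampled individuals; fixed-derived
    sites (i = n) are reported separately, as is the (0,0)/(nA,nB) corner
    mass of the joint spectrum.  ``n_sites_used`` counts successfully
    polarized, complete-case segregating sites contributing to counts.
    """

    kind: str  # "sfs-1d" | "jsfs-2d" | "folded"
    counts: np.ndarray
    n: tuple[int, ...]
    polarization: str
    subsample: int | None = None
    fixed_derived: int = 0
    corner_low: int = 0
    corner_high: int = 0

    @property
    def n_sites_used(self) -> int:
        return int(self.counts.sum())


@dataclass
class DiversityEstimate:
    """Watterson's and pairwise-difference estimators of theta per site."""

    theta_w: float
    theta_pi: float
    S: int
    n: int
    L: int


def watterson_a(n: int) -> float:
    """a_{n-1} = sum_{i=1}^{n-1} 1/i, the Watterson normalizer."""
    return float(np.sum(1.0 / np.arange(1, n)))


def polarize_sites(matrix: GenotypeMatrix, panel: PopulationPanel, mode: str,
                   label: str) -> AncestralAssignment:
    """Assign per-site ancestral states.

    reference-population mode: an allele observed anywhere in the
    reference population is ancestral; if both alleles are present there
    (or no calls survive) the site is unassigned.  outgroup mode: the
    outgroup allele is ancestral, but sites polymorphic or missing in the
    outgroup are unassigned.
    """
    if mode not in ("reference-population", "outgroup"):
        raise ValueError(f"unknown polarization mode: {mode!r}")
    idx = panel.indices(matrix, label)
    calls = matrix.calls[idx, :]
    has_ref = (calls == 0).any(axis=0)
    has_alt = (calls == 1).any(axis=0)
    n_missing = (calls == MISSING).all(axis=0)

    state = np.full(matrix.n_sites, UNASSIGNED, dtype=np.int8)
    if mode == "reference-population":
        state[has_ref & ~has_alt] = REF_ANCESTRAL
        state[has_alt & ~has_ref] = ALT_ANCESTRAL
        # both alleles present, or no observed calls -> unassigned
    else:
        complete = ~(calls == MISSING).any(axis=0) if idx.size else np.zeros(
            matrix.n_sites, dtype=bool)
        state[complete & has_ref & ~has_alt] = REF_ANCESTRAL
        state[complete & has_alt & ~has_ref] = ALT_ANCESTRAL
    del n_missing
    return AncestralAssignment(state=state, mode=mode,
                               n_unassigned=int((state == UNASSIGNED).sum()))


def derived_counts(matrix: GenotypeMatrix, sample_idx: np.ndarray,
                   assignment: AncestralAssignment | None):
    """(derived count, non-missing count) per site for the given samples.

    Without an assignment the alt allele is counted (caller must fold).
    Sites with an unassigned ancestral state get derived count -1.
    """
    calls = matrix.calls[sample_idx, :]
    nonmiss = (calls != MISSING).sum(axis=0)
    alt = (calls == 1).sum(axis=0)
    if assignment is None:
        return alt, nonmiss
    der = np.where(assignment.state == ALT_ANCESTRAL, nonmiss - alt, alt)
    der = np.where(assignment.state == UNASSIGNED, -1, der)
    return der, nonmiss


def _subsample(idx: np.ndarray, k: int | None, seed: int | None) -> np.ndarray:
    if k is None:
        return idx
    if k > idx.size:
        raise ValueError("subsample_n exceeds population size")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(idx, size=k, replace=False))


def sfs_1d(matrix: GenotypeMatrix, panel: PopulationPanel, pop: str,
           assignment: AncestralAssignment | None = None,
           subsample_n: int | None = None, seed: int | None = None) -> SpectrumResult:
    """Derived-allele (or folded minor-allele) site frequency spectrum.

    Individuals may be subsampled without replacement (seeded).  Sites
    with any missing call among the used individuals are dropped
    (complete-case), as are sites without an ancestral assignment.
    """
    idx = panel.indices(matrix, pop)
    if idx.size < 2:
        raise ValueError("population needs at least two samples")
    idx = _subsample(idx, subsample_n, seed)
    n = idx.size
    calls = matrix.calls[idx, :]
    complete = ~(calls == MISSING).any(axis=0)
    alt = (calls == 1).sum(axis=0)

    if assignment is None:
        minor = np.minimum(alt, n - alt)
        counts = np.zeros(n // 2 + 1, dtype=int)
        use = complete & (minor > 0)
        np.add.at(counts, minor[use], 1)
        return SpectrumResult(kind="folded", counts=counts[1:], n=(n,),
                              polarization="none", subsample=subsample_n)

    der = np.where(assignment.state == ALT_ANCESTRAL, n - alt, alt)
    use = complete & assignment.assigned()
    counts = np.zeros(n + 1, dtype=int)
    np.add.at(counts, der[use], 1)
    return SpectrumResult(
        kind="sfs-1d", counts=counts[1:n], n=(n,),
        polarization=assignment.mode, subsample=subsample_n,
        fixed_derived=int(counts[n]),
    )


def joint_sfs(matrix: GenotypeMatrix, panel: PopulationPanel, pop_a: str, pop_b: str,
              assignment: AncestralAssignment, subsample_n: int | None = 40,
              seed: int | None = None) -> SpectrumResult:
    """Joint derived-allele spectrum over two populations.

    Returns the full (n_A+1) x (n_B+1) count matrix including the shared
    and fixed margins; the invariant (0,0) and fixed-everywhere
    (n_A, n_B) corners are zeroed in the matrix and reported separately.
    """
    rng = np.random.default_rng(seed)
    idx_a = panel.indices(matrix, pop_a)
    idx_b = panel.indices(matrix, pop_b)
    sub_seed = (None, None) if seed is None else tuple(rng.integers(0, 2**31, 2))
    idx_a = _subsample(idx_a, subsample_n, sub_seed[0])
    idx_b = _subsample(idx_b, subsample_n, sub_seed[1])
    n_a, n_b = idx_a.size, idx_b.size

    der_a, nm_a = derived_counts(matrix, idx_a, assignment)
    der_b, nm_b = derived_counts(matrix, idx_b, assignment)
    use = (nm_a == n_a) & (nm_b == n_b) & (der_a >= 0) & (der_b >= 0)

    counts = np.zeros((n_a + 1, n_b + 1), dtype=int)
    np.add.at(counts, (der_a[use], der_b[use]), 1)
    corner_low = int(counts[0, 0])
    corner_high = int(counts[n_a, n_b])
    counts[0, 0] = 0
    counts[n_a, n_b] = 0
    return SpectrumResult(kind="jsfs-2d", counts=counts, n=(n_a, n_b),
                          polarization=assignment.mode, subsample=subsample_n,
                          corner_low=corner_low, corner_high=corner_high)


def diversity_estimates(matrix: GenotypeMatrix, panel: PopulationPanel, pop: str,
                        L: int) -> DiversityEstimate:
    """theta_W and theta_pi per site over L monitored sites.

    theta_W = S / (a_{n-1} L) with n the population sample size; theta_pi
    sums per-site mean pairwise differences 2 d (m - d) / (m (m - 1))
    over non-missing calls (m per site), divided by L.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    idx = panel.indices(matrix, pop)
    if idx.size < 2:
        raise ValueError("population needs at least two samples")
    calls = matrix.calls[idx, :]
    m = (calls != MISSING).sum(axis=0)
    alt = (calls == 1).sum(axis=0)
    seg = (alt > 0) & (alt < m) & (m >= 2)
    S = int(seg.sum())
    if S > L:
        raise ValueError("L must be at least the segregating-site count")
    theta_w = S / (watterson_a(idx.size) * L)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_site = np.where(
            m >= 2, 2.0 * alt * (m - alt) / (m * (m - 1.0)), 0.0)
    theta_pi = float(per_site.sum() / L)
    return DiversityEstimate(theta_w=theta_w, theta_pi=theta_pi, S=S,
                             n=idx.size, L=L)


def private_shared_summary(matrix: GenotypeMatrix, panel: PopulationPanel,
                           pops: list[str],
                           site_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Private/shared partition of variants across populations.

    For each variant present (alt allele observed) in a population,
    classifies it as private-segregating, private-fixed or shared with at
    least one other population, and reports proportions per population.
    ``site_mask`` optionally restricts the tally to a site class (e.g.
    four-fold degenerate sites).
    """
    if len(pops) < 1:
        raise ValueError("need at least one population")
    use = np.ones(matrix.n_sites, dtype=bool) if site_mask is None else np.asarray(site_mask, bool)
    presence, fixed = {}, {}
    skipped = 0
    for pop in pops:
        idx = panel.indices(matrix, pop)
        calls = matrix.calls[idx, :]
        m = (calls != MISSING).sum(axis=0)
        alt = (calls == 1).sum(axis=0)
        skipped += int(((m == 0) & use).sum())
        presence[pop] = (alt > 0) & (m > 0)
        fixed[pop] = (alt == m) & (m > 0)
    rows = []
    for pop in pops:
        others = [q for q in pops if q != pop]
        in_other = np.zeros(matrix.n_sites, dtype=bool)
        for q in others:
            in_other |= presence[q]
        here = presence[pop] & use
        private = here & ~in_other
        seg = private & ~fixed[pop]
        fix = private & fixed[pop]
        shared = here & in_other
        seg_here = here & ~fixed[pop]
        total = int(here.sum())
        denom = max(total, 1)
        rows.append({
            "population": pop,
            "n_variants": total,
            "n_segregating": int(seg_here.sum()),
            "private_segregating": int(seg.sum()) / denom,
            "private_fixed": int(fix.sum()) / denom,
            "private_total": int(private.sum()) / denom,
            "shared": int(shared.sum()) / denom,
            # share of the population's *segregating* variants private to it
            "private_of_segregating": (int(seg.sum()) / max(int(seg_here.sum()), 1)),
        })
    df = pd.DataFrame(rows)
    df.attrs["skipped_all_missing"] = skipped
    if len(pops) == 1:
        warnings.warn("single population: everything is private by construction")
    return df
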