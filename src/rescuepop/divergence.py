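"""Branch-specific fixation classes and the d_sel/d_neu divergence ratio.

d_sel/d_neu contrasts substitution rates at 0-fold (putatively selected)
and 4-fold (putatively neutral) degenerate coding sites, each scaled by
the genome-wide number of sites at risk for that mutation class.  Unity
means no selection; >1 suggests positive selection on the branch, <1
purifying selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING, GenotypeMatrix, PopulationPanel, SiteAnnotation
from .spectra import AncestralAssignment

__all__ = ["BRANCH_LABELS", "DivergenceRatio", "classify_branches", "dsel_dneu"]

BRANCH_LABELS = (
    "fixed_derived_CVI_shared",
    "fixed_derived_SA_only",
    "fixed_derived_FO_only",
    "segregating_SA",
    "segregating_FO",
    "present_in_Morocco",
    "unassigned",
)


class UndefinedRatioError(ZeroDivisionError):
    """Raised when d_neu = 0 makes the divergence ratio undefined."""


@dataclass
class DivergenceRatio:
    d_sel: int
    d_neu: int
    L0: int
    L4: int
    ratio: float
    bootstrap: np.ndarray | None = None
    ci: tuple[float, float] | None = None
    n_bootstrap: int = 0


def _pop_state(matrix, panel, pop, assignment):
    """(derived count, non-missing count) per site for one population."""
    idx = panel.indices(matrix, pop)
    calls = matrix.calls[idx, :]
    m = (calls != MISSING).sum(axis=0)
    alt = (calls == 1).sum(axis=0)
    der = np.where(assignment.state == 1, m - alt, alt)
    return der, m


def classify_branches(matrix: GenotypeMatrix, panel: PopulationPanel,
                      assignment: AncestralAssignment,
                      sa: str = "SantoAntao", fo: str = "Fogo",
                      mainland: str = "Morocco") -> np.ndarray:
    """Assign each site one branch label (mutually exclusive, exhaustive).

    "Absent" means derived-allele count zero among observed calls,
    "fixed" means derived count equals the non-missing sample size.
    Sites without an ancestral assignment, with fewer than two observed
    calls in a required population, or in a configuration outside the
    label vocabulary (e.g. derived segregating in both islands) are
    labelled unassigned.
    """
    der_sa, m_sa = _pop_state(matrix, panel, sa, assignment)
    der_fo, m_fo = _pop_state(matrix, panel, fo, assignment)
    der_mo, m_mo = _pop_state(matrix, panel, mainland, assignment)

    labels = np.full(matrix.n_sites, "unassigned", dtype=object)
    ok = assignment.assigned() & (m_sa >= 2) & (m_fo >= 2) & (m_mo >= 2)

    in_mo = der_mo > 0
    fixed_sa = der_sa == m_sa
    fixed_fo = der_fo == m_fo
    absent_sa = der_sa == 0
    absent_fo = der_fo == 0
    seg_sa = (der_sa > 0) & ~fixed_sa
    seg_fo = (der_fo > 0) & ~fixed_fo

    labels[ok & in_mo] = "present_in_Morocco"
    rest = ok & ~in_mo
    labels[rest & fixed_sa & fixed_fo] = "fixed_derived_CVI_shared"
    labels[rest & fixed_sa & absent_fo] = "fixed_derived_SA_only"
    labels[rest & fixed_fo & absent_sa] = "fixed_derived_FO_only"
    labels[rest & seg_sa & absent_fo] = "segregating_SA"
    labels[rest & seg_fo & absent_sa] = "segregating_FO"
    return labels


_BRANCH_TO_LABEL = {
    "CVI": "fixed_derived_CVI_shared",
    "SA": "fixed_derived_SA_only",
    "FO": "fixed_derived_FO_only",
}


def dsel_dneu(labels: np.ndarray, annotations: SiteAnnotation, branch: str,
              L0: int | None = None, L4: int | None = None,
              bootstrap_reps: int = 500, seed: int | None = None,
              block_ids: np.ndarray | None = None) -> DivergenceRatio:
    """d_sel/d_neu on one branch, with a bootstrap CI over substitutions.

    Counts branch substitutions annotated 0-fold (d_sel) and 4-fold
    (d_neu), scales each by its sites at risk (L0, L4; defaulting to the
    annotation's genome-wide counts) and bootstraps by resampling the
    substitution list with replacement (or whole blocks when
    ``block_ids`` is given).  d_neu = 0 raises UndefinedRatioError.
    """
    label = _BRANCH_TO_LABEL.get(branch, branch)
    if label not in BRANCH_LABELS:
        raise ValueError(f"unknown branch/label: {branch!r}")
    L0 = annotations.L0 if L0 is None else L0
    L4 = annotations.L4 if L4 is None else L4
    if L0 <= 0 or L4 <= 0:
        raise ValueError("L0 and L4 must be positive")

    on_branch = np.flatnonzero(labels == label)
    deg = np.asarray(annotations.degeneracy, dtype=object)[on_branch]
    is_sel = deg == "zero-fold"
    is_neu = deg == "four-fold"
    d_sel, d_neu = int(is_sel.sum()), int(is_neu.sum())
    if d_neu == 0:
        raise UndefinedRatioError("no neutral (4-fold) substitutions on branch")
    ratio = (d_sel / L0) / (d_neu / L4)

    boot = None
    ci = None
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        n = on_branch.size
        cls = np.where(is_sel, 0, np.where(is_neu, 1, 2))
        reps = np.empty(bootstrap_reps)
        if block_ids is None:
            # multinomial resampling of the substitution list
            counts = np.bincount(cls, minlength=3)
            draws = rng.multinomial(n, counts / n, size=bootstrap_reps)
            with np.errstate(divide="ignore", invalid="ignore"):
                reps = (draws[:, 0] / L0) / np.where(draws[:, 1] > 0,
                                                     draws[:, 1] / L4, np.nan)
        else:
            blocks = np.asarray(block_ids)[on_branch]
            uniq = np.unique(blocks)
            for r in range(bootstrap_reps):
                chosen = rng.choice(uniq, size=uniq.size, replace=True)
                s = sum(int(((blocks == b) & is_sel).sum()) for b in chosen)
                u = sum(int(((blocks == b) & is_neu).sum()) for b in chosen)
                reps[r] = (s / L0) / (u / L4) if u > 0 else np.nan
        boot = reps
        valid = reps[~np.isnan(reps)]
        if valid.size:
            ci = tuple(np.percentile(valid, [2.5, 97.5]))
    return DivergenceRatio(d_sel=d_sel, d_neu=d_neu, L0=L0, L4=L4, ratio=ratio,
                           bootstrap=boot, ci=ci, n_bootstrap=bootstrap_reps)
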