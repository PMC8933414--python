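"""F2 segregation, transgression statistics and the bulked-segregant scan.

A single recessive large-effect early-flowering allele produces a 1:3
early:late ratio in an F2; transgressive segregation (F2 individuals
beyond both parental ranges) is assessed per cross with a Monte-Carlo
Dunnett-type many-to-one comparison and combined across crosses with
Fisher's method; the BSA scan slides windows over per-site focal-parent
allele frequencies in a phenotypic-extreme bulk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import CombinedTestResult, fishers_method

__all__ = [
    "CrossPhenotypes",
    "BsaScanResult",
    "SplitFailureError",
    "segregation_ratio_test",
    "transgression_test",
    "bsa_scan",
]


class SplitFailureError(ValueError):
    """Raised when no valley separates two modes in the F2 distribution."""


@dataclass
class CrossPhenotypes:
    """Flowering phenotypes (days) for the parents and F2 of one cross."""

    cross_id: str
    parent_a: np.ndarray
    parent_b: np.ndarray
    f2: np.ndarray

    def __post_init__(self):
        self.parent_a = np.asarray(self.parent_a, dtype=float)
        self.parent_b = np.asarray(self.parent_b, dtype=float)
        self.f2 = np.asarray(self.f2, dtype=float)
        if np.any(self.parent_a < 0) or np.any(self.parent_b < 0) or np.any(self.f2 < 0):
            raise ValueError("phenotype values must be non-negative")


@dataclass
class BsaScanResult:
    """Windowed bulk focal-parent allele frequencies with flagged windows."""

    windows: pd.DataFrame  # chrom, start, end, n_variants, median_freq, sd_freq, flagged
    threshold: float
    flagged: pd.DataFrame = field(init=False)

    def __post_init__(self):
        mask = np.array([v is True for v in self.windows["flagged"]], dtype=bool)
        self.flagged = self.windows[mask] if mask.size else self.windows.iloc[:0]


def _kde_valley(values: np.ndarray) -> float:
    """Valley (density minimum) between the two main modes of a 1-D sample."""
    kde = sps.gaussian_kde(values)
    grid = np.linspace(values.min(), values.max(), 512)
    dens = kde(grid)
    # local maxima
    peaks = np.flatnonzero((dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])) + 1
    if peaks.size < 2:
        raise SplitFailureError("F2 distribution is not bimodal")
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = np.sort(top2)
    valley = lo + int(np.argmin(dens[lo:hi + 1]))
    return float(grid[valley])


def segregation_ratio_test(f2_values, split="mixture"):
    """Early/late classification and chi-square goodness of fit against 1:3.

    ``split`` is either an explicit day threshold (early = strictly
    below) or "mixture", which places the threshold at the kernel-density
    valley between the two F2 modes.  The one-degree-of-freedom
    chi-square uses a continuity correction (two discrete cells).
    Returns (n_early, n_late, p_value).
    """
    f2 = np.asarray(f2_values, dtype=float)
    if f2.size < 20:
        raise ValueError("need at least 20 F2 individuals")
    thr = _kde_valley(f2) if split == "mixture" else float(split)
    early = int((f2 < thr).sum())
    late = int(f2.size - early)
    n = f2.size
    expected = np.array([n / 4.0, 3.0 * n / 4.0])
    observed = np.array([early, late], dtype=float)
    dev = np.maximum(np.abs(observed - expected) - 0.5, 0.0)
    stat = float((dev ** 2 / expected).sum())
    return early, late, float(sps.chi2.sf(stat, 1))


def _dunnett_mc(obs_t: np.ndarray, sizes_parents: list[int], n_f2: int,
                tail: int | None, draws: int, seed: int) -> float:
    """Monte-Carlo family-wise p for the max-|t| many-to-one statistic.

    Simulates all groups from one common normal distribution, applies the
    same F2 tail selection as the observed analysis, recomputes every
    F2-tail-vs-parent t statistic and returns P(max|t*| >= max|t_obs|).
    """
    rng = np.random.default_rng(seed)
    obs = float(np.max(np.abs(obs_t)))
    exceed = 0
    done = 0
    block = max(1, min(draws, 200_000 // max(n_f2, 1)))
    while done < draws:
        b = min(block, draws - done)
        f2 = rng.standard_normal((b, n_f2))
        f2s = np.sort(f2, axis=1)
        max_t = np.zeros(b)
        for side, n_p in zip(("low", "high"), sizes_parents):
            if n_p is None:
                continue
            pmean = rng.standard_normal((b,)) / np.sqrt(n_p)
            pvar = rng.chisquare(n_p - 1, size=b) / (n_p - 1)
            if tail is None:
                grp = f2
            else:
                grp = f2s[:, :tail] if side == "low" else f2s[:, -tail:]
            gmean = grp.mean(axis=1)
            gvar = grp.var(axis=1, ddof=1)
            n_g = grp.shape[1]
            sp2 = ((n_g - 1) * gvar + (n_p - 1) * pvar) / (n_g + n_p - 2)
            t = (gmean - pmean) / np.sqrt(sp2 * (1.0 / n_g + 1.0 / n_p))
            max_t = np.maximum(max_t, np.abs(t))
        exceed += int((max_t >= obs).sum())
        done += b
    return (exceed + 1) / (draws + 1)


def _t_two_sample(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))


def transgression_test(crosses: list[CrossPhenotypes], seed: int = 0,
                       tail: int | None = 12, draws: int = 100_000):
    """Test for transgressive F2 segregation across crosses.

    Per cross, the low (high) tail of ``tail`` extreme F2 individuals is
    compared to the earlier (later) parent with a pooled-variance t
    statistic; the family-wise two-sided p comes from a seeded
    Monte-Carlo max-|t| null that simulates all groups from one normal
    distribution and repeats the tail selection (a Dunnett-type
    correction that accounts for picking extremes).  With ``tail=None``
    the whole F2 is compared to each parent (the classical many-to-one
    case).  Per-cross p-values are combined with Fisher's method.

    Returns (per-cross p-value list, CombinedTestResult).
    """
    rng = np.random.default_rng(seed)
    pvals = []
    for cross in crosses:
        parents = []
        for p in (cross.parent_a, cross.parent_b):
            parents.append(p if p.size >= 2 else None)
        if all(p is None for p in parents):
            import warnings
            warnings.warn(f"cross {cross.cross_id} lacks parental replicates; skipped")
            continue
        # order parents so index 0 is the earlier-flowering (low) parent
        means = [np.inf if p is None else p.mean() for p in parents]
        order = np.argsort(means) if parents[1] is not None else np.array([0, 1])
        plow = parents[order[0]] if parents[order[0]] is not None else None
        phigh = parents[order[1]] if len(parents) > 1 else None
        f2 = np.sort(cross.f2)
        k = f2.size if tail is None else min(tail, f2.size)
        obs_t = []
        sizes = []
        for side, parent in (("low", plow), ("high", phigh)):
            if parent is None:
                sizes.append(None)
                continue
            grp = f2 if tail is None else (f2[:k] if side == "low" else f2[-k:])
            obs_t.append(_t_two_sample(grp, parent))
            sizes.append(parent.size)
        p = _dunnett_mc(np.array(obs_t), sizes, f2.size,
                        None if tail is None else k, draws,
                        int(rng.integers(0, 2**31)))
        pvals.append(p)
    if not pvals:
        raise ValueError("no testable crosses")
    return pvals, fishers_method(pvals)


def bsa_scan(bulk_focal_counts, bulk_total_counts, positions, chroms=None,
             window: int = 100, step: int = 25, threshold: float = 0.95,
             min_informative: int = 5, window_unit: str = "variants") -> BsaScanResult:
    """Sliding-window scan of focal-parent allele frequency in a bulk.

    Per site, the focal-parent allele frequency is focal/total read (or
    allele) count; sites with zero total are uninformative.  Windows
    slide by variant count (default) or by bp; a window is flagged when
    its median frequency >= threshold, and windows with fewer than
    ``min_informative`` informative variants are reported as NA.
    """
    focal = np.asarray(bulk_focal_counts, dtype=float)
    total = np.asarray(bulk_total_counts, dtype=float)
    positions = np.asarray(positions)
    if chroms is None:
        chroms = np.array(["1"] * positions.size)
    chroms = np.asarray(chroms)
    if not (focal.size == total.size == positions.size == chroms.size):
        raise ValueError("bulk counts and coordinates must align")
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(total > 0, focal / np.maximum(total, 1), np.nan)
    if np.nanmax(freq, initial=0) > 1 + 1e-9:
        raise ValueError("focal counts exceed totals")

    rows = []
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        pos_c = positions[sel]
        freq_c = freq[sel]
        order = np.argsort(pos_c)
        pos_c, freq_c = pos_c[order], freq_c[order]
        if window_unit == "variants":
            starts = range(0, max(1, pos_c.size - window + 1), step) \
                if pos_c.size >= window else [0]
            spans = [(s, min(s + window, pos_c.size)) for s in starts]
            bounds = [(int(pos_c[a]), int(pos_c[b - 1]) + 1) for a, b in spans]
        elif window_unit == "bp":
            lo, hi = int(pos_c.min()), int(pos_c.max())
            spans, bounds = [], []
            for w_start in range(lo, hi + 1, step):
                w_end = w_start + window
                a = np.searchsorted(pos_c, w_start, side="left")
                b = np.searchsorted(pos_c, w_end, side="left")
                spans.append((a, b))
                bounds.append((w_start, w_end))
                if w_end > hi:
                    break
        else:
            raise ValueError("window_unit must be 'variants' or 'bp'")
        for (a, b), (w_start, w_end) in zip(spans, bounds):
            vals = freq_c[a:b]
            vals = vals[~np.isnan(vals)]
            if vals.size < min_informative:
                rows.append((chrom, w_start, w_end, int(vals.size),
                             np.nan, np.nan, None))
                continue
            med = float(np.median(vals))
            rows.append((chrom, w_start, w_end, int(vals.size), med,
                         float(vals.std(ddof=0)), bool(med >= threshold)))
    windows = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_variants",
                       "median_freq", "sd_freq", "flagged"])
    return BsaScanResult(windows=windows, threshold=threshold)
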