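"""Statistical primitives shared by every analysis stage.

Rank tests, Fisher's p-value combination, add-one empirical p-values, a
two-sided (minimum-likelihood) Poisson test and seeded percentile
bootstrapping.  Everything here is deterministic given its inputs; the
stochastic routines take an explicit integer seed and report it back.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "RankTestResult",
    "CombinedTestResult",
    "EmpiricalP",
    "BootstrapResult",
    "mww_test",
    "chisq_sf",
    "fishers_method",
    "empirical_pvalue",
    "poisson_two_sided",
    "percentile_bootstrap",
]

#: combined sample size at or below which the exact MWW enumeration is used
EXACT_MWW_LIMIT = 20


@dataclass(frozen=True)
class RankTestResult:
    """Mann-Whitney-Wilcoxon rank-sum test outcome.

    ``W`` is the Mann-Whitney U statistic for the first sample (number of
    (x, y) pairs with x > y, counting ties as 1/2), ``method`` records
    whether the p-value came from exact enumeration of rank assignments or
    from the tie-corrected normal approximation.
    """

    W: float
    p_value: float
    method: str  # "exact-enumeration" | "normal-approximation"


@dataclass(frozen=True)
class CombinedTestResult:
    """Fisher's combined-probability statistic S = -2 sum(ln p) with 2k df."""

    S: float
    df: int
    p_value: float


@dataclass(frozen=True)
class EmpiricalP:
    """Add-one empirical p-value (r+1)/(n+1) from a resampling null."""

    r: int
    n: int
    p_value: float


@dataclass(frozen=True)
class BootstrapResult:
    """Seeded percentile-bootstrap interval and replicate distribution."""

    lower: float
    upper: float
    replicates: np.ndarray = field(repr=False)
    seed: int = 0
    rng_algorithm: str = "numpy-PCG64"


def _mww_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for x (ties count 1/2). 0 <= U <= n_x * n_y."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mww_test(x, y, alternative: str = "two-sided") -> RankTestResult:
    """Two-sample Mann-Whitney-Wilcoxon rank-sum test.

    Uses exact enumeration of all C(n_x+n_y, n_x) assignments of the pooled
    values to the two groups when the combined sample size is at most
    ``EXACT_MWW_LIMIT`` (this remains exact under ties), and the
    tie-corrected normal approximation with continuity correction
    otherwise.  The method actually used is recorded in the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative: {alternative!r}")

    u_obs = _mww_u(x, y)
    n_x, n_y = x.size, y.size

    if n_x + n_y <= EXACT_MWW_LIMIT:
        # U_x = (sum of pooled mid-ranks of the x group) - n_x(n_x+1)/2,
        # which stays valid under ties; enumerate every group assignment.
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        offset = n_x * (n_x + 1) / 2.0
        us = np.array(
            [ranks[list(comb)].sum() - offset
             for comb in itertools.combinations(range(n_x + n_y), n_x)]
        )
        total = us.size
        eps = 1e-9
        p_greater = np.count_nonzero(us >= u_obs - eps) / total
        p_less = np.count_nonzero(us <= u_obs + eps) / total
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2.0 * min(p_greater, p_less))
        return RankTestResult(W=u_obs, p_value=p, method="exact-enumeration")

    res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return RankTestResult(W=float(res.statistic), p_value=float(res.pvalue),
                          method="normal-approximation")


def chisq_sf(x: float, df: int) -> float:
    """Chi-square survival function P(X2_df >= x) for even df.

    Closed-form series for even degrees of freedom:
    exp(-x/2) * sum_{k=0}^{df/2 - 1} (x/2)^k / k!
    computed in log space for numerical stability in the deep tail.
    """
    if x < 0:
        raise ValueError("x must be non-negative")
    if df <= 0 or df % 2 != 0:
        raise ValueError("only positive even df supported")
    half = x / 2.0
    if half == 0.0:
        return 1.0
    # log-sum-exp over terms  -half + k*log(half) - log(k!)
    log_terms = [-half + k * math.log(half) - math.lgamma(k + 1)
                 for k in range(df // 2)]
    m = max(log_terms)
    return float(min(1.0, math.exp(m) * sum(math.exp(t - m) for t in log_terms)))


def fishers_method(pvals) -> CombinedTestResult:
    """Combine independent p-values with Fisher's method.

    S = -2 sum(ln p_i), compared to a chi-square with 2k degrees of freedom.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(pvals <= 0) or np.any(pvals > 1):
        raise ValueError("p-values must lie in (0, 1]")
    S = float(-2.0 * np.log(pvals).sum())
    df = 2 * int(pvals.size)
    return CombinedTestResult(S=S, df=df, p_value=chisq_sf(S, df))


def empirical_pvalue(r: int, n: int) -> EmpiricalP:
    """Add-one empirical p-value (r+1)/(n+1).

    ``r`` is the number of null replicates at least as extreme as the
    observed statistic, ``n`` the number of null replicates.  The add-one
    rule guarantees p > 0 and is the convention consistent with reporting
    (0+1)/(2000+1) = 4.9975e-4 for zero exceedances in 2000 resamples.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= r <= n:
        raise ValueError("need 0 <= r <= n")
    return EmpiricalP(r=int(r), n=int(n), p_value=(r + 1) / (n + 1))


def poisson_two_sided(k: int, lam: float) -> float:
    """Two-sided Poisson test p-value by the minimum-likelihood rule.

    Sums Poisson(lam) probabilities of every outcome whose probability does
    not exceed that of the observed count ``k`` (ties included, with the
    same 1 + 1e-7 relative slack as R's poisson.test).  Returns 1 when
    ``k`` is the modal outcome.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    k = int(k)
    if k < 0:
        raise ValueError("k must be a non-negative count")
    rel_err = 1 + 1e-7
    d = sps.poisson.pmf(k, lam) * rel_err
    m = math.floor(lam)
    if k == m:
        return 1.0
    if k < m:
        # lower tail up to k plus the matching far upper tail
        p_low = sps.poisson.cdf(k, lam)
        # find smallest y > lam with pmf(y) <= d
        y = m + 1
        step = 1
        while sps.poisson.pmf(y, lam) > d:
            y += step
            step = min(2 * step, 1 << 20)
        lo, hi = max(m + 1, y - step), y
        while lo < hi:  # first index in [lo, hi] with pmf <= d
            mid = (lo + hi) // 2
            if sps.poisson.pmf(mid, lam) <= d:
                hi = mid
            else:
                lo = mid + 1
        p_high = sps.poisson.sf(lo - 1, lam)
        return float(min(1.0, p_low + p_high))
    # k > m: upper tail from k plus the matching far lower tail
    p_high = sps.poisson.sf(k - 1, lam)
    ys = np.arange(0, m + 1)
    p_low = float(sps.poisson.pmf(ys, lam)[sps.poisson.pmf(ys, lam) <= d].sum())
    return float(min(1.0, p_high + p_low))


def percentile_bootstrap(values, statistic, reps: int, seed: int,
                         alpha: float = 0.05) -> BootstrapResult:
    """Seeded percentile bootstrap of ``statistic`` over ``values``.

    Resamples rows with replacement ``reps`` times and returns the
    alpha/2 and 1-alpha/2 percentile bounds plus the replicate
    distribution.  Reproducible: the same seed yields identical output.
    """
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = values.shape[0]
    replicates = np.array(
        [statistic(values[rng.integers(0, n, size=n)]) for _ in range(reps)],
        dtype=float,
    )
    lower, upper = np.percentile(replicates, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapResult(lower=float(lower), upper=float(upper),
                           replicates=replicates, seed=seed)
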