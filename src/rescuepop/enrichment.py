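"""Private-variant enrichment and fitness-variance procedures.

Covers (i) the proportion of line-differentiating variants private to a
focal island per annotation category, with a two-sided Poisson test
against the genome-wide rate; (ii) variance in fitness explained by a
variant set (OLS R^2); (iii) forward-backward (sequential-replacement)
stepwise selection scored by out-of-bag bootstrap RMSE; and (iv) the
resampled null of random variant sets yielding an add-one empirical p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import MISSING, GenotypeMatrix, PopulationPanel
from .stats import EmpiricalP, empirical_pvalue, poisson_two_sided

__all__ = [
    "CategoryEnrichment",
    "ModelFit",
    "private_rate_by_category",
    "poisson_enrichment",
    "variance_explained",
    "stepwise_select",
    "resampling_null",
]


@dataclass
class CategoryEnrichment:
    category: str
    k_private: int
    n_total: int
    genome_rate: float
    fold: float
    p_value: float


@dataclass
class ModelFit:
    """Selected variant columns, full-data R^2 and bootstrap-RMSE score."""

    selected: list[int]
    r_squared: float
    bootstrap_rmse: float
    n_bootstraps: int
    rmse_convention: str = "resample-train/out-of-bag-evaluate"
    seed: int | None = None


def private_rate_by_category(matrix: GenotypeMatrix, panel: PopulationPanel,
                             categories: dict[str, np.ndarray],
                             contrast: tuple[str, str], focal_pop: str,
                             other_pops: list[str]) -> dict[str, tuple[int, int, float]]:
    """Per-category counts of line-differentiating variants private to an island.

    For each category (boolean site mask), n counts variants at which the
    two contrast lines carry different observed alleles and k the subset
    whose contrast-line-A allele is segregating in the focal population
    and absent from every population in ``other_pops``.  The genome-wide
    pair is returned under the key "genome".
    """
    ia = matrix.sample_index(contrast[0])
    ib = matrix.sample_index(contrast[1])
    a, b = matrix.calls[ia, :], matrix.calls[ib, :]
    differs = (a != b) & (a != MISSING) & (b != MISSING)

    f_idx = panel.indices(matrix, focal_pop)
    f_calls = matrix.calls[f_idx, :]
    f_m = (f_calls != MISSING).sum(axis=0)
    # count of the contrast-line-A allele in the focal population
    f_match = ((f_calls == a[None, :]) & (f_calls != MISSING)).sum(axis=0)
    segregating_focal = (f_match > 0) & (f_match < f_m)

    absent_elsewhere = np.ones(matrix.n_sites, dtype=bool)
    for pop in other_pops:
        o_calls = matrix.calls[panel.indices(matrix, pop), :]
        o_match = ((o_calls == a[None, :]) & (o_calls != MISSING)).sum(axis=0)
        absent_elsewhere &= o_match == 0

    private = differs & segregating_focal & absent_elsewhere

    out = {}
    full = np.ones(matrix.n_sites, dtype=bool)
    for name, mask in {"genome": full, **categories}.items():
        mask = np.asarray(mask, dtype=bool)
        n = int((differs & mask).sum())
        k = int((private & mask).sum())
        if n == 0:
            warnings.warn(f"category {name!r} holds no differentiating variants")
            out[name] = (0, 0, float("nan"))
        else:
            out[name] = (k, n, k / n)
    return out


def poisson_enrichment(k: int, n: int, genome_rate: float,
                       category: str = "") -> CategoryEnrichment:
    """Fold enrichment and two-sided Poisson p against the genome-wide rate."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < genome_rate < 1:
        raise ValueError("genome_rate must lie in (0, 1)")
    fold = (k / n) / genome_rate
    p = poisson_two_sided(k, n * genome_rate)
    return CategoryEnrichment(category=category, k_private=int(k), n_total=int(n),
                              genome_rate=genome_rate, fold=fold, p_value=p)


def _design(genotypes: np.ndarray, phenotype: np.ndarray):
    """Complete-case design matrix with intercept; drops aliased columns."""
    G = np.asarray(genotypes, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    y = np.asarray(phenotype, dtype=float)
    ok = ~np.isnan(y) & ~(G == MISSING).any(axis=1) & ~np.isnan(G).any(axis=1)
    G, y = G[ok], y[ok]
    keep: list[int] = []
    X = np.ones((G.shape[0], 1))
    for j in range(G.shape[1]):
        cand = np.column_stack([X, G[:, j]])
        if np.linalg.matrix_rank(cand) > X.shape[1]:
            X = cand
            keep.append(j)
        else:
            warnings.warn(f"dropping aliased/constant predictor column {j}")
    return X, y, keep


def variance_explained(genotypes: np.ndarray, phenotype: np.ndarray) -> float:
    """OLS R^2 of phenotype on the given variant columns (with intercept)."""
    X, y, keep = _design(genotypes, phenotype)
    if y.size <= X.shape[1]:
        raise ValueError("need more observations than predictors")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("phenotype is constant")
    return float(1.0 - (resid @ resid) / sst)


def _bootstrap_rmse(X: np.ndarray, y: np.ndarray, boot_idx: np.ndarray) -> np.ndarray:
    """Per-resample out-of-bag RMSE over pre-drawn bootstrap row index sets.

    Fits on each bootstrap resample and evaluates on the rows left out of
    that resample; batched over resamples via the normal equations.
    """
    B, n = boot_idx.shape
    k = X.shape[1]
    Xb = X[boot_idx]                          # (B, n, k)
    yb = y[boot_idx]                          # (B, n)
    A = np.einsum("bni,bnj->bij", Xb, Xb)
    A += 1e-10 * np.eye(k)[None, :, :]        # guard near-singular resamples
    c = np.einsum("bni,bn->bi", Xb, yb)
    beta = np.linalg.solve(A, c[..., None])[..., 0]   # (B, k)
    pred = X @ beta.T                          # (n, B) predictions on all rows
    resid2 = (y[:, None] - pred) ** 2
    inbag = np.zeros((B, n), dtype=bool)
    rows = np.repeat(np.arange(B), n)
    inbag[rows, boot_idx.ravel()] = True
    oob = ~inbag                               # (B, n)
    denom = oob.sum(axis=1)
    rmse = np.sqrt((resid2.T * oob).sum(axis=1) / np.maximum(denom, 1))
    return rmse[denom > 0]


def stepwise_select(variants: np.ndarray, phenotype: np.ndarray,
                    n_bootstraps: int = 1000, seed: int = 0) -> ModelFit:
    """Sequential-replacement stepwise regression scored by bootstrap RMSE.

    Alternates forward additions and backward deletions over the candidate
    variant columns, scoring every candidate model by mean out-of-bag RMSE
    over ``n_bootstraps`` seeded bootstrap resamples (the same resamples
    for all models, so comparisons are paired), until no move lowers the
    mean score.  The returned model applies the one-standard-error rule:
    among the best model of each size encountered during the search, the
    smallest whose mean RMSE lies within one resampling standard
    deviation of the overall best is selected, guarding against noise
    predictors that shave the mean score by overfitting.  Ties prefer the
    smaller column index / smaller model.  Bit-reproducible given the
    seed.
    """
    G = np.asarray(variants, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    y = np.asarray(phenotype, dtype=float)
    ok = ~np.isnan(y) & ~(G == MISSING).any(axis=1) & ~np.isnan(G).any(axis=1)
    G, y = G[ok], y[ok]
    n = y.size
    if n < 3:
        raise ValueError("too few complete observations")
    if np.all(y == y[0]):
        raise ValueError("phenotype is constant")
    usable = [j for j in range(G.shape[1]) if not np.all(G[:, j] == G[0, j])]
    # drop exact duplicates of an earlier column (aliasing tie-break: keep first)
    uniq: list[int] = []
    for j in usable:
        if not any(np.array_equal(G[:, j], G[:, i]) for i in uniq):
            uniq.append(j)
    if not uniq:
        raise ValueError("no usable (non-constant) candidate variants")

    rng = np.random.default_rng(seed)
    boot_idx = rng.integers(0, n, size=(n_bootstraps, n))
    cache: dict[tuple, tuple[float, float]] = {}

    def score(cols: list[int]) -> tuple[float, float]:
        key = tuple(cols)
        if key not in cache:
            X = np.column_stack([np.ones(n)] + [G[:, j] for j in cols])
            reps = _bootstrap_rmse(X, y, boot_idx)
            cache[key] = (float(reps.mean()), float(reps.std(ddof=1)))
        return cache[key]

    best_by_size: dict[int, tuple[float, tuple]] = {}

    def record(cols: list[int], mean: float) -> None:
        k = len(cols)
        if k not in best_by_size or mean < best_by_size[k][0] - 1e-12:
            best_by_size[k] = (mean, tuple(cols))

    current: list[int] = []
    current_score = score(current)[0]
    record(current, current_score)
    improved = True
    while improved:
        improved = False
        # forward
        best_j, best_s = None, current_score
        for j in uniq:
            if j in current:
                continue
            cand = sorted(current + [j])
            s = score(cand)[0]
            record(cand, s)
            if s < best_s - 1e-12:
                best_j, best_s = j, s
        if best_j is not None:
            current = sorted(current + [best_j])
            current_score = best_s
            improved = True
        # backward
        best_j, best_s = None, current_score
        for j in current:
            cand = [c for c in current if c != j]
            s = score(cand)[0]
            record(cand, s)
            if s < best_s - 1e-12:
                best_j, best_s = j, s
        if best_j is not None:
            current = [c for c in current if c != best_j]
            current_score = best_s
            improved = True

    # one-SE rule over the best model of each size
    best_mean = min(m for m, _ in best_by_size.values())
    best_cols = min((cols for m, cols in best_by_size.values()
                     if m <= best_mean + 1e-12), key=len)
    cutoff = best_mean + score(list(best_cols))[1]
    chosen = min((cols for m, cols in best_by_size.values() if m <= cutoff),
                 key=lambda c: (len(c), c))
    selected = list(chosen)
    final_mean = score(selected)[0]
    r2 = variance_explained(G[:, selected], y) if selected else 0.0
    return ModelFit(selected=selected, r_squared=r2, bootstrap_rmse=final_mean,
                    n_bootstraps=n_bootstraps, seed=seed)


def resampling_null(pruned_genotypes: np.ndarray, phenotype: np.ndarray,
                    observed_r2: float, set_size: int = 7, n_sets: int = 2000,
                    n_bootstraps: int = 1000, seed: int = 0,
                    statistic: str = "full") -> EmpiricalP:
    """Empirical p of an observed R^2 against random variant-set nulls.

    Draws ``n_sets`` seeded random sets of ``set_size`` distinct columns
    from the LD-pruned genotype matrix and recomputes on each the same
    statistic the observed value was computed with: by default the joint
    OLS R^2 of the whole set (the headline variance-explained figure);
    ``statistic="stepwise"`` instead scores the stepwise-selected model's
    R^2, mirroring the model-search pipeline.  Null values tied with the
    observed count as exceedances (conservative); p = (r+1)/(n+1).
    """
    if statistic not in ("full", "stepwise"):
        raise ValueError("statistic must be 'full' or 'stepwise'")
    G = np.asarray(pruned_genotypes, dtype=float)
    if G.ndim != 2 or G.shape[1] < set_size:
        raise ValueError("pruned matrix must have at least set_size variant columns")
    rng = np.random.default_rng(seed)
    r = 0
    for _ in range(n_sets):
        cols = rng.choice(G.shape[1], size=set_size, replace=False)
        sub_seed = int(rng.integers(0, 2**31))
        try:
            if statistic == "stepwise":
                null_r2 = stepwise_select(G[:, cols], phenotype,
                                          n_bootstraps=n_bootstraps,
                                          seed=sub_seed).r_squared
            else:
                null_r2 = variance_explained(G[:, cols], phenotype)
        except ValueError:
            null_r2 = 0.0
        if null_r2 >= observed_r2:
            r += 1
    return empirical_pvalue(r, n_sets)
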