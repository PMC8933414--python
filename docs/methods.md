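# Methods

`rescuepop` implements the population-genetic computations used to
reconstruct adaptation and evolutionary rescue in island-colonizing,
highly selfing *Arabidopsis* lineages: polarized diversity and spectra,
branch-specific selected/neutral divergence ratios, private-variant
enrichment, fitness-variance resampling, cross/BSA mapping statistics,
and forward Wright–Fisher simulation of rescue under
strong-selection/weak-mutation (SSWM) conditions.  Every stage is
exercisable on synthetic colonization scenarios with known truth.

## Data model

Inbred, highly selfing lines are coded as **haploid sequences**: haploid
VCF genotypes are kept, homozygous diploid genotypes collapse to one
allele, and heterozygous calls become missing — a conservative choice
for selfers whose residual heterozygosity is mostly genotyping noise.
Only biallelic SNPs are retained.  Coordinates are 1-based in VCF/GFF3,
0-based half-open in BED and internally.  The one place diploid genetics
matters — F1 heterozygosity, recombination, recessivity in crosses — is
handled explicitly by the cross simulator.

## Statistical primitives (`stats`)

- **MWW rank test** — exact enumeration of all group assignments when
  the pooled size is ≤ 20 (remains exact under ties), tie-corrected
  normal approximation with continuity correction above that.  The
  method used is recorded in the result, since either convention is
  defensible.
- **Chi-square survival** uses the closed-form series for even degrees
  of freedom, `exp(-x/2) Σ (x/2)^k / k!`, evaluated in log space so the
  deep tail (p ~ 1e-12) keeps full precision.  Fisher's combination is
  `S = -2 Σ ln p`, referred to 2k df.
- **Empirical p-values** use the add-one rule `(r+1)/(n+1)`: never zero,
  and the only convention that reproduces `(0+1)/(2000+1) = 4.9975e-4`
  for zero exceedances in 2000 resamples.
- **Two-sided Poisson test** sums the probabilities of all outcomes no
  more likely than the observed count (minimum-likelihood rule, with the
  same `1 + 1e-7` tie slack as the conventional R implementation).
- All stochastic routines take explicit integer seeds (numpy PCG64).

## Site annotation and LD (`io`)

Degeneracy is classified per coding position from the standard codon
table: 0-fold if every substitution changes the amino acid, 4-fold if
none does; 2-/3-fold positions, non-CDS positions and positions claimed
by conflicting overlapping CDS are "other" and excluded from divergence
counts.  Genome-wide 0-/4-fold sites-at-risk counts (L0, L4) are
computed over all annotated CDS, not just polymorphic sites.  Transcripts
whose CDS length is not a multiple of three are skipped with a warning.

CpG sites (hypermutable) are flagged when the reference context forms a
CG dinucleotide on either strand; repeat/pericentromere masks arrive as
BED.  The missing-data filter removes sites with *more than* 5% missing
calls (≤ is kept).

LD pruning is greedy and windowed (default 50 variants, step 10,
r² > 0.1): within a window the member of an offending pair with greater
missingness is removed, ties dropping the later position — a stated,
deterministic rule, since the conventional tool's tie-break is not
documented.  LD decay averages r² in 1 kb bins up to 10 kb, complete-case
per pair.

## Polarization and spectra (`spectra`)

Two polarization modes. *Reference-population*: an allele observed
anywhere in the reference population (the mainland) is ancestral; if
both alleles are present there, or no calls survive, the site is
unassigned and excluded (counted).  A corollary worth noting: under
mainland polarization a derived allele is by construction absent from
the mainland, so the `present_in_Morocco` branch class is only reachable
with *outgroup* polarization, where sites polymorphic or missing in the
outgroup are unassigned.

Spectra subsample individuals without replacement (seeded), matching the
subsample-then-count convention, with per-site complete-case handling;
hypergeometric projection is not used (sampling noise is part of what
downstream consumers see).  θ_W = S/(a_{n-1}·L) and θ_π (mean pairwise
difference per site, per-site n-adjusted) require an explicit monitored
length L — it is never inferred from the variant list.

Because haploid coding halves the number of sequences, neutral
simulation checks use θ = 2Nμ scaling (N haploid lineages), and the
synthetic generator states the same scaling.

## Branch divergence (`divergence`)

Sites are assigned mutually exclusive branch labels (fixed derived in
both islands and absent from the mainland; fixed derived in exactly one
island and absent elsewhere; segregating in one island; derived present
in the mainland).  Configurations outside this vocabulary — e.g. derived
segregating in both islands — are labelled `unassigned` and counted, so
the partition stays exhaustive.  "Absent" and "fixed" are evaluated on
observed calls only; sites with fewer than two observed calls in a
required population are unassigned.

d_sel/d_neu = (d₀/L0)/(d₄/L4) over a branch's substitutions.  A zero
d₄ raises an explicit undefined-ratio error rather than returning
infinity.  The bootstrap resamples the substitution list (multinomial
over 0-fold/4-fold/other classes); a block bootstrap over user-supplied
block ids is available for linked data.  Replicates that lose all
4-fold substitutions are recorded as NaN and excluded from the
percentile CI.

## Enrichment and fitness variance (`enrichment`)

Private-variant enrichment takes a two-line contrast (the island-derived
line vs a distant reference line), counts differentiating variants per
category (n) and the subset segregating in the focal island and absent
from the other populations (k), and tests k against n·(genome-wide rate)
with the two-sided Poisson test.

Variance explained is plain OLS with intercept, complete-case, aliased
columns dropped with a warning.  Stepwise selection is
forward–backward (sequential replacement) scored by **out-of-bag
bootstrap RMSE**: models are fit on each bootstrap resample and
evaluated on the rows left out of it, with one common set of seeded
resamples for all models so comparisons are paired.  The returned model
applies the **one-standard-error rule** — the smallest model whose mean
RMSE is within one resampling SD of the best — which is the standard
guard against noise predictors that shave the mean score by overfitting
(without it, pure-noise columns are co-selected in roughly half of
strong-signal datasets).

The resampling null draws seeded random sets of k variants from the
LD-pruned matrix and recomputes on each the same statistic as the
observed value: by default the **joint R² of the whole set** (the
headline variance-explained figure, continuous under the null and hence
uniformly distributed as an empirical p), with the stepwise-selected R²
available as an option (its null distribution has an atom at zero where
nothing is selected, so its empirical p is conservative, not uniform).
Ties between null and observed count as exceedances.

## Crosses and BSA (`crosses`)

The 1:3 segregation test classifies early/late by an explicit threshold
or by the kernel-density valley between the two F2 modes (raising an
error on unimodal data), then applies a 1-df chi-square with continuity
correction — without the correction the discrete two-cell test is
slightly anticonservative (~6.5% rejections at nominal 5%).

The transgression test compares the extreme F2 tails (default: as many
individuals as the parent has replicates) to the corresponding parent
with pooled-variance t statistics, and obtains the family-wise p from a
seeded Monte-Carlo max-|t| null (default 1e5 draws) that simulates all
groups from one normal distribution *and repeats the tail selection*, so
the selection bias of picking extremes is part of the null.  With
`tail=None` the procedure reduces to classical many-to-one comparisons,
and in the two-group degenerate case it reproduces the two-sample t-test
within Monte-Carlo error.  Per-cross p-values are combined with Fisher's
method.

The BSA scan computes the focal-parent allele frequency per site from
bulk counts and slides windows by variant count (default here 20
variants, step 5) or by bp; a window is flagged when its median
frequency ≥ 0.95 — the least-assumptive reading of flagging windows
where the frequency "reaches" fixation — and windows with fewer than 5
informative variants are NA.  Window sizing must be matched to the
variant density per Morgan: windows spanning ≫ 0.05 Morgan around the
causal site dilute the median below threshold.

## Rescue dynamics (`rescue`)

The forward simulation is a diploid Wright–Fisher model with partial
selfing: genotype fitnesses 1 : 1+hs : 1+s, each offspring drawing its
parent(s) fitness-proportionally and selfing with probability σ,
Mendelian transmission, and beneficial mutations arising as
Poisson(2NU_b) new heterozygous copies at distinct unlinked loci
(interaction only through shared reproduction — negligible at the U_b
of interest, ~1e-6).  Defaults are the Fogo-like conditions: s = 0.09273,
U_b = 1.54e-6, N = 400, σ = 0.95, h = 0.5 (dominance is not stated by
the source analyses; 0.5 is the simulation default there too, and it is
exposed and reported), 6000 generations, 200 replicates.  "Adapted"
means any beneficial allele fixed within the horizon; replicates with
copies still segregating at the horizon are reported separately.
Generations with no segregating copy are skipped geometrically (exact
for constant N), which makes the 6000-generation runs cheap.

The diffusion benchmark uses F = σ/(2−σ), h_e = h(1−F)+F,
N_e = N/(1+F), drift M(x) = s·x(1−x)[h_e + (1−2h)(1−F)x] and variance
x(1−x)/(2N_e).  Its known limits check out: s = 0 gives 1/(2N); σ = 0,
h = ½ gives Haldane's ≈ s; σ = 1 gives ≈ s (one new heterozygous copy
seeds on average half an established homozygous line, each fixing with
probability ≈ 2s among N effective haploid lines — *not* 2s per copy).
The approximation's relative truncation error grows like s at high
selfing (the clumped transmission of selfed copies inflates offspring
variance beyond the diffusion's term), and the early stochastic phase
weights the raw h, not h_e, so validation grids pair h-variation with
outcrossing and keep s ≤ 0.05 at σ ≥ 0.9.

Regime classification compares s and U_b to the drift scale 1/(4N_e):
SSWM requires U_b < 1/(4N_e) *and* s > 1/(4N_e); WSSM the strict double
reversal; boundary equalities fall to "mixed".

Founder-variant survival is a neutral haploid-lineage simulation over an
explicit N(t) trajectory (the trajectory is an input — the published
reconstruction behind the corresponding field estimate is not
redistributable, so no claim is made to reproduce its exact figure):
founder variants start from the neutral 1/i spectrum among founders, de
novo singletons arrive at rate N·μ·L, and every count drifts
binomially.  The reported quantity is the founder-inherited fraction
(per 10,000) among variants segregating at the end; its CI is a
percentile bootstrap of the replicate mean (the replicate distribution
itself is zero-inflated, so replicate percentiles would not bracket the
mean).

## Synthetic scenarios (`simulate`)

The generator emulates the statistical structure the analyses assume,
not sequence-level realism:

- **Mainland**: segregating-site count Poisson(θ·L·a_{n−1}) with
  allele counts from the neutral 1/i law, assigned to samples
  independently per site.  Default θ = 5.56e-3/site over a 500 kb
  two-chromosome genome, 64 samples.  There is no linkage structure in
  the mainland sample, so LD-based checks use purpose-built inputs.
- **Islands**: founders (default 40 and 48) drawn without replacement
  from the mainland sample; forward binomial drift over a 1700-generation
  schedule — 400 generations at founder size, exponential growth to
  2000 over 400 generations, then constant — with de novo singletons at
  rate N·μ·L (μ = 7.1e-9/site).  These horizons are chosen so the
  bottleneck purges standing variation the way the emulated history
  does: >95% of island segregating variants are de novo in truth, while
  a run takes a couple of seconds.
- **Planted variants**: one segregating large-effect flowering allele on
  the first island (s = 0.0456, arising late enough to be mid-sweep at
  the end) and one fixed on the second (s = 0.09273).  Their forward
  trajectories are conditioned on reaching the scenario's realized state
  (segregating at intermediate frequency / fixed) by retrying, which is
  the meaning of "planted".
- **Phenotypes**: flowering = baseline 62 d + planted effects (−34 d,
  −27 d) + N(0, 3 d), right-censored at the 65-day scoring horizon;
  fitness is negative-binomial (dispersion 2) with log-mean declining
  0.08/day of flowering delay from 400 seeds at 30 d.  These defaults
  produce the strong negative flowering–fitness association the
  scenario emulates (sample Spearman ρ ≈ −0.5 to −0.8 across seeds at
  n = 120 islanders; the spread comes from the planted allele's
  frequency and the negative-binomial noise); no quantitative noise
  model is published, so all are configurable.
- **Crosses**: F1 selfed; gametes recombine with Poisson crossovers
  under the Haldane (no-interference) map; F2 individuals homozygous for
  the focal parent's allele at the causal locus flower early, everyone
  else late — both the 1:3 ratio and late-side transgression follow.
  The early bulk pools the early tail (25%) but never past the
  phenotypic gap (the protocol pools plants that actually flowered
  early); per-site bulk allele counts are binomial at 50× depth.

All randomness flows from one root seed through numpy `SeedSequence`
spawning; identical seeds give byte-identical fixtures.

What passing on these scenarios does **not** show: robustness to LD
between variants (carrier assignment is site-independent), to
polarization error from deep mainland structure, to genotyping error
beyond missingness, or to phenotype distributions far from the
configured model.

## Problem sizes

Tests and the acceptance script run at desk scale, as the package's own
choice of problem size: the default scenario (~13,000 sites, 184
samples) takes ~2 s; the neutral d_sel/d_neu calibration uses 200
datasets × 600 substitutions × 500 bootstrap replicates; the neutral
fixation check uses 2×10⁵ replicates at N = 50 (vectorized across
replicates); the diffusion validation grid uses 12 parameter points ×
15,000 replicates, balancing Monte-Carlo error against the benchmark's
own truncation error; BSA recovery uses 100 end-to-end crosses of 488
F2s over 1000 variants; the resampling-null uniformity check uses 200
runs at 99 null sets.  The Monte-Carlo Dunnett default is 1e5 draws
(tests use 5–20k).

## Known limitations

- `ld_prune`/`ld_r2_decay` are O(window²)/O(pairs) pure-Python loops:
  fine at the tens-of-thousands-of-sites scale they are used at here,
  not tuned for whole-genome panels.
- The branch-label vocabulary intentionally mirrors the two-island
  design; other topologies need relabelling.
- The rescue simulator's independent-locus approximation is only valid
  while segregating beneficial copies are rare (2NU_b ≪ 1).
- The diffusion fixation benchmark degrades at s ≳ 0.1 combined with
  σ ≳ 0.95, as documented above; the simulator, not the benchmark, is
  the reference there.
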