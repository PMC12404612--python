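# Methods

`wormexpress` analyses single-individual transcriptomes against
quantitative traits in an isogenic cohort. The motivating setting is a
clonal *C. elegans* population: 180 genetically identical worms, reared
in five biological replicates under a 2x2 historical-environment design
(parent of day-1 vs day-3 adulthood; constant 20 °C vs an early 25 °C
shift), each phenotyped for two reproductive traits — egg-laying onset
(ELO, integer hours on a 66–74 h observation window) and early brood
(progeny in the first 24 h of laying) — and profiled by single-worm
mRNA-seq. Because the worms are isogenic, trait variation is entirely
non-genetic; the analyses partition it into historical-environment
effects and residual expression "noise", and ask how predictive
aggregate expression is of individual traits.

## Normalization and gene filters

Counts are normalized to plain counts-per-million,
`cpm = counts * 1e6 / library_size`, with library size the column sum.
TMM effective library sizes are not applied (a `tmm` flag exists but is
unimplemented); the downstream models consume plain CPM. Two strict
(`>`) filters are used: *any CPM > 10* (a gene clears 10 CPM in at
least one worm) for the trait scans, and *all CPM > 1* (every worm)
where zeros destabilize model fitting (NB models, PCA, elastic net).
For PCA and penalized regression, CPM is mean-normalized per gene and
log2-transformed as `log2((cpm + eps) / mean(cpm + eps))` with a fixed
pseudocount `eps = 0.5` CPM applied before both steps; the order
(divide by the gene mean, then log) makes the transform invariant to
per-gene rescaling.

## The mixed-model engine

All single-gene inference uses a random-intercept linear mixed model

    y = X b + u_rep + e,  u_j ~ N(0, s2_u),  e_i ~ N(0, s2_e / w_i)

fitted by REML with the variance ratio `lam = s2_u / s2_e` profiled.
Because the grouping factor is a single partition (biological
replicate), the Woodbury identity reduces every quantity the restricted
likelihood needs to cross-products and per-group sums, so one fit costs
O(n) once plus O(groups) per objective evaluation. This matters: the
calibration suites fit on the order of 1e5 models, which would be
impractical with a generic solver. The optimizer is bounded scalar
minimization on log(lam) (with the lam = 0 boundary checked
explicitly); tests cross-check estimates against an explicit-covariance
profiled-likelihood grid search and against statsmodels MixedLM.

Fixed-effect p-values are Wald t with `df = n - n_fixed - n_groups`; a
normal-approximation switch (`df_rule="normal"`) is provided because
mixed-model engines differ in their df conventions and the choice is
material only at small n.

**Trait scan.** One model per gene with the trait as response, the
gene's CPM as the fixed effect (a log-CPM switch is provided) and
replicate as the random intercept. Genes are flagged by a Bonferroni
cut at `alpha / G` over the `G` scanned genes — for alpha = 0.05 over
the 8824-gene *any CPM > 10* universe this is the familiar 5.67e-6.
Effects are also reported standardized (`b * sd(x) / sd(y)`).

**Environment scan.** Per gene, a negative-binomial mixed model on the
raw counts with parental age and early temperature as fixed effects,
replicate as random intercept, and log library size as an offset
(libraries span roughly an order of magnitude, so the offset is
statistically necessary even though the response is raw counts). The NB
parameterization is mean/dispersion with `Var = mu + mu^2 / theta`. No
installed Python package fits this model, so it is fitted by penalized
quasi-likelihood: iterated weighted working-response LMM steps
(weights `mu / (1 + mu/theta)`) alternating with one-dimensional
profile-ML updates of `theta` at the current means. Simulations show
the planted log-fold-changes are recovered within sampling error and
per-gene type-I error is controlled (slightly conservative).

**Variance Z-scores.** A gene's "unexplained variance" is the sample
variance of the log-scale working residuals `(y - mu) / mu` of its NB
mixed model — expression variability left after environment and
replicate. Because variance grows with abundance, `log10(variance)` is
regressed on `log10(mean CPM)` by loess (tricube weights, degree 2,
span 0.75; written in-house since the installed smoother is degree-1
only) and residuals from the trend are z-scored (centered, so the Z
vector has exactly zero mean). Genes with zero variance are excluded
with a log entry; at least 50 genes are required for a stable trend.

## Path decomposition

For each trait-associated gene, three models quantify how much of the
expression-trait association survives adjustment for historical
environment:

* Model 1: `trait ~ expression + (1 | replicate)` — total effect beta1;
* Model 2: `trait ~ expression + age + temp + (1 | replicate)` —
  adjusted effect beta2, plus environment-on-trait paths beta3, beta4;
* Expression model: `expression ~ age + temp + (1 | replicate)` —
  environment-on-expression paths beta5, beta6.

All coefficients are standardized by sample SDs (binary environment
variables included, so beta3–beta6 are comparable across genes);
p-values come from the unstandardized fits; intercepts are computed but
not reported. In trait units, a standardized beta maps to
`beta * sd(trait)`: at an early-brood SD of 20.3, standardized effects
of 0.39 and 0.26 correspond to 7.9 and 5.3 progeny.

Genes are then classified against the environment scan: **noise**
(beta2 significant, parental-age DE not), **parental_age** (the
converse), **both**, or **neither**. The beta2 Bonferroni family
defaults to the trait-significant gene set (the classification operates
within it); the whole-scan family is available by configuration.

## Prediction suite

These analyses are plain multiple regressions — the question is
predictive power, not per-gene inference — and all use the *all CPM>1*
log layer unless noted.

* **Cumulative-PC regression.** PC scores come from a per-gene-centered
  SVD (signs fixed by the largest-magnitude loading). PCs enter the
  regression in variance order; the null band comes from shuffling the
  trait (default 100 permutations). Orthonormality gives the exact null
  mean `E[R^2 at k PCs] = k / (n-1)`, which the tests verify; the curve
  reaches 1 at k = n-1 even for shuffled traits.
* **Greedy forward selection.** At each step the gene maximizing the
  R^2 increment given the selected set is added, implemented by
  orthogonalizing candidates against the current design so each step is
  one matrix-vector pass. Ties within 1e-12 break lexicographically by
  gene id. Verified against exhaustive best-subset enumeration for the
  first two steps.
* **Train/test resampling.** The cohort is split into random halves
  (default 500 times); the top-k genes (k = 10) are selected and refit
  on the train half and scored on the test half. Test R^2 is the
  squared Pearson correlation of predicted versus observed
  (`1 - SSE/SST` available by configuration). Iterations are seeded by
  SeedSequence spawning so any single iteration is reproducible alone.
  On synthetic cohorts whose trait carries a five-gene signal with a
  process R^2 of 0.6, the median test R^2 sits slightly below the
  process value (selection and estimation on n/2 worms shrink
  out-of-sample fit); null traits give a median test R^2 near zero.
* **Elastic-net LOOCV.** One elastic net per worm (L1 ratio 0.5),
  trained on the other n-1 worms with the penalty weight chosen by
  5-fold cross-validation inside the training fold and predictors
  standardized within the fold, then used to predict the held-out worm.
  The held-out trait never enters its own prediction (asserted
  bitwise in tests).

## Enrichment analyses

Gene-level effects and variability are compared across a chromatin/
tissue annotation (domains: H3K27me3-marked *regulated* vs broadly
expressed *active*, plus *other*; tissues: soma, germline, other).

* **Two-way ANOVA** (tissue x domain with interaction, Type II sums of
  squares via nested OLS comparisons) on per-gene effect sizes,
  restricted to soma/germline and active/regulated with at least three
  genes per cell; Tukey HSD over the four cell means; one-sample
  t-tests of each cell against zero. Verified against textbook
  sums-of-squares on balanced fixtures.
* **Regulated-proportion comparison.** For each predictive gene set,
  the proportion of regulated genes among its active+regulated members
  ("other" and unannotated genes leave the denominator; sets with no
  annotated member are excluded). The observed distribution over
  resampling iterations is compared with same-size random sets from the
  expressed background by a two-sample Kolmogorov–Smirnov statistic.
  The p-value is computed by **label permutation** rather than the
  classical KS null: set proportions take only a few dozen values, and
  under such heavy ties the continuity-assuming KS null is badly
  conservative (measured type-I error ~0.017 at nominal 0.05), whereas
  the permutation null — vectorized as multivariate-hypergeometric
  splits of per-value counts — stays calibrated. The classical
  asymptotic and exact variants remain available via ``ks_method``.
* **Variance by domain.** Two-sided Wilcoxon rank-sum test of variance
  Z-scores, regulated versus active genes.

## Isogenicity check

Per-site, per-worm base counts (pileup-style) are filtered to >= 20
reads; calls are *unambiguous* (one base), *two-base*, or *multi*
(tallied, never candidates). Sites need coverage in >= 10 worms.
Candidate homozygous variants are minority unambiguous calls at sites
where another worm is unambiguous for a different base; candidate
heterozygous variants are two-base calls with both allele fractions in
[0.3, 0.7] (inclusive — skewed fractions are the sequencing-error
signature) while >= 10 other worms are unambiguous for one shared base.
Rates are candidates per site x worm observation passing the filters.
Error-free simulations without variants yield exactly zero candidates;
planted variants at 1e-6 over ~1e7 observations are recovered exactly.

## Synthetic cohorts

The generator reproduces the study's design parameters: 180 worms, five
replicates, Bernoulli(0.5) environment assignment, an early-brood SD
calibrated to 20.3 around a mean of 120 progeny (a realistic first-day
brood for wild-type hermaphrodites), and ELO as a discretized affine
map of a Gaussian latent onto 66–74 h. Counts are negative-binomial
(default theta = 10, a moderate overdispersion typical of bulk
libraries) around log-uniform abundances of 1–3000 CPM, with log-normal
library sizes around 2e6 counted reads, replicate intercepts of SD 0.1
on the log scale, and planted parental-age effects on 2.5% of genes
(log-effect SD 0.35); temperature effects are not planted by default,
mirroring how rare they are in real data. Traits are built generatively
from the adjusted-model structure — standardized gene effects (2% of
genes, effect SD 0.15) plus environment (default standardized
parental-age effect 0.3 on brood, 0.2/0.2 on ELO), replicate intercept
and unit Gaussian noise — so that recovery of beta2 is directly
testable. The stored library sizes of a simulated matrix are its
realized column sums (an NB draw cannot hit a preset total; the target
size enters the generative mean as an offset).

What the generator does **not** emulate: read-level error profiles,
gene-gene co-expression beyond shared replicate/environment structure,
compositional coupling beyond the CPM constraint, batch effects other
than replicate intercepts, and the wet-lab time course. Passing tests
therefore demonstrate statistical correctness and calibration of the
machinery under the declared generative model, not performance on any
real cohort.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run everything at desk
scale, chosen as the smallest sizes at which the Monte-Carlo bands are
informative: calibration suites use 100–500 replicate cohorts of
300–500 genes x 180 worms; prediction checks use 100–300 genes;
the variant-rate recovery uses 50 worms x 2e5 sites (~1e7
observations). Tie-breaks are lexicographic (greedy selection) or
lowest-index (majority base). Degenerate inputs — constant predictors,
zero-variance traits, empty annotation cells, zero library sizes —
raise informative errors or are skipped with log entries rather than
propagating NaNs; non-converged per-gene fits are excluded and logged,
never silently kept.

## Known limitations

* The NB mixed model uses PQL, which is biased for very small counts
  and few replicate levels; the contract is on estimate recovery at the
  study's scale (n = 180, five replicates, filtered genes), where the
  bias is negligible relative to sampling error.
* Wald t inference with a single df rule is an approximation; no
  Satterthwaite/Kenward-Roger correction is attempted.
* CPM (not TMM) normalization assumes composition effects are mild.
* The elastic-net LOOCV refits the penalty path per fold and is the
  slowest stage; the pipeline leaves it off by default (`run_enet`).
* Classification of genes into noise/parental-age groups inherits the
  arbitrariness of its two Bonferroni families; both are exposed.
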