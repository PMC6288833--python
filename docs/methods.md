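# Methods

## Model and tests

`mvqtlmap` fits, at every position of an evaluation grid, a double
generalized linear model (DGLM): a normal mean submodel and a log-linear
variance submodel,

    y_i ~ Normal(mu_i, sigma_i^2),
    mu_i = x_mean,i' beta,    log sigma_i^2 = x_var,i' theta,

where both design matrices contain an intercept, any user-named
covariates, and the locus's additive and dominance dosage columns.
Dosages are expectations under the HMM genotype posterior: additive
= P(BB) − P(AA) ∈ [−1, 1], dominance = P(AB) ∈ [0, 1] (a backcross has
only the additive column).  Any full-rank linear recoding of these
columns leaves the likelihood-ratio tests unchanged (asserted in the
test suite), so the uncentered dominance coding is a convention, not a
modeling choice.

Four tests per locus, all likelihood-ratio comparisons reported as LOD =
log10 LR with a nominal p from chi-square(df = parameter-count
difference):

* **mQTL** — null drops the locus terms from the mean submodel only; the
  variance-side locus terms are *retained* in the null, so the test is
  specifically about mean effects under a locus-aware variance model.
* **vQTL** — mirror image: null drops the variance-side locus terms.
* **mvQTL** — null drops locus terms from both submodels.
* **traditional** — ordinary homoscedastic interval mapping: mean-side
  locus terms vs none, intercept-plus-covariates variance in *neither*
  model (closed-form OLS likelihoods).

The three DGLM tests share one alternative fit per locus.  Null fits
that do not depend on the locus (the mvQTL and traditional nulls, when
covariates are locus-free) are fitted once per scan and reused; equality
with the unfactored path is asserted in the tests.

## Fitting

Full maximum likelihood (not REML — REML likelihoods are not comparable
across mean designs, and the scan compares likelihoods).
Block-coordinate ascent: (i) weighted least squares for `beta` with
weights 1/sigma_i^2; (ii) for `theta`, Fisher scoring with step halving
on the squared residuals d_i = (y_i − mu_i)^2 — the estimating equations
of a gamma GLM with log link and prior weights 1/2.  The theta block
objective is concave, so each halved step ascends; both block updates
maximize their block, making the total log-likelihood monotone across
iterations (asserted on every traced fit).  Convergence: |Δ loglik| <
1e-8, max 50 outer iterations; non-convergence is reported on the fit
object and surfaces as a missing LOD with a warning, never a silent 0.

Numerical guards: squared residuals floored at 1e-12 before the
log-link update; the linear predictor of the variance submodel clipped
to ±30 (sigma^2 within e^±30); exactly singular per-locus systems fall
back to a pseudoinverse solve, which leaves fitted values (hence LODs)
well defined at degenerate loci; a locus whose dosage columns are
constant is reported as LOD 0, p 1 outright.  Standard errors:
Cov(beta) = (X_m' W X_m)^{-1} at the converged weights; Cov(theta) =
2 (X_v' X_v)^{-1}, the inverse Fisher information of the dispersion
block.  Initialization: OLS for beta; theta from a regression of
log d_i + 1.2704 (the mean of log chi-square_1) on the variance design.

The scan machinery runs on a batched version of this fitter that
vectorizes many small fits (loci × permutations × resamples) through
stacked normal equations.  The batched and single-fit paths are the same
algorithm and are asserted equal in the tests; each batch member's
trajectory depends only on its own data, so results are independent of
how work is chunked or parallelized.

## Genotype probabilities

A hidden Markov chain per chromosome: stationary start (1/4, 1/2, 1/4)
for F2, (1/2, 1/2) for backcross; transition kernels from the Haldane
map function r(d) = (1 − e^(−2d/100))/2 (no interference; Kosambi not
offered, keeping the chain exactly checkable by path enumeration);
emission 1 − e for the observed class with e split over the others,
uninformative at missing markers and pseudomarkers.  The evaluation grid
is the union of markers and pseudomarkers at exact multiples of the step
(default 2 cM) from the chromosome start, named `c{chr}.loc{pos}`.  The
genotyping-error rate defaults to 1e-4 — a small allowance in the spirit
of standard cross-analysis practice; the forward-backward posterior is
verified against exhaustive hidden-path enumeration on all short chains.

## Permutation significance

Nominal p-values ignore multiplicity, so genome-wide significance is
empirical.  One permutation of individuals per scan is applied to the
dosage columns of the *alternative* models only — mean block for the
mQTL (and traditional) test, variance block for the vQTL test, both for
the mvQTL test — while the phenotype, covariates and all null models
stay fixed.  This preserves the covariate structure and the linkage
structure of the genome (a per-locus permutation would break the
correlation of maxima along chromosomes).  The same permutation serves
all four tests at one permutation index, so their maxima are comparable
and the computation is shared.  An alternative reading would permute the
null models' variance-side dosages too; we keep the nulls untouched,
which also lets them be cached across permutations.

Genome-wide maximum LODs over permutations are fitted with a
maximum-likelihood GEV (method-of-moments Gumbel start; scipy's shape
sign convention mapped to the standard ξ).  Observed LODs become
FWER-adjusted p = 1 − F_GEV(LOD), clamped to [1/(n_perms+1), 1] so a
finite permutation set never reports p = 0.  Below 25 permutations the
GEV fit is refused and raw empirical quantiles are used, with a warning;
a fitted |shape| > 1 also warns (heavy-tail instability).  Batches run
with different base seeds can be pooled: maxima are concatenated, the
GEV refit, and the observed scan re-evaluated.  Per-permutation seeds
are pre-derived from the base seed, so results are identical for any
worker count.

## Bootstrap location intervals

Nonparametric case bootstrap for QTL position: resample n individuals
with replacement, rescan the QTL's chromosome only, record the peak
position of the chosen test (ties broken toward the smallest cM),
then take percentile intervals — 10th–90th for 80%, 5th–95th for 90%
(percentile rather than BCa: it is the standard for QTL position and
keeps resamples poolable).  1000 resamples is the default
recommendation.  Genotype probabilities are per-individual, so a
resample is an exact row subset of the precomputed array.  Degenerate
resamples are redrawn with a fresh derived seed and counted.

## Effect summaries and plots

`effects_at_locus` refits the locus DGLM with the requested focal and
nuisance factors in both submodels and predicts per focal group: mean
x'beta with SE sqrt(x' Cov(beta) x); SD exp(eta/2) with the delta-method
SE(SD) = SD·SE(eta)/2.  Nuisance factors are averaged on the linear
predictor scale with equal weight per observed level
(observation-frequency weighting available).  A model-free companion
hard-assigns individuals to their most probable genotype and reports raw
group moments with textbook SEs (SE(SD) ≈ s/√(2(n−1))) — a quick check
that the model is not being led by a few points.  Plot functions return
the exact numbers they draw (and the CLI writes them as CSV), so no test
parses pixels.

## Simulator

The simulator emulates a small F2 study: each parental gamete is a
two-state Markov chain along the marker grid with Haldane recombination
probabilities; offspring genotype is the sum of two independent gametes;
sex is assigned deterministically (males then females).  Phenotypes are
y = a·d + ε with d the −1/0/+1 code at the QTL marker (placed at the
central marker, so effect recovery is exact at a scanned locus) and
ε ~ Normal(0, sd[g]^2 · svr^(2·sex)).  The additive coefficient is
derived from the target variance-explained fraction f via the F2
identity Var(d) = 1/2: a = sqrt(2 f σ̄²/(1−f)), with σ̄² the
(1/4, 1/2, 1/4)-weighted mean residual variance.  Dominance mean effects
are zero in the shipped benchmark specs.  The vQTL SD triple
(0.8, 1, 1.25) is additive on the log-SD scale; the mvQTL triple
(0.85, 1, 1.17) is used as printed.  The female/male residual-SD ratio
for the sex-heteroscedastic variants defaults to 1.5 ("greater" made
concrete; configurable).  One seeded generator drives gamete chains and
noise in a documented order, so crosses are bit-reproducible.

What the simulator does *not* emulate: genotyping errors and missing
genotypes (scans tolerate them; simulated data are complete), epistasis,
multiple linked QTL, selective genotyping, non-normal residuals, and
real linkage-disequilibrium structure.  Passing tests therefore
demonstrate correctness of the machinery under the model's own
assumptions, not robustness to their violation.

## Problem sizes used in the checks

The shipped checks run at desk scale on one core: effect-size recovery
at n = 10,000 (SD triples) and n = 100,000 (variance explained via locus
R²); FWER calibration over 200 single-chromosome null crosses (n = 200,
51 grid loci, 100 permutations each); detection power over 20 replicate
benchmark crosses (n = 400, 100 permutations); bootstrap coverage over
50 replicates × 200 resamples.  Binomial 99% bands are used for the
calibration and coverage checks.

## Known limitations

* F2 and backcross only; no multi-parent or RIL designs, no
  X-chromosome-specific treatment (X is simply excluded from the
  supported codings).
* Normal response only; the nominal chi-square p-values inherit the
  usual sensitivity to residual non-normality — the permutation p-values
  are the robust ones.
* Degrees of freedom count dosage columns as ordinary regressors; no
  correction for the fact that dosages are estimated probabilities.
* The GEV tail model with ~100 permutations gives usable but noisy
  adjusted p-values near 0.05; more permutations (or pooled batches)
  sharpen them.
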