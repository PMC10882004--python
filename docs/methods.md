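# Methods

## Model and procedure

The package studies a two-arm trial whose end point is the change in a
cognitive score (CDR-SB) over a follow-up period. Its core quantity is the
allocation bias of a randomization procedure — the placebo-minus-treatment
difference in mean *true* outcome change created purely by the random
split — and everything else is built on top of its Monte-Carlo
distribution:

1. **Extraction.** Each replicate draws n participants from the cohort
   (without replacement; with replacement once n exceeds the cohort size).
2. **Allocation.** A randomization table — a random sequence of two-label
   permuted blocks, each `[P,T]` or `[T,P]` with probability ½ — is
   regenerated per replicate and consumed in extraction order. Stratified
   methods first bin participants on one index into half-open intervals of
   width `interval` (edges offset by `shift`), with two boundary strata
   catching out-of-range values, and run an independent table per stratum;
   an odd-sized stratum leaves its last participant on the first label of
   the next unused block, so per-stratum arm counts differ by at most one.
3. **Bias.** The replicate's bias is recorded in outcome units and on the
   Cohen's *d* scale (divided by the pooled two-arm SD, n−1 weights).
   The SAE is the SD (ddof = 1) of the replicate biases; the 95% possible
   effect size under a null treatment is `±1.96·SAE`.

For non-stratified allocation of an even n this yields the closed form
SAE = 2σ/√n (σ the cohort outcome SD, ddof = 1), which the tests use as an
independent oracle; stratification removes the between-strata share of the
outcome variance and floors at `2·σ·√(1−ρ²)/√n` plus the leftover and
within-stratum terms discussed under *Limitations*.

## Synthetic cohort

All variables share one latent Gaussian factor z (the pre-rounding true
change):

* latent truth `L = μ + σ·z`, observed truth = L rounded to the score grid
  (default 0.5, halves away from zero);
* prediction `pred = μ + ρ|ρ|σ·z + |ρ|σ√(1−ρ²)·e` with e ⊥ z — the
  *calibrated-regression* form: `Var(pred) = ρ²σ²`, unit regression slope
  of truth on prediction, population correlation ρ with the latent truth.
  This is how a well-calibrated fitted regressor behaves, and it makes
  stratification efficiency depend on ρ alone;
* each auxiliary index keeps its own marginal mean/SD and correlation c,
  `v = m + c·s·z + s√(1−c²)·e_k`, with the noises independent across
  indices given z (single-factor structure — only an index's own
  correlation with the truth matters for single-index stratification).

Defaults: n = 506, μ = 0.978, σ = 1.899, grid 0.5, ρ = 0.601.

**Moment matching (`exact_moments=True`, default).** The generator emulates
*one specific* cohort described by its summary statistics, so the realized
sample mean/SD of the latent truth and its sample correlation with each
index are matched exactly (z-scores standardized and noises orthogonalized,
in the style of `MASS::mvrnorm(empirical=TRUE)`). Without matching, a
single 506-draw realization carries ~3% noise in its sample SD, which
propagates one-for-one into every SAE; with it, cohort-to-cohort
variability reduces to the rounding step (realized outcome SD ≈ 1.905,
the √(σ² + grid²/12) inflation). Set `exact_moments=False` for ordinary
i.i.d. draws.

The generator does **not** emulate: the heavy-tailed decline distribution
of real cohorts (extreme decliners with |ΔCDR-SB| up to ~10), the
prediction model's error profile (real predictors tend to be sharper in
the bulk and useless on outliers — under the Gaussian copula the global
Pearson ρ is the whole story, on real data it is not), missing data, or
dependence among auxiliary indices beyond the shared factor. Consequently,
passing tests validate the *simulation machinery* and the ρ-driven
mechanism of bias reduction; absolute SAE levels for stratified methods on
a real cohort can differ from the Gaussian surrogate in either direction.
In particular, a predictor whose bulk accuracy exceeds what its global
Pearson correlation suggests stratifies better than this surrogate
predicts.

## Default stratification ranges

Stratum ranges for an index default to its 1st/99th cohort percentiles
rounded outward to the 0.5 grid, interval 0.5, and shift = half the
outcome grid (0.25) for continuous indices, 0 for grid-valued ones — so
grid values sit mid-stratum rather than on edges. All are overridable per
method in the run config.

## Trial simulation

A treatment effect of x% multiplies each treated participant's true change
by (1 − x/100): the effect acts on the decline itself, so the treated
arm's mean *and* SD shrink by the same factor. An additive-shift mode is
deliberately not provided. Arms are compared with a pooled-variance
(Student) two-sample t test (Welch behind a flag for sensitivity
analysis); one-tailed tests use the alternative "placebo declines more".
The deterministic *perfect allocation* reference assigns both arms the
population moments exactly; simulated p-value medians overlay it.
Detection rates at p < 0.05 are reported conditionally on whether the
placebo arm was declining faster before the effect (ties on the grid count
as placebo-worse, for determinism).

In the two-phase design, a proof-of-concept trial (n = 500, one-tailed
α = 0.1) gates a confirmatory trial sized from the observed effect: per-arm
m = ⌈z²·(sd_P² + sd_T²)/OES²⌉ with z the upper 0.01 normal quantile — the
smallest size at which the *expected* statistic reaches the design
quantile, the minimal reading of "size the next phase to achieve p = 0.01".
Targeting 0.01 while deciding at 0.05 builds in margin against an
over-estimated OES; when the OES estimate is exact this yields confirm
power Φ(z₀.₀₁ − z₀.₀₅) ≈ 0.75. The estimate is clamped into [4, 20 000]
(cap flagged in output) against pathologically small gated effects;
confirmatory participants are drawn fresh, independent of the PoC sample.

## Numerical and design choices

* Bias sign convention: placebo − treatment (distribution symmetric, SAE
  unaffected).
* Block size fixed at 2; larger permuted blocks are out of scope.
* Sample-size curves record the running bias of one sequential allocation
  per replicate at every grid point (grid: step 1 to 600, step 10 to
  3000) — within-replicate values are correlated across s, but the per-s SD
  across replicates is what is estimated, and an independent-per-s mode
  validates the shortcut. The extraction sequence is a cohort permutation
  continued by with-replacement draws, so every prefix up to the cohort
  size is a without-replacement sample.
* The minimum-sample-size solver defaults to inverting a least-squares
  `c/√s` fit: the literal first-crossing rule on a noisy Monte-Carlo curve
  returns the first noise-induced dip, and on the coarse part of the grid
  can only land on a multiple of the step.
* Degenerate inputs: a constant-outcome cohort has SAE exactly 0 and an
  undefined (NaN) Cohen's-d SAE; zero-variance arms give p = 1 on equal
  means and p = 0 otherwise; out-of-range index values are clamped into
  boundary strata so every participant stays allocable.
* Randomness: every public function takes a seed/Generator; replicate
  loops run on spawned substreams, and the experiment driver derives one
  substream per (stage, method) from the root seed, so results are
  reproducible independent of which stages run. Summary JSON and CSVs are
  byte-stable across reruns.

## Problem sizes

Library defaults follow the reference design: 10,000 replicates for bias
distributions, n = 500 trials on the 506-participant cohort. The test
suite exercises the same code paths at 800–4,000 replicates (with
tolerances widened by the corresponding √reps factor, Monte-Carlo SE of an
SD ≈ SAE/√(2·reps)) and 2,000 replicates for the trial/multiphase property
checks.

## Known limitations

* Two arms, one stratification index, 1:1 allocation only; no
  multi-index or adaptive randomization.
* The stratified SAE carries two overheads the idealized `2σ√(1−ρ²)/√n`
  floor omits: odd-stratum leftovers (each a free ±1 coin toss on one
  participant, ~order #strata/2 per trial) and within-stratum index
  variance (~interval²/12 of explained variance). At the default geometry
  these add ~3–4% to the stratified SAE at n = 500.
* The Gaussian-copula cohort makes the global Pearson ρ the sole driver of
  stratification benefit; real predictors with structured error profiles
  are not representable (see *Synthetic cohort*).
* The confirmatory-phase size formula uses the normal approximation with
  the PoC arm SDs; no variance-inflation or dropout adjustment.
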