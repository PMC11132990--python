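# Methods

This note documents the models, parameters and numerical choices behind
`rhythmprior`, and what the synthetic validation does and does not show.

## The rhythm simplex

A three-interval rhythm (s₁, s₂, s₃), s₁+s₂+s₃ = s, is represented by its
proportion triple p = (s₁, s₂, s₃)/s and embedded in the equilateral
triangle with vertices P₁ = (0,0), P₂ = (1,0), P₃ = (½, √3/2) as
x = p·(P₁,P₂,P₃).  All distances anywhere in the package are Euclidean
distances in this unit-side embedding; converting a triangle distance to a
duration scale multiplies by the cycle period (0.006 units ≙ 12 ms at
2,000 ms).  The *inner region* is the set of rhythms with every proportion
strictly above f = min-seed-interval / period = 300/2000 = 0.15; seeds are
sampled uniformly there (an affine map of a uniform simplex draw, so the
sampler is deterministic per rng stream), and only reproductions whose
trial mean lies there enter the prior estimate.  Boundary membership uses
strict inequality, mirroring the strict seed constraint; the measure-zero
boundary cannot arise in floating data anyway.

Integer-ratio categories are enumerated exactly: ordered triples over
{1..3}, deduplicated as exact rationals (`fractions.Fraction`), filtered to
minimum proportion ≥ 0.15.  This yields the 22 ratios Ω₂₂, whose partition
under cyclic rotation gives 8 classes (labelled by the lexicographically
minimal rotation: 111, 112, 122, 113, 123, 223, 233, 132); adding the
rotations of 7:2:3 gives Ω₂₅ with 9 classes.  d_min, the minimal pairwise
distance among projected Ω₂₂ members, is 0.0433 (the 3:3:2 ↔ 2:2:1 pair).

## Tap preprocessing

Onsets from audio are threshold crossings at 1.45% of the maximal *power*
(squared amplitude — the text leaves amplitude vs power open; power is
assumed) within non-overlapping 15 s windows; onsets closer than 80 ms are
merged greedily left-to-right (a motor limit on human tapping — this
constant does **not** scale with tempo).  Each response is matched to its
nearest stimulus click; the mean asynchrony m is computed once over all
initial matches (a single pass, not iterated); responses with
|(r − m) − s| > 150 ms are dropped, and at most one response survives per
click (smallest centred asynchrony, ties to the earlier tap).

Averaging is cycle-relative: the tap matched to click 3c+k contributes
time r − O₃c at position k.  The final (31st) onset folds to position 0 of
a notional 11th cycle and is excluded from interval averaging.  Missing
taps are imputed with the position mean (leaving the mean unchanged), and
the averaged response is r = (t₁−t₀, t₂−t₁, s−(t₂−t₀)), which sums to the
stimulus cycle duration exactly.  An iteration is valid iff every position
was tapped in ≥ 3 of 10 repetitions and min(r) ≥ 285 ms.  The 150 ms
window, the 285 ms floor and the 300 ms seed floor scale linearly with the
period in the fast-tempo (1,000 ms) variant.

Per-repetition points for the kernel estimator are built the same way,
one row per cycle with at least one detected tap (fully-missing cycles
would only duplicate the mean).

## The protocol

Valid iteration ⇒ the averaged response becomes the next stimulus;
invalid ⇒ the stimulus repeats.  The invalid count is cumulative within a
trial; at three the trial stops.  Iterations keep their attempted index,
so a "fifth iteration" is always the fifth attempt.

## The synthetic tapper

The generator is a stand-in with known ground truth; no claim is made
that it models human tapping beyond the statistical structure the
analysis assumes.  Its prior is a mixture of isotropic Gaussian modes on
the triangle (optionally plus a broad background component), its
observation is the stimulus plus isotropic sensory noise (sd `sigma_s`,
triangle units), and its posterior is computed by quadrature on the
analysis grid.  Production follows the estimated intervals, re-anchored at
each stimulus cycle start, with per-interval motor noise (`sigma_m_ms`,
default 10 ms), a per-tap anticipatory asynchrony (mean `mu_a_ms` = −50 ms,
sd `sigma_a_ms` = 25 ms — the negative mean asynchrony of sensorimotor
synchronization) and i.i.d. tap deletion (`p_miss` = 0.05).  Interval sums
are *not* renormalized: real tapping does not conserve the period, which
is why the analysis works in proportions.

Three observer regimes exist:

1. **Posterior mean** (default, `sigma_s` = 0.04): deterministic attractor
   dynamics.  Chains converge toward prior modes over a few iterations —
   this regime carries the transmission-error convergence property — but
   the probability of ending at a given mode is its basin mass under the
   seed distribution, *not* its mixture weight.
2. **Posterior sample** (`sample_posterior=True`): the textbook iterated-
   learning sampler whose stationary distribution is the prior.  In this
   protocol it is, however, truncated: a cross-category jump moves taps
   more than 150 ms from their clicks, the iteration is invalidated, and
   category frequencies become biased by trial stopping.
3. **Persistent target** (`persistent_target=True`, used with an
   effectively uninformative observation, `sigma_s` = 1): the percept is
   sampled from the posterior once per trial — with weak observation this
   is a draw from the prior itself — and production drifts toward it by at
   most `max_step` = 0.07 triangle units per iteration (≤ ~140 ms per
   onset, inside the matching window).  Every iteration stays
   protocol-valid and fifth-iteration category frequencies equal the
   ground-truth weights.  `recovery_params()` packages this regime.

### Recovery-study design

Weight recovery is only defined when the ground truth is identifiable by
the constrained model class, so the three-mode calibration prior places
its modes on the three cyclic classes whose nearest neighbours within Ω₂₂
are farthest away — 1:1:3 (0.087), 3:1:2 (0.083) and 1:1:1 (0.072), about
three mode widths (sd 0.025) — rather than on d_min-adjacent anchors such
as 3:3:2/2:2:1, where a 0.025-wide mode is inherently ambiguous between
two components.  Seeds for recovery studies are drawn from the
ground-truth prior itself (stationary initialization): five
protocol-limited iterations cannot traverse the full inner triangle from a
uniform cold start (~27% of chains fall short, biasing weights toward
path-adjacent categories), and that transient is a property of the
experiment's burn-in, not of the estimator being calibrated.  Default
simulations elsewhere keep uniform seeds.

The convergence (transmission-error) study uses the posterior-mean regime
with `sigma_s` = `sigma_prior` = 0.025, giving a posterior shrink factor of
1/2 per iteration, so the expected error decays geometrically through the
fifth iteration and the non-increase assertion sits far above Monte-Carlo
noise at 300 trials.

### What passing the synthetic tests does not show

The generator has no tempo drift, no lapses or double taps, no metrical
accent structure, no participant heterogeneity beyond independent rng
streams, and misses are independent per tap.  Passing therefore validates
the *pipeline* (geometry, matching, validity accounting, KDE, constrained
EM, statistics) under the stated noise model; it says nothing about how
human priors look or how robust the pipeline is to structured artifacts
(e.g. sensor dropouts or off-beat tapping).

## Prior estimation

Each completed trial contributes one Gaussian kernel with the empirical
mean and covariance (ddof = 1) of its fifth-iteration repetition points,
regularized as Σ′ = Σ + (γ/period)² I with γ = 15 ms.  The source text
adds "γ = 15 ms" to a covariance, a dimensional mismatch; treating γ as a
standard deviation is the default here, with γ-as-variance behind a flag.
Kernels are evaluated at bin centres over the *full* triangle (bin 0.006;
0.003 for display), without boundary truncation or reflection, and the
average over trials is renormalized to sum to one (to 1e−12).  The
uniform reference U lives on the inner-region bins; P′ = P/U is the
density-relative-to-uniform, and display clipping (at 5) never alters the
underlying probabilities.

## Constrained mixture

EM is initialized at the anchors with covariance (d_min/4)² I and uniform
weights.  After each M-step: means are projected onto the closed ball of
radius d_min/2 around their anchor; covariance eigenvalues are truncated
at d_min/2 and clamped to aspect bounds A = 1/5 (eigenvectors preserved;
both projections are idempotent); a component with vanishing
responsibility is reset to its anchor.  Convergence is an absolute change
below 1e−6 in the mean log-likelihood; non-convergence returns the last
iterate with `converged_ = False` and a warning.  The prose bound
|λ| < d_min conflicts with the printed truncation at d_min/2; the printed
formula wins.  The model is fitted to per-trial mean points (one point
per trial), matching the KDE's one-kernel-per-trial weighting.

Class weights average the component weights within each cyclic class
(isochrony keeps its single weight), so class weights do not sum to one.
The categorical-perception predictor raises weights to γ = 7 and triples
the isochrony weight *before* exponentiation (so the effective boost is
3⁷; the order of operations is ambiguous in the source and switchable via
`boost_before_exponent`).  Ties go to the component with the nearer mean.

## Statistics: nulls and calibration

All resampling operates at the trial level, with sample (ddof = 1)
standard deviations, explicit Bonferroni factors, and seeds recorded in
results.  JSD is base-2 (bits) with 0·log 0 = 0; bins whose mixture
underflows below double precision are dropped (their true contribution is
< 1e−300).  Null KDEs inside resampling loops bin the points and convolve
with the regularizer-only kernel — numerically the same kernel, evaluated
once per grid — while observed statistics always use the exact per-trial
kernels.

- **Split-half group test**: 95% CIs and the difference statistic D come
  from bootstrap split halves; the p-value ranks the mean cross-group
  half-JSD within both within-group null distributions (significant only
  against both).  Because the within-group halves are complementary,
  their deviations from the pool mean are anti-correlated and the null
  JSD is roughly twice that of independent halves: the procedure is
  conservative by construction (empirical type-I ≈ 0 at α = 0.05).  It is
  implemented as printed; rejections it does produce are trustworthy, but
  it is not an exact test.  For identical or overlapping trial sets D is
  negative (shared trials shrink the cross term), again conservative.
- **Peakiness**: top-33%-of-inner-bins mass and peak-to-mean density
  ratio, both computed over inner-region bins.  The null draws N points
  uniformly on the inner region (N = trials used) with one
  regularizer-width kernel each — the inner region because that is the
  support of every pipeline output, making null and observed exchangeable
  under the no-structure hypothesis.
- **Integer-ratio overlap**: (1) mean minimal distance vs. 22-point sets
  uniform on the full triangle — a qualitative control that is strongly
  anti-conservative for inner-region data (Ω₂₂ covers the inner region
  better than random full-triangle sets); (2) the spacing-matched null
  (each point jittered within a disk of radius d_min/2 around its
  anchor), the variant to use for inference — approximately calibrated,
  with a small residual anti-conservatism (~0.08 at nominal 0.05) from
  the minimum over jittered candidates being biased low; (3) the
  integerness score, JSD to the 1/22-atom indicator distribution vs.
  mean-randomized refits of an unconstrained 22-component mixture.
- **Bias test**: ratio of mean squared Mahalanobis distances (to the
  empirical mean vs. to the anchor); affine-invariant; the null resamples
  Gaussian clouds with the empirical covariance centred at the anchor.
  Empirically calibrated.
- **Reliability**: Pearson correlation between half-dataset prior grids,
  Spearman–Brown corrected (r* = 2r/(1+r)), averaged over random splits.
- **MDS**: metric stress majorization (SMACOF) from the classical-scaling
  solution, hence deterministic; orientation is arbitrary and all
  downstream uses are rotation/reflection invariant.  PCA on prior grids
  centres but does not scale features (shared units); signs arbitrary.
  RIN correlation CIs rank-transform both variables to normal scores and
  apply the Fisher z interval.

## Problem sizes

The test suite and the acceptance script size their simulations for a
single CPU: 400 trials for weight recovery, 300 for the group-level
analysis, 200 replicates at 100 bootstrap/null samples for type-I
calibration, six groups of 150 trials for the graded-3:3:2 MDS study
(gradient spanning class weights 0–0.15, the range real groups exhibit;
smaller gradients drown in the ±0.02 weight-estimation noise at this
group size).

## Known limitations

- The persistent-target regime sidesteps, rather than resolves, the
  tension between posterior-sampling dynamics and the matching window;
  modelling graded within-iteration drift would be more faithful but adds
  parameters the analysis cannot identify.
- Edge effects of the KDE are handled by renormalization only; a mode
  hugging the inner boundary loses some kernel mass outward.
- The split-half group test's conservatism (above) means its absence of
  significance is weak evidence; the pairwise-distance permutation test
  is the calibrated alternative for group contrasts.
- Onset extraction assumes a quiet recording with impulsive taps; it has
  no echo suppression or adaptive thresholding beyond the per-window
  relative threshold.
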