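# rhythmprior

Estimation of rhythm priors from iterated reproduction ("telephone-game")
tapping experiments, for auditory psychophysics and computational
cognitive science.

## The problem

A three-interval rhythm is a repeating cycle of inter-onset intervals
(s₁, s₂, s₃) with fixed total duration s = s₁ + s₂ + s₃ (2,000 ms by
default).  Normalizing by s maps every such rhythm to a point on the
2-simplex, drawn as an equilateral triangle with vertices P₁ = (0, 0),
P₂ = (1, 0), P₃ = (½, √3⁄2).

In an iterated-reproduction experiment a participant synchronizes finger
taps to ten repetitions of a rhythm; the averaged reproduction (r₁, r₂, r₃)
becomes the stimulus of the next iteration, five iterations per trial,
starting from a random seed.  Under Bayesian accounts of perception the
chain converges toward the listener's **prior** over rhythms, so the
distribution of fifth-iteration reproductions across many trials is an
estimate of that prior.  Empirically these priors are dominated by discrete
modes at small-integer-ratio rhythms (1:1:1, 1:1:2, 3:3:2, …), with
weights that differ across listener groups.

`rhythmprior` implements the full analysis pipeline:

- **Geometry** (`rhythm_space`): the simplex embedding, the 22 unique
  integer ratios over {1, 2, 3} (Ω₂₂), their 8 cyclic-rotation classes
  (Ω₈), the 7:2:3 extension (Ω₂₅), and uniform seed sampling from the
  inner region of producible rhythms (all intervals > 300 ms).
- **Tap preprocessing** (`tap_preprocess`): onset extraction from audio
  (1.45%-of-peak-power threshold per 15 s window, 80 ms merge gap),
  nearest-click matching with a single mean-asynchrony estimate m and a
  ±150 ms window around the perceptual centre, cycle-relative averaging
  with imputation, and validity rules (≥ 3 taps per position out of 10,
  no interval below 285 ms).
- **Protocol** (`reproduction`): the seed → reproduce → feed-back loop
  with the invalid-iteration bookkeeping (invalid ⇒ stimulus repeats;
  three invalids ⇒ the trial stops).
- **Synthetic tapper** (`synthetic`): a generative Bayesian observer +
  motor model with a known ground-truth prior, used to validate the
  pipeline end-to-end.
- **Prior estimation** (`prior_estimation`): one Gaussian kernel per
  trial, N(μᵢ, Σᵢ + γ²I) with mean and covariance from the
  fifth-iteration repetitions (γ = 15 ms), averaged across trials on a
  0.006-unit triangle grid — exposed as the sklearn-style estimator
  `TrianglePriorKDE`.
- **Category model** (`category_model`): a Gaussian mixture
  Q(x) = Σᵢ wᵢ N(x; μᵢ, Cᵢ) with one component per integer ratio, fitted
  by EM under the constraints ‖μᵢ − μᵢ⁰‖ < ½d_min (anchoring), eigenvalue
  truncation λ′ = min(λ, ½d_min) and the aspect clamp
  A ≤ λ/(λ₁+λ₂) ≤ 1−A with A = 1/5 — the sklearn-style estimator
  `ConstrainedCategoryGMM` — plus per-class weights (averaged over cyclic
  permutations), explained variance, and the categorical-perception
  predictor Uᵢ(x) ∝ wᵢ^γ N(x; μᵢ, Cᵢ) with γ = 7 and a 3× isochrony boost.
- **Statistics** (`stats`): Jensen–Shannon divergence in bits, split-half
  bootstrap group comparisons, peakiness (top-33% mass and peak-to-uniform
  ratio), three integer-ratio overlap analyses, the Mahalanobis bias test,
  transmission error e = ‖s − r‖, tapping asynchrony metrics, split-half
  reliability with Spearman–Brown correction, and cyclic-permutation
  asymmetry.
- **Cross-group structure** (`dim_reduction`): metric MDS on the pairwise
  JSD matrix, PCA on gridded priors, and rank-based inverse-normal (RIN)
  correlation CIs.
- **IO / CLI** (`io`, `config`, `cli`): tap-record TSV round-trips, a flat
  key = value config with fast-tempo scaling, and a `rhythmprior` command
  with `simulate`, `preprocess`, `estimate-prior`, `fit-gmm`, `stats`,
  `compare`, `dimreduce`, `categorize` and `pipeline` subcommands.

## Worked example

Simulate 400 trials from an observer whose ground-truth prior has modes at
1:1:3, 3:1:2 and 1:1:1 with weights 0.5 / 0.3 / 0.2, then recover the
prior and the category weights:

```python
import numpy as np
from rhythmprior import fit_constrained_gmm, omega22, TrianglePriorKDE
from rhythmprior.pipeline import fifth_iteration_point_sets
from rhythmprior.synthetic import (
    recovery_params, sample_prior_seeds, simulate_dataset, three_mode_prior,
)
from rhythmprior.stats import peakiness, tapping_metrics

prior = three_mode_prior()          # modes at 1:1:3, 3:1:2, 1:1:1 (w = .5/.3/.2)
rng = np.random.default_rng(0)
trials = simulate_dataset(
    recovery_params(prior), 400, rng, seeds=sample_prior_seeds(prior, 400, rng)
)
kde = TrianglePriorKDE().fit(fifth_iteration_point_sets(trials))
model = fit_constrained_gmm(kde.trial_means_)

labels = omega22().member_labels()
top = np.argsort(model.weights_)[::-1][:3]
print("trials used:", kde.n_used_, "of", len(trials))
for k in top:
    print(f"  category {labels[k]}: weight {model.weights_[k]:.3f}")
mass, peak = peakiness(kde, np.random.default_rng(1), n_null=200)
print(f"top-33% mass: {100*mass.statistic:.1f}%  (p = {mass.p_value:.4f})")
print(f"peak/uniform: {peak.statistic:.1f}  (p = {peak.p_value:.4f})")
mean_a, sd_a = tapping_metrics(trials)
print(f"mean asynchrony: {mean_a:.1f} ms, sd {sd_a:.1f} ms")
```

Output:

```
trials used: 336 of 400
  category 113: weight 0.507
  category 312: weight 0.271
  category 111: weight 0.181
top-33% mass: 97.5%  (p = 0.0050)
peak/uniform: 14.6  (p = 0.0050)
mean asynchrony: -45.8 ms, sd 74.8 ms
```

The fitted component weights recover the generative weights; 64 of the 400
trials were dropped by the protocol's validity rules (missing taps,
out-of-region reproductions).  The peakiness statistics show the estimated
prior is far from uniform (the p-values are the resolution limit of 200
null samples), and the tapping shows the anticipatory negative mean
asynchrony built into the motor model.

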