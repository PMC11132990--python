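"""Synthetic Bayesian tapper: a generative observer + motor model.

The observer carries a ground-truth prior over the rhythm triangle
(a mixture of isotropic Gaussian components, or a flat prior).  On each
iteration it receives the stimulus corrupted by isotropic sensory noise
(sd ``sigma_s`` in triangle units), forms the posterior over rhythms by
grid quadrature, and reproduces either the posterior mean (default;
deterministic attractor dynamics that converge over a few iterations) or a
posterior sample (``sample_posterior=True``; the iterated chain then has
the prior as its stationary distribution, which is the regime used for
parameter-recovery studies).

The motor stage taps each click of the stimulus sequence: tap times follow
the *estimated* intervals, perturbed per interval by motor noise
(sd ``sigma_m_ms``) and shifted per tap by an anticipatory asynchrony
(mean ``mu_a_ms``, typically negative; sd ``sigma_a_ms``).  Taps are
deleted independently with probability ``p_miss``.  Interval sums are not
renormalized — real tapping does not conserve the period, which is why the
analysis works with proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import rhythm_space as rs
from .prior_estimation import triangle_grid
from .reproduction import TrialRecord, run_group
from .tap_preprocess import REPETITIONS, OnsetStream, stimulus_onsets

__all__ = [
    "PriorComponent",
    "GroundTruthPrior",
    "ObserverParams",
    "recovery_params",
    "sample_prior_seeds",
    "flat_prior",
    "three_mode_prior",
    "default_prior",
    "BayesianTapper",
    "perceive",
    "produce_taps",
    "simulate_dataset",
]


@dataclass(frozen=True)
class PriorComponent:
    """One isotropic Gaussian mode of the ground-truth prior."""

    proportions: tuple[float, float, float]
    weight: float
    sd: float = 0.025  # triangle units

    @property
    def point(self) -> np.ndarray:
        p = np.asarray(self.proportions, dtype=float)
        return np.asarray(rs.project(p / p.sum()))


@dataclass(frozen=True)
class GroundTruthPrior:
    """Mixture prior on the triangle; no components means flat."""

    components: tuple[PriorComponent, ...] = ()

    @property
    def is_flat(self) -> bool:
        return len(self.components) == 0

    def density(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        if self.is_flat:
            return np.ones(len(pts))
        total = sum(c.weight for c in self.components)
        dens = np.zeros(len(pts))
        for c in self.components:
            d2 = np.sum((pts - c.point) ** 2, axis=1)
            dens += (
                c.weight
                / total
                * np.exp(-0.5 * d2 / c.sd**2)
                / (2.0 * np.pi * c.sd**2)
            )
        return dens

    def grid_density(self, bin_width: float = 0.006) -> np.ndarray:
        """Ground-truth prior discretized on the analysis grid (sums to 1)."""
        grid = triangle_grid(bin_width)
        d = self.density(grid.centers)
        return d / d.sum()


def flat_prior() -> GroundTruthPrior:
    return GroundTruthPrior()


def three_mode_prior(
    ratios=((1, 1, 3), (3, 1, 2), (1, 1, 1)),
    weights=(0.5, 0.3, 0.2),
    sd: float = 0.025,
) -> GroundTruthPrior:
    """Ground-truth prior with modes at three integer-ratio rhythms.

    The default anchors are the three categories whose nearest neighbours
    within the 22-ratio set are farthest away (1:1:3, 3:1:2 and 1:1:1, at
    0.087, 0.083 and 0.072 triangle units, about 3 mode widths): mixture
    weights are only recoverable when modes are identifiable, i.e. narrow
    relative to the anchor spacing.
    """
    comps = tuple(
        PriorComponent(tuple(float(x) / sum(r) for x in r), w, sd)
        for r, w in zip(ratios, weights)
    )
    return GroundTruthPrior(comps)


def default_prior() -> GroundTruthPrior:
    """A multi-mode prior loosely shaped like a Western listener's:
    strong simple-ratio modes, moderate 6/8 and 3:3:2 modes, plus a broad
    background component providing realistic diffuse mass."""
    spec = [
        ((1, 1, 1), 0.16, 0.025),
        ((1, 1, 2), 0.07, 0.025),
        ((1, 2, 1), 0.07, 0.025),
        ((2, 1, 1), 0.07, 0.025),
        ((1, 2, 2), 0.05, 0.025),
        ((2, 1, 2), 0.05, 0.025),
        ((2, 2, 1), 0.05, 0.025),
        ((1, 2, 3), 0.03, 0.025),
        ((2, 3, 1), 0.03, 0.025),
        ((3, 1, 2), 0.03, 0.025),
        ((3, 3, 2), 0.04, 0.025),
        ((3, 2, 3), 0.04, 0.025),
        ((2, 3, 3), 0.04, 0.025),
        ((1, 1, 1), 0.27, 0.15),  # broad background centred at isochrony
    ]
    comps = tuple(
        PriorComponent(tuple(float(x) / sum(r) for x in r), w, sd)
        for r, w, sd in spec
    )
    return GroundTruthPrior(comps)


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of the generative observer + motor model.

    sigma_s : sensory noise sd, triangle units.
    sigma_m_ms : per-interval motor noise sd, ms.
    mu_a_ms, sigma_a_ms : per-tap asynchrony mean and sd, ms (negative mean
        models anticipatory tapping).
    p_miss : independent per-tap deletion probability.
    sample_posterior : reproduce a posterior sample instead of the mean.
    posterior_bin : grid resolution for posterior quadrature.
    persistent_target : categorical-percept persistence — the observer
        samples its percept from the posterior once, on the first iteration
        of a trial, and production then drifts toward that target in steps
        of at most ``max_step`` triangle units per iteration.  Synchronized
        tapping cannot move arbitrarily far from the stimulus within one
        iteration (the matching window discards such taps), so this is the
        regime in which the chain's fifth-iteration category frequencies
        reproduce the ground-truth mixture weights.
    max_step : per-iteration production drift bound, triangle units.
    start_after_longest : drop first-cycle taps before the onset that
        follows the longest stimulus interval (models hearing that onset as
        the pattern's beginning).
    """

    prior: GroundTruthPrior = field(default_factory=default_prior)
    sigma_s: float = 0.04
    sigma_m_ms: float = 10.0
    mu_a_ms: float = -50.0
    sigma_a_ms: float = 25.0
    p_miss: float = 0.05
    sample_posterior: bool = False
    posterior_bin: float = 0.006
    persistent_target: bool = False
    max_step: float = 0.07
    start_after_longest: bool = False


def sample_prior_seeds(
    prior: GroundTruthPrior,
    n: int,
    rng: np.random.Generator,
    period: float = 2000.0,
    min_interval: float = 300.0,
) -> list[rs.IntervalPattern]:
    """Seed rhythms drawn from the ground-truth prior (inner region only).

    Rejection-samples mixture draws until all proportions exceed the seed
    floor.  Used by recovery studies to start chains in the stationary
    regime: weight recovery calibrates the estimator on the converged
    state, whereas uniform cold-start seeds add a burn-in transient that
    five protocol-limited iterations cannot always traverse.
    """
    if prior.is_flat:
        return [rs.sample_seed(rng, period, min_interval) for _ in range(n)]
    f = min_interval / period
    weights = np.array([c.weight for c in prior.components])
    weights = weights / weights.sum()
    seeds: list[rs.IntervalPattern] = []
    while len(seeds) < n:
        c = prior.components[rng.choice(len(weights), p=weights)]
        point = c.point + rng.normal(0.0, c.sd, 2)
        props = rs.barycentric(point)
        if np.all(props > f):
            seeds.append(rs.IntervalPattern.from_proportions(props, period))
    return seeds


def recovery_params(prior: GroundTruthPrior, **overrides) -> ObserverParams:
    """Observer configuration for parameter-recovery studies.

    A single, effectively uninformative observation per trial (large
    sensory noise) makes the sampled percept a draw from the ground-truth
    prior itself, and drift-limited production carries the chain there
    within a trial's five iterations.
    """
    defaults = dict(
        prior=prior,
        sigma_s=1.0,
        sample_posterior=True,
        persistent_target=True,
        max_step=0.07,
    )
    defaults.update(overrides)
    return ObserverParams(**defaults)


def perceive(
    stimulus_point: np.ndarray,
    params: ObserverParams,
    rng: np.random.Generator,
    _cache: dict | None = None,
) -> np.ndarray:
    """Internal estimate of the stimulus rhythm.

    The observation is the stimulus plus isotropic Gaussian noise; the
    posterior over triangle locations is computed by quadrature on the
    analysis grid and summarized by its mean (or a sample, with
    within-bin jitter, when ``sample_posterior``).
    """
    stim = np.asarray(stimulus_point, dtype=float)
    if params.sigma_s == 0.0:
        return stim.copy()
    obs = stim + rng.normal(0.0, params.sigma_s, size=2)
    if _cache is not None and "grid" in _cache:
        grid, log_prior = _cache["grid"], _cache["log_prior"]
    else:
        grid = triangle_grid(params.posterior_bin)
        with np.errstate(divide="ignore"):
            log_prior = np.log(params.prior.density(grid.centers))
        if _cache is not None:
            _cache["grid"], _cache["log_prior"] = grid, log_prior
    d2 = np.sum((grid.centers - obs) ** 2, axis=1)
    log_post = log_prior - 0.5 * d2 / params.sigma_s**2
    log_post -= log_post.max()
    post = np.exp(log_post)
    post /= post.sum()
    if params.sample_posterior:
        idx = rng.choice(grid.n_bins, p=post)
        jitter = rng.uniform(-0.5, 0.5, size=2) * grid.bin_width
        return grid.centers[idx] + jitter
    return post @ grid.centers


def produce_taps(
    stimulus: rs.IntervalPattern,
    estimate_proportions: np.ndarray,
    params: ObserverParams,
    rng: np.random.Generator,
    repetitions: int = REPETITIONS,
) -> OnsetStream:
    """Tap onsets for one iteration, following the internal estimate."""
    onsets = stimulus_onsets(stimulus, repetitions)
    est = np.asarray(estimate_proportions, dtype=float) * stimulus.period
    taps = []
    for c in range(repetitions):
        start = onsets[3 * c]
        intervals = est + rng.normal(0.0, params.sigma_m_ms, size=3)
        offsets = np.array([0.0, intervals[0], intervals[0] + intervals[1]])
        for k in range(3):
            t = start + offsets[k] + rng.normal(params.mu_a_ms, params.sigma_a_ms)
            if rng.random() >= params.p_miss:
                taps.append(t)
    # closing onset of the sequence
    t = onsets[-1] + rng.normal(params.mu_a_ms, params.sigma_a_ms)
    if rng.random() >= params.p_miss:
        taps.append(t)
    taps = np.asarray(taps)
    if params.start_after_longest and len(taps):
        target_pos = (int(np.argmax(stimulus.intervals)) + 1) % 3
        taps = taps[taps >= onsets[target_pos] + params.mu_a_ms - 4 * params.sigma_a_ms]
    return OnsetStream(stimulus_onsets=onsets, response_onsets=np.sort(taps))


class BayesianTapper:
    """Responder for :func:`rhythmprior.reproduction.run_trial`.

    One instance per trial: in ``persistent_target`` mode the sampled
    percept is kept for the remainder of the trial.
    """

    def __init__(self, params: ObserverParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self._cache: dict = {}
        self._target: np.ndarray | None = None

    def _estimate(self, point: np.ndarray) -> np.ndarray:
        p = self.params
        if not p.persistent_target:
            return perceive(point, p, self.rng, self._cache)
        if self._target is None:
            self._target = perceive(point, p, self.rng, self._cache)
        delta = self._target - point
        dist = float(np.hypot(delta[0], delta[1]))
        if dist <= p.max_step:
            return self._target.copy()
        return point + delta * (p.max_step / dist)

    def __call__(self, stimulus: rs.IntervalPattern) -> OnsetStream:
        point = np.asarray(stimulus.point())
        estimate = self._estimate(point)
        est_props = rs.unproject(estimate, tol=1e-6)
        est_props = np.clip(est_props, 1e-6, None)
        est_props /= est_props.sum()
        return produce_taps(stimulus, est_props, self.params, self.rng)


def simulate_dataset(
    params: ObserverParams,
    n_trials: int,
    rng: np.random.Generator,
    period: float = 2000.0,
    group_id: str = "sim",
    n_participants: int = 20,
    **group_kwargs,
) -> list[TrialRecord]:
    """Full iterated-reproduction dataset from the generative model."""
    shared_cache: dict = {}

    def factory(pid: str, trial_rng: np.random.Generator):
        tapper = BayesianTapper(params, trial_rng)
        tapper._cache = shared_cache
        return tapper

    return run_group(
        n_trials,
        factory,
        rng,
        group_id=group_id,
        n_participants=n_participants,
        period=period,
        **group_kwargs,
    )
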