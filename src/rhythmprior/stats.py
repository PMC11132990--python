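"""Hypothesis tests and summary statistics for rhythm priors.

Covers Jensen–Shannon divergence between binned priors (bits), split-half
bootstrap comparison of two groups, the discrete-mode ("peakiness")
statistics, the three integer-ratio overlap analyses, the category bias
test, transmission error, tapping asynchrony metrics, split-half
reliability with Spearman–Brown correction, cyclic-permutation asymmetry
and group weight comparisons.

All resampling operates at the trial level and is reproducible for a given
rng; results carry the seed that produced them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import rel_entr

from . import rhythm_space as rs
from .prior_estimation import (
    DiscretePrior,
    TriangleGrid,
    TrianglePriorKDE,
    density_from_histogram,
    triangle_grid,
)
from .reproduction import TrialRecord

__all__ = [
    "BootstrapResult",
    "jsd",
    "split_half_group_test",
    "peakiness",
    "integer_overlap",
    "bias_test",
    "transmission_error",
    "tapping_metrics",
    "split_half_reliability",
    "permutation_asymmetry",
    "first_tap_after_long_fraction",
    "weight_comparison",
    "pairwise_distance_permutation",
    "cohens_d",
]


@dataclass
class BootstrapResult:
    """A resampling-based test result (statistic, null, p, effect size)."""

    statistic: float
    p_value: float
    null: np.ndarray | None = None
    effect_size: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with the pooled (ddof=1) standard deviation."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / pooled)


# ---------------------------------------------------------------- JSD


def _kl_bits(p: np.ndarray, m: np.ndarray) -> np.ndarray:
    # rel_entr handles 0 log 0; additionally guard bins whose mixture
    # underflows to exactly zero while p is still subnormal (~1e-324):
    # their true contribution is below double precision.
    terms = rel_entr(p, m)
    terms[~np.isfinite(terms)] = 0.0
    return terms.sum(axis=-1) / np.log(2.0)


def jsd(p, q) -> float:
    """Jensen–Shannon divergence in bits; 0*log(0) treated as 0."""
    if isinstance(p, DiscretePrior) and isinstance(q, DiscretePrior):
        if not p.same_grid(q):
            raise ValueError("priors live on different grids")
        p, q = p.p, q.p
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions have mismatched shapes")
    m = 0.5 * (p + q)
    return float(0.5 * _kl_bits(p, m) + 0.5 * _kl_bits(q, m))


def _jsd_rows(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Row-wise JSD for matched (n, B) probability matrices."""
    M = 0.5 * (P + Q)
    return 0.5 * _kl_bits(P, M) + 0.5 * _kl_bits(Q, M)


# --------------------------------------------- split-half group test


def _half_means(
    grids: np.ndarray, rng: np.random.Generator, n_boot: int
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap split halves of per-trial kernel grids -> half-mean KDEs."""
    n = grids.shape[0]
    half = n // 2
    first = np.empty((n_boot, grids.shape[1]))
    second = np.empty((n_boot, grids.shape[1]))
    for j in range(n_boot):
        perm = rng.permutation(n)
        a = grids[perm[:half]].mean(axis=0)
        b = grids[perm[half:]].mean(axis=0)
        first[j] = a / a.sum()
        second[j] = b / b.sum()
    return first, second


def split_half_group_test(
    trials_a,
    trials_b,
    rng: np.random.Generator,
    n_boot: int = 1000,
    bin_width: float = 0.006,
    f: float = 0.15,
    gamma_ms: float = 15.0,
    period: float = 2000.0,
) -> BootstrapResult:
    """Bootstrap test of whether two groups' priors differ.

    For each of ``n_boot`` random split halves of each group's trials, the
    cross-group half JSD is compared with both within-group half JSDs.
    The observed statistic (the mean cross-group half JSD) is ranked within
    each within-group null distribution, and the reported p-value is the
    larger of the two rank p-values: the distance must be significant with
    respect to *both* within-group nulls.  The reported difference D
    averages the two contrasts, with a 95% percentile CI.

    ``trials_a``/``trials_b`` are either fitted :class:`TrianglePriorKDE`
    objects or sequences of per-trial repetition point arrays.
    """

    def _grids(t):
        if isinstance(t, TrianglePriorKDE):
            return t.trial_grids_
        kde = TrianglePriorKDE(
            bin_width=bin_width, f=f, gamma_ms=gamma_ms, period_ms=period
        ).fit(t)
        return kde.trial_grids_

    ga, gb = _grids(trials_a), _grids(trials_b)
    if ga.shape[0] < 4 or gb.shape[0] < 4:
        raise ValueError("need at least 4 usable trials per group")
    a1, a2 = _half_means(ga, rng, n_boot)
    b1, b2 = _half_means(gb, rng, n_boot)
    cross = _jsd_rows(a1, b1)
    within_a = _jsd_rows(a1, a2)
    within_b = _jsd_rows(b1, b2)
    d = 0.5 * ((cross - within_a) + (cross - within_b))
    mean_cross = cross.mean()
    p_a = (1 + np.sum(within_a >= mean_cross)) / (n_boot + 1)
    p_b = (1 + np.sum(within_b >= mean_cross)) / (n_boot + 1)
    within_all = np.concatenate([within_a, within_b])
    eff = (cross.mean() - within_all.mean()) / np.sqrt(
        0.5 * (np.var(cross, ddof=1) + np.var(within_all, ddof=1))
    )
    lo, hi = np.percentile(d, [2.5, 97.5])
    return BootstrapResult(
        statistic=float(d.mean()),
        p_value=float(max(p_a, p_b)),
        null=within_all,
        effect_size=float(eff),
        ci_low=float(lo),
        ci_high=float(hi),
        extra={"mean_cross_jsd": float(cross.mean())},
    )


# ----------------------------------------------------------- peakiness


def _inner_stats(
    p: np.ndarray, inner: np.ndarray, top_frac: float
) -> tuple[float, float]:
    pin = p[inner]
    total = pin.sum()
    k = int(np.ceil(top_frac * len(pin)))
    top = np.sort(pin)[::-1][:k].sum()
    mass_frac = top / total
    peak_ratio = pin.max() / (total / len(pin))
    return float(mass_frac), float(peak_ratio)


def peakiness(
    kde: TrianglePriorKDE,
    rng: np.random.Generator,
    n_null: int = 1000,
    top_frac: float = 0.33,
) -> tuple[BootstrapResult, BootstrapResult]:
    """Discrete-mode statistics with a uniform-sampling null.

    Returns (top-fraction mass, peak-to-uniform ratio), each with a null
    built from N points sampled uniformly on the inner region (N = trials
    used by the KDE), one regularizer-width kernel per point.  Sampling the
    null on the inner region makes it exchangeable with the pipeline's
    observed output (whose trials all survive the inner-region exclusion)
    under the no-structure hypothesis.
    """
    prior = kde.prior_
    inner = prior.inner_mask
    obs_mass, obs_peak = _inner_stats(prior.p, inner, top_frac)
    null_mass = np.empty(n_null)
    null_peak = np.empty(n_null)
    grid = prior.grid
    for j in range(n_null):
        pts = rs.sample_inner_points(rng, kde.n_used_, prior.f)
        p = density_from_histogram(pts, grid, kde.gamma_ms, kde.period_ms)
        null_mass[j], null_peak[j] = _inner_stats(p, inner, top_frac)
    p_mass = (1 + np.sum(null_mass >= obs_mass)) / (n_null + 1)
    p_peak = (1 + np.sum(null_peak >= obs_peak)) / (n_null + 1)

    def _z(obs, null):
        sd = np.std(null, ddof=1)
        return float((obs - null.mean()) / sd) if sd > 0 else float("nan")

    return (
        BootstrapResult(obs_mass, float(p_mass), null_mass, effect_size=_z(obs_mass, null_mass)),
        BootstrapResult(obs_peak, float(p_peak), null_peak, effect_size=_z(obs_peak, null_peak)),
    )


# ------------------------------------------------- integer-ratio overlap


def _indicator_distribution(
    omega: rs.IntegerRatioSet, grid: TriangleGrid
) -> np.ndarray:
    idx = grid.bin_index_of(omega.points)
    p = np.zeros(grid.n_bins)
    np.add.at(p, idx[idx >= 0], 1.0)
    return p / p.sum()


def integer_overlap(
    points: np.ndarray,
    omega: rs.IntegerRatioSet,
    rng: np.random.Generator,
    variant: str = "uniform-null",
    n_null: int = 1000,
    prior: DiscretePrior | None = None,
    gamma_ms: float = 15.0,
    period: float = 2000.0,
) -> BootstrapResult:
    """Overlap of fifth-iteration reproductions with integer ratios.

    variants:
      ``uniform-null`` — observed mean minimal distance to the projected
        ratio set vs. null sets of the same size sampled uniformly from the
        full triangle;
      ``spaced-null`` — null sets with each point jittered uniformly within
        a disk of radius d_min/2 around its ratio anchor (spacing-matched);
      ``integerness-jsd`` — JSD between the KDE of the points and the
        normalized indicator distribution of the ratio set, vs. a null from
        an unconstrained mixture refit with randomized component means.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) == 0:
        raise ValueError("no points supplied")
    anchors = omega.points
    K = len(anchors)
    if variant in ("uniform-null", "spaced-null"):
        obs = float(np.mean(rs.min_distances_to_points(pts, anchors)))
        null = np.empty(n_null)
        for j in range(n_null):
            if variant == "uniform-null":
                null_set = rs.sample_triangle_points(rng, K)
            else:
                radius = 0.5 * rs.min_pairwise_distance(omega)
                r = radius * np.sqrt(rng.random(K))
                theta = rng.uniform(0.0, 2.0 * np.pi, K)
                null_set = anchors + np.column_stack(
                    [r * np.cos(theta), r * np.sin(theta)]
                )
            null[j] = np.mean(rs.min_distances_to_points(pts, null_set))
        p = (1 + np.sum(null <= obs)) / (n_null + 1)
        return BootstrapResult(obs, float(p), null)
    if variant != "integerness-jsd":
        raise ValueError(f"unknown variant {variant!r}")
    from sklearn.mixture import GaussianMixture

    grid = prior.grid if prior is not None else triangle_grid()
    indicator = _indicator_distribution(omega, grid)
    if prior is not None:
        p_obs = prior.p
    else:
        p_obs = density_from_histogram(pts, grid, gamma_ms, period)
    obs = jsd(p_obs, indicator)
    k_fit = min(K, len(pts))
    gm = GaussianMixture(
        n_components=k_fit,
        covariance_type="full",
        reg_covar=1e-6,
        random_state=int(rng.integers(2**31)),
        n_init=1,
    ).fit(pts)
    null = np.empty(n_null)
    for j in range(n_null):
        means = rs.sample_triangle_points(rng, k_fit)
        comp = rng.choice(k_fit, size=len(pts), p=gm.weights_)
        sim = means[comp] + np.einsum(
            "nij,nj->ni",
            np.linalg.cholesky(gm.covariances_)[comp],
            rng.standard_normal((len(pts), 2)),
        )
        null[j] = jsd(density_from_histogram(sim, grid, gamma_ms, period), indicator)
    p = (1 + np.sum(null <= obs)) / (n_null + 1)
    return BootstrapResult(obs, float(p), null)


# ------------------------------------------------------------ bias test


def _mahalanobis_ratio(points: np.ndarray, anchor: np.ndarray) -> float:
    mean = points.mean(axis=0)
    cov = np.cov(points.T, ddof=1)
    if np.linalg.matrix_rank(cov) < 2:
        import warnings

        warnings.warn("singular covariance in bias test; regularizing")
        cov = cov + 1e-12 * np.eye(2)
    inv = np.linalg.inv(cov)
    dm = points - mean
    da = points - anchor
    num = np.mean(np.einsum("ni,ij,nj->n", dm, inv, dm))
    den = np.mean(np.einsum("ni,ij,nj->n", da, inv, da))
    return float(num / den)


def bias_test(
    points: np.ndarray,
    anchor: np.ndarray,
    rng: np.random.Generator,
    n_null: int = 10000,
) -> BootstrapResult:
    """Is a category's component-mean cloud biased away from its anchor?

    The statistic is the ratio of the average squared Mahalanobis distance
    to the empirical mean over that to the integer-ratio anchor (<= 1;
    smaller means more bias).  The null resamples Gaussian clouds with the
    empirical covariance but mean at the anchor (zero bias).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 3:
        raise ValueError("need at least 3 group means")
    anchor = np.asarray(anchor, dtype=float)
    obs = _mahalanobis_ratio(pts, anchor)
    cov = np.cov(pts.T, ddof=1)
    chol = np.linalg.cholesky(cov + 1e-15 * np.eye(2))
    null = np.empty(n_null)
    for j in range(n_null):
        sim = anchor + rng.standard_normal((len(pts), 2)) @ chol.T
        null[j] = _mahalanobis_ratio(sim, anchor)
    p = (1 + np.sum(null <= obs)) / (n_null + 1)
    return BootstrapResult(obs, float(p), null)


# --------------------------------------------------- per-trial metrics


def transmission_error(trial: TrialRecord) -> np.ndarray:
    """Per-iteration error e = ||stimulus - response|| in ms (NaN invalid)."""
    out = np.full(5, np.nan)
    for it in trial.iterations:
        if it.record.valid and it.record.response is not None:
            diff = it.stimulus.intervals - it.record.response
            out[it.index - 1] = np.sqrt(np.sum(diff**2))
    return out


def tapping_metrics(trials: list[TrialRecord]) -> tuple[float, float]:
    """Mean and sd (ddof=1) of tap asynchrony over all valid iterations."""
    asyn = []
    for trial in trials:
        for it in trial.iterations:
            if not it.record.valid:
                continue
            stim = it.stream.stimulus_onsets
            asyn.extend(r - stim[i] for i, r in it.record.matches)
    if not asyn:
        return float("nan"), float("nan")
    a = np.asarray(asyn)
    sd = float(np.std(a, ddof=1)) if len(a) > 1 else float("nan")
    return float(a.mean()), sd


def split_half_reliability(
    kde: TrianglePriorKDE, rng: np.random.Generator, n_splits: int = 20
) -> float:
    """Spearman–Brown-corrected split-half reliability of the prior grid."""
    grids = kde.trial_grids_
    n = grids.shape[0]
    if n < 2:
        raise ValueError("need at least 2 trials")
    half = n // 2
    rstars = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        a = grids[perm[:half]].mean(axis=0)
        b = grids[perm[half:]].mean(axis=0)
        if np.std(a) == 0 or np.std(b) == 0:
            continue
        r = np.corrcoef(a, b)[0, 1]
        rstars.append(2.0 * r / (1.0 + r))
    if not rstars:
        return float("nan")
    return float(np.mean(rstars))


# ------------------------------------------------ cyclic-permutation use


def permutation_asymmetry(
    proportions: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Fractions of responses whose longest interval is in position 1/2/3.

    Ties in the longest interval are excluded; the tie count is returned.
    """
    p = np.atleast_2d(np.asarray(proportions, dtype=float))
    longest = np.argmax(p, axis=1)
    mx = p[np.arange(len(p)), longest]
    ties = np.sum(np.isclose(p, mx[:, None]).sum(axis=1) > 1)
    keep = np.isclose(p, mx[:, None]).sum(axis=1) == 1
    counts = np.bincount(longest[keep], minlength=3)
    fractions = counts / counts.sum() if counts.sum() else np.full(3, np.nan)
    return fractions, int(ties)


def first_tap_after_long_fraction(trials: list[TrialRecord]) -> float:
    """Fraction of trials whose first detected tap falls on the onset
    immediately following the longest stimulus interval (first iteration;
    stimuli with tied longest intervals are skipped)."""
    hits, total = 0, 0
    for trial in trials:
        it = trial.iteration(1)
        if it is None or not it.record.matches:
            continue
        s = it.stimulus.intervals
        if np.isclose(s, s.max()).sum() > 1:
            continue
        target = (int(np.argmax(s)) + 1) % 3
        first_idx = min(i for i, _ in it.record.matches)
        total += 1
        if first_idx % 3 == target:
            hits += 1
    return hits / total if total else float("nan")


# ------------------------------------------------- group comparisons


def weight_comparison(
    a: np.ndarray,
    b: np.ndarray,
    rng: np.random.Generator,
    n_boot: int = 1000,
) -> BootstrapResult:
    """One-sided Wilcoxon rank-sum comparison of category weights (a > b),
    with Cohen's d, mean difference and a bootstrap CI on the difference."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    stat = sps.mannwhitneyu(a, b, alternative="greater")
    diffs = np.empty(n_boot)
    for j in range(n_boot):
        diffs[j] = rng.choice(a, len(a)).mean() - rng.choice(b, len(b)).mean()
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return BootstrapResult(
        statistic=float(a.mean() - b.mean()),
        p_value=float(stat.pvalue),
        effect_size=cohens_d(a, b),
        ci_low=float(lo),
        ci_high=float(hi),
        extra={"u_statistic": float(stat.statistic)},
    )


def pairwise_distance_permutation(
    dist: np.ndarray,
    idx_a,
    idx_b,
    rng: np.random.Generator,
    n_perm: int = 10000,
) -> BootstrapResult:
    """Are within-set-A pairwise distances smaller than within-set-B ones?

    Shuffled sets are sampled without replacement from the union of the two
    index sets; one-sided p for the observed difference (mean within-A
    minus mean within-B) being as small as or smaller than the null.
    """
    dist = np.asarray(dist, dtype=float)
    idx_a = list(idx_a)
    idx_b = list(idx_b)

    def mean_within(idx):
        sub = dist[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        return sub[iu].mean()

    obs = mean_within(idx_a) - mean_within(idx_b)
    union = np.array(idx_a + idx_b)
    null = np.empty(n_perm)
    for j in range(n_perm):
        perm = rng.permutation(union)
        null[j] = mean_within(perm[: len(idx_a)]) - mean_within(perm[len(idx_a) :])
    p = (1 + np.sum(null <= obs)) / (n_perm + 1)
    return BootstrapResult(float(obs), float(p), null)
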