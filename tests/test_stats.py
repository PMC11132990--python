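"""Divergences, bootstrap tests and summary statistics."""

import numpy as np
import pytest

from rhythmprior import rhythm_space as rs
from rhythmprior import stats as st
from rhythmprior.prior_estimation import TrianglePriorKDE, triangle_grid
from rhythmprior.reproduction import run_trial
from rhythmprior.rhythm_space import IntervalPattern
from rhythmprior.synthetic import (
    ObserverParams,
    flat_prior,
    recovery_params,
    simulate_dataset,
    three_mode_prior,
)
from rhythmprior.tap_preprocess import OnsetStream, stimulus_onsets


def jsd_oracle(p, q):
    """Direct per-bin summation oracle (base-2, 0 log 0 = 0)."""
    total = 0.0
    for pi, qi in zip(p, q):
        m = 0.5 * (pi + qi)
        if pi > 0:
            total += 0.5 * pi * np.log2(pi / m)
        if qi > 0:
            total += 0.5 * qi * np.log2(qi / m)
    return total


def mode_trials(centre_props, n_trials, sd=0.01, reps=10, seed=0):
    """Synthetic per-trial repetition point sets around one mode."""
    g = np.random.default_rng(seed)
    centre = np.asarray(rs.project(centre_props))
    out = []
    for _ in range(n_trials):
        mean = centre + g.normal(0, sd, 2)
        out.append(mean + g.normal(0, 0.003, size=(reps, 2)))
    return out


def uniform_trials(n_trials, seed, f=0.15, reps=10, sd=0.003):
    g = np.random.default_rng(seed)
    means = rs.sample_inner_points(g, n_trials, f)
    return [m + g.normal(0, sd, size=(reps, 2)) for m in means]


class TestJSD:
    def test_self_divergence_is_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert st.jsd(p, p) == 0.0

    def test_disjoint_supports_give_one_bit(self):
        assert st.jsd([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0, abs=1e-15)

    def test_matches_summation_oracle(self):
        p, q = np.array([0.5, 0.5]), np.array([0.9, 0.1])
        assert st.jsd(p, q) == pytest.approx(jsd_oracle(p, q), abs=1e-12)
        g = np.random.default_rng(0)
        a, b = g.dirichlet(np.ones(40)), g.dirichlet(np.ones(40))
        assert st.jsd(a, b) == pytest.approx(jsd_oracle(a, b), abs=1e-12)

    def test_grid_mismatch_raises(self):
        from rhythmprior.prior_estimation import DiscretePrior

        g6, g3 = triangle_grid(0.006), triangle_grid(0.003)
        a = DiscretePrior(grid=g6, p=np.full(g6.n_bins, 1 / g6.n_bins))
        b = DiscretePrior(grid=g3, p=np.full(g3.n_bins, 1 / g3.n_bins))
        with pytest.raises(ValueError):
            st.jsd(a, b)


class TestSplitHalfGroupTest:
    def test_identical_groups_not_significant(self):
        # literally identical trial lists: halves of A and B overlap, so
        # the cross JSD can only be smaller than the within JSD (D <= 0);
        # no spurious positive distance, never significant
        trials = uniform_trials(24, seed=1)
        res = st.split_half_group_test(
            trials, trials, np.random.default_rng(0), n_boot=200
        )
        assert res.p_value > 0.05
        assert res.statistic < 0.02

    def test_same_distribution_groups_not_significant(self):
        a = uniform_trials(24, seed=6)
        b = uniform_trials(24, seed=7)
        res = st.split_half_group_test(a, b, np.random.default_rng(0), n_boot=200)
        assert res.p_value > 0.05

    def test_separated_modes_detected(self):
        a = mode_trials((0.25, 0.25, 0.5), 100, seed=2)
        b = mode_trials((0.375, 0.375, 0.25), 100, seed=3)
        res = st.split_half_group_test(a, b, np.random.default_rng(0), n_boot=200)
        assert res.p_value <= 0.01
        assert res.statistic > 0.1

    def test_too_few_trials_rejected(self):
        t = uniform_trials(3, seed=4)
        with pytest.raises(ValueError):
            st.split_half_group_test(t, t, np.random.default_rng(0))


class TestPeakiness:
    def test_uniform_prior_statistics(self):
        # the uniform distribution itself: top-33% mass = 0.33, peak = 1
        grid = triangle_grid()
        inner = grid.inner_mask(0.15)
        p = inner / inner.sum()
        mass, peak = st._inner_stats(p, inner, 0.33)
        assert mass == pytest.approx(0.33, abs=0.01)
        assert peak == pytest.approx(1.0, abs=1e-12)

    def test_uniform_data_calibrates(self):
        kde = TrianglePriorKDE().fit(uniform_trials(60, seed=5))
        mass, peak = st.peakiness(kde, np.random.default_rng(0), n_null=200)
        assert mass.p_value > 0.05 and peak.p_value > 0.05

    def test_delta_prior_mass_near_one(self):
        kde = TrianglePriorKDE().fit(mode_trials((1 / 3, 1 / 3, 1 / 3), 40, sd=0.002))
        mass, peak = st.peakiness(kde, np.random.default_rng(0), n_null=50)
        assert mass.statistic > 0.95
        assert peak.statistic > 5.0


class TestIntegerOverlap:
    def test_points_on_ratios_are_maximally_close(self):
        omega = rs.omega22()
        res = st.integer_overlap(
            omega.points, omega, np.random.default_rng(0), n_null=100
        )
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 101)

    def test_spaced_null_respects_radius(self):
        omega = rs.omega22()
        g = np.random.default_rng(1)
        radius = 0.5 * rs.min_pairwise_distance(omega)
        # audit by reconstructing null sets exactly as the test draws them
        for _ in range(20):
            r = radius * np.sqrt(g.random(22))
            theta = g.uniform(0, 2 * np.pi, 22)
            null_set = omega.points + np.column_stack(
                [r * np.cos(theta), r * np.sin(theta)]
            )
            assert np.all(
                np.hypot(*(null_set - omega.points).T) <= radius + 1e-12
            )

    def test_integerness_jsd_detects_ratio_concentration(self):
        omega = rs.omega22()
        g = np.random.default_rng(2)
        near = omega.points[g.integers(0, 22, 300)] + g.normal(0, 0.008, (300, 2))
        res = st.integer_overlap(
            near, omega, np.random.default_rng(3), variant="integerness-jsd",
            n_null=60,
        )
        assert res.p_value < 0.05

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            st.integer_overlap(
                np.zeros((1, 2)), rs.omega22(), np.random.default_rng(0),
                variant="bogus",
            )


class TestBiasTest:
    def test_unbiased_cloud_not_significant(self):
        g = np.random.default_rng(0)
        anchor = np.array([0.5, 0.3])
        pts = anchor + g.normal(0, 0.01, (39, 2))
        res = st.bias_test(pts, anchor, np.random.default_rng(1), n_null=500)
        assert res.statistic <= 1.0
        assert res.p_value > 0.01

    def test_shifted_cloud_detected(self):
        g = np.random.default_rng(0)
        anchor = np.array([0.5, 0.3])
        pts = anchor + np.array([0.03, 0.0]) + g.normal(0, 0.01, (39, 2))
        res = st.bias_test(pts, anchor, np.random.default_rng(1), n_null=2000)
        assert res.p_value < 0.001

    def test_statistic_is_affine_invariant(self):
        g = np.random.default_rng(3)
        anchor = np.array([0.4, 0.25])
        pts = anchor + np.array([0.02, -0.01]) + g.normal(0, 0.01, (30, 2))
        A = np.array([[2.0, 0.7], [-0.3, 1.4]])
        ratio = st._mahalanobis_ratio(pts, anchor)
        ratio_t = st._mahalanobis_ratio(pts @ A.T, anchor @ A.T)
        assert ratio_t == pytest.approx(ratio, abs=1e-12)


class TestTransmissionAndTapping:
    def test_transmission_error_examples(self):
        stim = stimulus_onsets(IntervalPattern(600, 700, 700))

        def responder(pattern):
            s = stimulus_onsets(pattern)
            return OnsetStream(stimulus_onsets=s, response_onsets=s[:-1])

        trial = run_trial(IntervalPattern(600, 700, 700), responder)
        assert np.allclose(st.transmission_error(trial), 0.0)

    def test_transmission_error_hand_value(self):
        diff = np.array([600, 700, 700]) - np.array([610, 690, 700])
        assert np.sqrt(np.sum(diff**2)) == pytest.approx(np.sqrt(200))

    def test_tapping_metrics_round_trip(self):
        params = ObserverParams(
            prior=flat_prior(), sigma_s=0.0, sigma_m_ms=0.0,
            mu_a_ms=-50.0, sigma_a_ms=20.0, p_miss=0.0,
        )
        trials = simulate_dataset(params, 20, np.random.default_rng(4))
        mean, sd = st.tapping_metrics(trials)
        assert mean == pytest.approx(-50.0, abs=1.5)
        assert sd == pytest.approx(20.0, rel=0.06)

    def test_tapping_metrics_exact_taps(self):
        def responder(pattern):
            s = stimulus_onsets(pattern)
            return OnsetStream(stimulus_onsets=s, response_onsets=s[:-1])

        trial = run_trial(IntervalPattern(600, 700, 700), responder)
        mean, sd = st.tapping_metrics([trial])
        assert mean == 0.0 and sd == 0.0

    def test_tapping_metrics_two_tap_sample_sd(self):
        def responder(pattern):
            s = stimulus_onsets(pattern)
            return OnsetStream(
                stimulus_onsets=s, response_onsets=np.sort(s[:-1] + np.tile([10.0, -10.0], 15))
            )

        trial = run_trial(IntervalPattern(600, 700, 700), responder)
        mean, sd = st.tapping_metrics([trial])
        assert mean == pytest.approx(0.0, abs=1e-9)
        # sample (ddof=1) convention over the 150 retained taps: the
        # population value (10.0) would miss this by 3e-2
        expected = np.std(np.tile([10.0, -10.0], 75), ddof=1)
        assert sd == pytest.approx(expected, abs=1e-9)


class TestReliability:
    def test_identical_trials_give_unit_reliability(self):
        pts = np.tile(np.asarray(rs.project((1 / 3, 1 / 3, 1 / 3))), (10, 1))
        kde = TrianglePriorKDE().fit([pts] * 8)
        r = st.split_half_reliability(kde, np.random.default_rng(0), n_splits=5)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_reliability_grows_with_trials(self):
        rels = []
        for n in (8, 64):
            kde = TrianglePriorKDE().fit(uniform_trials(n, seed=n))
            rels.append(
                st.split_half_reliability(kde, np.random.default_rng(1), n_splits=10)
            )
        assert rels[1] > rels[0]

    def test_power_target_reliability(self, recovery_kde):
        """400 simulated trials exceed the 0.8 reliability power target."""
        r = st.split_half_reliability(recovery_kde, np.random.default_rng(2))
        assert r > 0.8


class TestPermutationAsymmetry:
    def test_symmetric_data(self):
        g = np.random.default_rng(0)
        props = g.dirichlet(np.ones(3), 6000)
        frac, ties = st.permutation_asymmetry(props)
        assert frac == pytest.approx([1 / 3] * 3, abs=0.03)
        assert frac.sum() == pytest.approx(1.0)

    def test_third_interval_longest(self):
        props = np.tile([0.25, 0.25, 0.5], (10, 1))
        frac, ties = st.permutation_asymmetry(props)
        assert frac.tolist() == [0.0, 0.0, 1.0]
        assert ties == 0

    def test_ties_are_excluded(self):
        props = np.array([[0.4, 0.4, 0.2], [0.2, 0.4, 0.4], [0.5, 0.3, 0.2]])
        frac, ties = st.permutation_asymmetry(props)
        assert ties == 2
        assert frac.tolist() == [1.0, 0.0, 0.0]


class TestWeightComparisons:
    def test_shifted_groups_detected(self):
        g = np.random.default_rng(0)
        a = 0.1 + g.normal(0, 0.01, 12)
        b = g.normal(0.0, 0.01, 12) + 0.07
        res = st.weight_comparison(a, b, np.random.default_rng(1))
        assert res.p_value < 0.01
        assert res.effect_size > 1.0
        assert res.ci_low < res.statistic < res.ci_high

    def test_identical_distributions_calibrate(self):
        g = np.random.default_rng(2)
        ps = []
        for _ in range(200):
            a, b = g.normal(size=10), g.normal(size=10)
            ps.append(
                st.weight_comparison(a, b, np.random.default_rng(0), n_boot=10).p_value
            )
        # one-sided p should be roughly uniform: mean near 0.5
        assert np.mean(ps) == pytest.approx(0.5, abs=0.08)

    def test_pairwise_distance_permutation(self):
        # two tight clusters of priors: within-A distances smaller
        g = np.random.default_rng(3)
        coords = np.concatenate([g.normal(0, 0.1, 6), g.normal(30, 5.0, 6)])
        D = np.abs(coords[:, None] - coords[None, :])
        res = st.pairwise_distance_permutation(
            D, range(6), range(6, 12), np.random.default_rng(4), n_perm=2000
        )
        assert res.p_value < 0.01
        # identical sets: p roughly uniform across permuted labels
        res0 = st.pairwise_distance_permutation(
            D[:6, :6][np.ix_(range(6), range(6))], range(3), range(3, 6),
            np.random.default_rng(5), n_perm=500,
        )
        assert 0.0 < res0.p_value <= 1.0
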