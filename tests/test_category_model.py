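"""Constrained category mixture: EM, weights, prediction, reference maps."""

import numpy as np
import pandas as pd
import pytest

from rhythmprior import rhythm_space as rs
from rhythmprior.category_model import (
    ConstrainedCategoryGMM,
    _clamp_covariance,
    _project_mean,
    build_reference_map,
    category_map_distance,
    category_weights,
    explained_variance,
    fit_constrained_gmm,
    predict_category,
)
from rhythmprior.prior_estimation import DiscretePrior, triangle_grid

OMEGA = rs.omega22()
LABELS = OMEGA.member_labels()


def cloud(ratio, n, sd, seed=0):
    centre = np.asarray(rs.project(np.array(ratio) / np.sum(ratio)))
    return centre + np.random.default_rng(seed).normal(0, sd, size=(n, 2))


class TestFit:
    def test_single_tight_cluster_takes_all_weight(self):
        pts = cloud((1, 1, 1), 300, 0.004)
        model = fit_constrained_gmm(pts)
        assert model.weights_[LABELS.index("111")] >= 0.99

    def test_three_cluster_weight_recovery(self):
        pts = np.vstack(
            [
                cloud((1, 1, 3), 250, 0.01, seed=1),
                cloud((3, 1, 2), 150, 0.01, seed=2),
                cloud((1, 1, 1), 100, 0.01, seed=3),
            ]
        )
        model = fit_constrained_gmm(pts)
        w = model.weights_
        assert w[LABELS.index("113")] == pytest.approx(0.5, abs=0.05)
        assert w[LABELS.index("312")] == pytest.approx(0.3, abs=0.05)
        assert w[LABELS.index("111")] == pytest.approx(0.2, abs=0.05)

    def test_responsibilities_match_hand_formula(self):
        # brute-force responsibility oracle on a small subset
        pts = cloud((1, 1, 1), 10, 0.02)
        model = fit_constrained_gmm(cloud((1, 1, 1), 100, 0.02))
        logp = model._component_log_pdf(pts)
        manual = np.zeros_like(logp)
        for k, (m, c) in enumerate(zip(model.means_, model.covariances_)):
            inv = np.linalg.inv(c)
            for i, x in enumerate(pts):
                d = x - m
                manual[i, k] = (
                    -0.5 * d @ inv @ d
                    - np.log(2 * np.pi)
                    - 0.5 * np.log(np.linalg.det(c))
                )
        assert np.allclose(logp, manual, atol=1e-9)

    def test_constraint_contract_on_scattered_data(self, rng):
        pts = rs.sample_inner_points(np.random.default_rng(8), 400)
        model = fit_constrained_gmm(pts)
        r = 0.5 * model.d_min_
        for k in range(len(model.weights_)):
            assert np.linalg.norm(model.means_[k] - model.anchor_points_[k]) <= r + 1e-12
            lam = np.linalg.eigvalsh(model.covariances_[k])
            assert np.all(lam <= r + 1e-12)
            assert lam.min() / lam.sum() >= 0.2 - 1e-9
            assert lam.max() / lam.sum() <= 0.8 + 1e-9
        assert model.weights_.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_constrained_gmm(np.empty((0, 2)))

    def test_projections_are_idempotent(self):
        d_min, A = 0.04, 0.2
        cov = np.array([[0.01, 0.004], [0.004, 0.002]])
        once = _clamp_covariance(cov, d_min, A)
        assert np.allclose(_clamp_covariance(once, d_min, A), once, atol=1e-15)
        anchor = np.array([0.4, 0.3])
        mean = np.array([0.6, 0.5])
        once_m = _project_mean(mean, anchor, d_min)
        assert np.allclose(_project_mean(once_m, anchor, d_min), once_m)


class TestCategoryWeights:
    def test_uniform_weights(self):
        model = ConstrainedCategoryGMM()
        model.anchor_set_ = OMEGA
        model.weights_ = np.full(22, 1 / 22)
        w = category_weights(model)
        assert all(v == pytest.approx(1 / 22) for v in w.values())
        assert len(w) == 8

    def test_single_component_class_mean(self):
        model = ConstrainedCategoryGMM()
        model.anchor_set_ = OMEGA
        w = np.zeros(22)
        w[LABELS.index("332")] = 1.0
        model.weights_ = w
        assert category_weights(model)["233"] == pytest.approx(1 / 3)

    def test_invariant_to_rotation_relabelling(self):
        model = ConstrainedCategoryGMM()
        model.anchor_set_ = OMEGA
        g = np.random.default_rng(0)
        w = g.dirichlet(np.ones(22))
        model.weights_ = w.copy()
        before = category_weights(model)
        # permute weights within each cyclic class
        for idx in OMEGA.cyclic_classes.values():
            model.weights_[list(idx)] = np.roll(w[list(idx)], 1)
        assert category_weights(model) == pytest.approx(before)


class TestExplainedVariance:
    def test_model_density_explains_itself(self):
        model = fit_constrained_gmm(cloud((1, 1, 1), 200, 0.01))
        grid = triangle_grid()
        q = model.density(grid.centers)
        prior = DiscretePrior(grid=grid, p=q / q.sum(), f=0.15)
        assert explained_variance(model, prior) == pytest.approx(1.0, abs=1e-12)

    def test_constant_density_is_flagged(self):
        model = fit_constrained_gmm(cloud((1, 1, 1), 50, 0.01))
        grid = triangle_grid()
        prior = DiscretePrior(grid=grid, p=np.full(grid.n_bins, 1 / grid.n_bins), f=0.15)
        prior.p[:] = 1 / grid.n_bins
        model.density = lambda pts: np.ones(len(pts))  # degenerate model
        with pytest.warns(UserWarning):
            assert np.isnan(explained_variance(model, prior))


class TestPredictCategory:
    def test_dominant_component_wins_at_its_mean(self):
        pts = np.vstack([cloud((1, 1, 3), 300, 0.01, 1), cloud((1, 1, 1), 60, 0.01, 2)])
        model = fit_constrained_gmm(pts)
        k = LABELS.index("113")
        assert model.predict_category(model.means_[[k]])[0] == k

    def test_equal_weights_boundary_is_the_bisector(self):
        # two components, equal weights and covariances: the decision
        # boundary is the perpendicular bisector between the means
        members = tuple(
            OMEGA.members[LABELS.index(lbl)] for lbl in ("113", "111")
        )
        pair = rs.IntegerRatioSet("pair", members, rs.cyclic_classes(members))
        model = ConstrainedCategoryGMM(anchors=pair, gamma_cat=1.0, iso_boost=1.0)
        model.anchor_set_ = pair
        model.anchor_points_ = pair.points
        model.d_min_ = rs.min_pairwise_distance(pair)
        model.means_ = pair.points.copy()
        model.covariances_ = np.array([np.eye(2) * 1e-4] * 2)
        model.weights_ = np.full(2, 0.5)
        pa, pb = model.means_
        mid = 0.5 * (pa + pb)
        eps = 1e-4 * (pa - pb)
        perp = 0.3 * np.array([-(pa - pb)[1], (pa - pb)[0]])  # along the bisector
        for shift in (0.0 * perp, perp, -perp):
            assert model.predict_category([mid + eps + shift])[0] == 0
            assert model.predict_category([mid - eps + shift])[0] == 1

    def test_larger_gamma_never_shrinks_top_weight_region(self):
        pts = np.vstack([cloud((1, 1, 3), 300, 0.02, 1), cloud((1, 1, 1), 100, 0.02, 2)])
        grid = rs.sample_inner_points(np.random.default_rng(3), 400)
        top_regions = {}
        for gamma in (1.0, 3.0, 7.0):
            model = fit_constrained_gmm(pts, gamma_cat=gamma, iso_boost=1.0)
            top = int(np.argmax(model.weights_))
            top_regions[gamma] = model.predict_category(grid) == top
        assert np.all(top_regions[1.0] <= top_regions[3.0])
        assert np.all(top_regions[3.0] <= top_regions[7.0])


class TestCategoryMap:
    def test_identical_maps_have_zero_distance(self):
        m = OMEGA.proportions[:5]
        assert category_map_distance(m, m) == 0.0

    def test_printed_example(self):
        d = category_map_distance([[0.5, 0.25, 0.25]], [[0.5, 0.2, 0.3]])
        assert d == pytest.approx(np.linalg.norm([0.0, -0.05, 0.05]), abs=1e-12)
        assert d == pytest.approx(0.0707, abs=5e-4)

    def test_symmetry(self):
        g = np.random.default_rng(0)
        a = g.dirichlet(np.ones(3), 20)
        b = g.dirichlet(np.ones(3), 20)
        assert category_map_distance(a, b) == category_map_distance(b, a)

    def test_missing_assignment_raises(self):
        a = np.full((3, 3), 1 / 3)
        b = a.copy()
        b[1, 1] = np.nan
        with pytest.raises(ValueError):
            category_map_distance(a, b)


class TestReferenceMap:
    def test_single_category_everywhere(self):
        table = pd.DataFrame(
            [
                {"stim_p1": 0.3, "stim_p2": 0.3, "stim_p3": 0.4,
                 "cat_p1": 0.25, "cat_p2": 0.25, "cat_p3": 0.5, "count": 7},
            ]
        )
        pts = rs.sample_inner_points(np.random.default_rng(0), 50)
        ref = build_reference_map(table, pts)
        assert np.allclose(ref, [0.25, 0.25, 0.5])

    def test_two_category_boundary_at_kernel_midline(self):
        # two stimuli with equal counts and isotropic kernels: the modal
        # category flips exactly at the perpendicular bisector
        sa, sb = (0.45, 0.25, 0.3), (0.25, 0.45, 0.3)
        table = pd.DataFrame(
            [
                {"stim_p1": sa[0], "stim_p2": sa[1], "stim_p3": sa[2],
                 "cat_p1": 0.5, "cat_p2": 0.25, "cat_p3": 0.25, "count": 5},
                {"stim_p1": sb[0], "stim_p2": sb[1], "stim_p3": sb[2],
                 "cat_p1": 0.25, "cat_p2": 0.5, "cat_p3": 0.25, "count": 5},
            ]
        )
        pa = np.asarray(rs.project(sa))
        pb = np.asarray(rs.project(sb))
        mid = 0.5 * (pa + pb)
        eps = 1e-3 * (pa - pb)
        ref = build_reference_map(table, np.vstack([mid + eps, mid - eps]))
        assert np.allclose(ref[0], [0.5, 0.25, 0.25])
        assert np.allclose(ref[1], [0.25, 0.5, 0.25])

    def test_three_category_self_consistency(self):
        g = np.random.default_rng(5)
        cats = [(0.25, 0.25, 0.5), (0.5, 0.25, 0.25), (1 / 3, 1 / 3, 1 / 3)]
        rows = []
        for c in cats:
            centre = np.asarray(rs.project(c))
            for _ in range(15):
                p = centre + g.normal(0, 0.02, 2)
                props = rs.barycentric(p)
                if np.any(props <= 0):
                    continue
                rows.append(
                    {"stim_p1": props[0], "stim_p2": props[1], "stim_p3": props[2],
                     "cat_p1": c[0], "cat_p2": c[1], "cat_p3": c[2], "count": 1}
                )
        table = pd.DataFrame(rows)
        pts = rs.sample_inner_points(g, 400)
        ref = build_reference_map(table, pts)
        # generating partition: nearest category centre
        centres = rs.project_many(np.array(cats))
        nearest = np.argmin(
            np.sum((pts[:, None, :] - centres[None, :, :]) ** 2, axis=2), axis=1
        )
        agree = np.mean(
            [np.allclose(ref[i], cats[nearest[i]]) for i in range(len(pts))]
        )
        assert agree >= 0.95

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            build_reference_map(pd.DataFrame(), np.zeros((1, 2)))
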