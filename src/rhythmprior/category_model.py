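"""Constrained Gaussian mixture model anchored at integer-ratio categories.

The mixture Q(x) = sum_i w_i N(x; mu_i, C_i) is fitted by EM with one
component per integer-ratio rhythm.  After every M-step three constraints
are enforced so that each component stays identified with its category:

* mode identity — each mean is projected onto the ball of radius d_min / 2
  around its anchor, where d_min is the minimal pairwise distance among the
  anchors;
* overlap — covariance eigenvalues are truncated at d_min / 2;
* aspect — each eigenvalue is clamped to lie within
  [A (l1 + l2), (1 - A)(l1 + l2)] with A = 1/5 (eigenvectors preserved).

Component weights averaged over cyclic permutations give per-class category
weights; an exponent-weighted variant of the mixture (weights raised to
gamma = 7, isochrony boosted threefold) predicts categorical-perception
judgements, which can be compared with a reference category map via the
mean L2 distance between assigned category ratio triples.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from . import rhythm_space as rs
from .prior_estimation import DiscretePrior

__all__ = [
    "ConstrainedCategoryGMM",
    "fit_constrained_gmm",
    "category_weights",
    "explained_variance",
    "predict_category",
    "category_map_distance",
    "build_reference_map",
]


def _clamp_covariance(cov: np.ndarray, d_min: float, aspect: float) -> np.ndarray:
    """Eigenvalue truncation and aspect clamp; idempotent."""
    lam, vec = np.linalg.eigh(cov)
    lam = np.maximum(lam, 1e-12)
    lam = np.minimum(lam, 0.5 * d_min)
    s = lam.sum()
    lam = np.clip(lam, aspect * s, (1.0 - aspect) * s)
    return (vec * lam) @ vec.T


def _project_mean(mean: np.ndarray, anchor: np.ndarray, d_min: float) -> np.ndarray:
    delta = mean - anchor
    norm = np.hypot(delta[0], delta[1])
    r = 0.5 * d_min
    if norm <= r:
        return mean
    return anchor + delta * (r / norm)


class ConstrainedCategoryGMM(BaseEstimator):
    """EM-fitted Gaussian mixture with category-anchored components.

    Parameters
    ----------
    anchors : IntegerRatioSet or None
        Category anchors; defaults to the 22 small-integer ratios.
    tol : absolute convergence threshold on the mean log-likelihood.
    aspect_bound : the constant A of the aspect constraint.
    gamma_cat, iso_boost : parameters of the categorical-perception
        predictor (weight exponent, isochrony weight boost).
    boost_before_exponent : apply the isochrony boost to w before raising
        to gamma (the effective factor is then iso_boost ** gamma_cat).

    Attributes
    ----------
    means_, covariances_, weights_ : fitted component parameters.
    anchor_points_ : (K, 2) projected anchors.
    d_min_ : minimal pairwise anchor distance.
    converged_, n_iter_, log_likelihood_ : EM diagnostics.
    """

    def __init__(
        self,
        anchors: rs.IntegerRatioSet | None = None,
        tol: float = 1e-6,
        max_iter: int = 1000,
        aspect_bound: float = 0.2,
        gamma_cat: float = 7.0,
        iso_boost: float = 3.0,
        boost_before_exponent: bool = True,
    ):
        self.anchors = anchors
        self.tol = tol
        self.max_iter = max_iter
        self.aspect_bound = aspect_bound
        self.gamma_cat = gamma_cat
        self.iso_boost = iso_boost
        self.boost_before_exponent = boost_before_exponent

    # -- log densities -------------------------------------------------
    @staticmethod
    def _log_gauss(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
        det = cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[1, 0]
        inv00, inv11, inv01 = cov[1, 1] / det, cov[0, 0] / det, -cov[0, 1] / det
        d = X - mean
        q = inv00 * d[:, 0] ** 2 + 2 * inv01 * d[:, 0] * d[:, 1] + inv11 * d[:, 1] ** 2
        return -0.5 * q - np.log(2.0 * np.pi) - 0.5 * np.log(det)

    def _component_log_pdf(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [
                self._log_gauss(X, m, c)
                for m, c in zip(self.means_, self.covariances_)
            ]
        )

    # -- fitting -------------------------------------------------------
    def fit(self, X: np.ndarray, y=None) -> "ConstrainedCategoryGMM":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2 or len(X) == 0:
            raise ValueError("X must be a non-empty (n, 2) array of triangle points")
        anchors = self.anchors if self.anchors is not None else rs.omega22()
        self.anchor_set_ = anchors
        A = anchors.points
        K = len(A)
        self.anchor_points_ = A
        self.d_min_ = rs.min_pairwise_distance(anchors)
        self.means_ = A.copy()
        init_var = (0.25 * self.d_min_) ** 2
        self.covariances_ = np.array([np.eye(2) * init_var for _ in range(K)])
        self.weights_ = np.full(K, 1.0 / K)
        prev_ll = -np.inf
        self.converged_ = False
        for it in range(1, self.max_iter + 1):
            with np.errstate(divide="ignore"):
                log_wpdf = self._component_log_pdf(X) + np.log(self.weights_)
            norm = logsumexp(log_wpdf, axis=1)
            ll = float(np.mean(norm))
            resp = np.exp(log_wpdf - norm[:, None])
            # M-step
            nk = resp.sum(axis=0)
            self.weights_ = nk / nk.sum()
            for k in range(K):
                if nk[k] < 1e-12:
                    self.means_[k] = A[k]
                    self.covariances_[k] = np.eye(2) * init_var
                    continue
                mean = resp[:, k] @ X / nk[k]
                d = X - mean
                cov = (resp[:, k][:, None] * d).T @ d / nk[k]
                self.means_[k] = _project_mean(mean, A[k], self.d_min_)
                self.covariances_[k] = _clamp_covariance(
                    cov, self.d_min_, self.aspect_bound
                )
            if abs(ll - prev_ll) < self.tol:
                self.converged_ = True
                prev_ll = ll
                break
            prev_ll = ll
        else:
            warnings.warn("constrained EM did not converge", RuntimeWarning)
        self.n_iter_ = it
        self.log_likelihood_ = prev_ll
        return self

    # -- inference -----------------------------------------------------
    def score(self, X: np.ndarray, y=None) -> float:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        with np.errstate(divide="ignore"):
            return float(
                np.mean(logsumexp(self._component_log_pdf(X) + np.log(self.weights_), axis=1))
            )

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Maximum-responsibility component index (plain GMM semantics)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        with np.errstate(divide="ignore"):
            return np.argmax(self._component_log_pdf(X) + np.log(self.weights_), axis=1)

    def density(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        with np.errstate(divide="ignore"):
            return np.exp(
                logsumexp(self._component_log_pdf(pts) + np.log(self.weights_), axis=1)
            )

    def _category_log_scores(self, X: np.ndarray) -> np.ndarray:
        w = self.weights_.copy()
        iso = [
            i
            for i, m in enumerate(self.anchor_set_.members)
            if len(set(m)) == 1
        ]
        if self.boost_before_exponent:
            w[iso] *= self.iso_boost
            logw = self.gamma_cat * np.log(np.maximum(w, 1e-300))
        else:
            logw = self.gamma_cat * np.log(np.maximum(w, 1e-300))
            logw[iso] += np.log(self.iso_boost)
        return self._component_log_pdf(X) + logw

    def predict_category(self, X: np.ndarray) -> np.ndarray:
        """Component index under the exponent-weighted category predictor.

        Ties are broken toward the component with the nearer mean.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        scores = self._category_log_scores(X)
        best = np.argmax(scores, axis=1)
        top = scores[np.arange(len(X)), best]
        ties = np.isclose(scores, top[:, None], rtol=0, atol=1e-12)
        multi = ties.sum(axis=1) > 1
        for i in np.flatnonzero(multi):
            cand = np.flatnonzero(ties[i])
            d = np.linalg.norm(self.means_[cand] - X[i], axis=1)
            best[i] = cand[np.argmin(d)]
        return best


def fit_constrained_gmm(
    points: np.ndarray, anchors: rs.IntegerRatioSet | None = None, **kwargs
) -> ConstrainedCategoryGMM:
    return ConstrainedCategoryGMM(anchors=anchors, **kwargs).fit(points)


def category_weights(model: ConstrainedCategoryGMM) -> dict[str, float]:
    """Per-cyclic-class weights: the mean of each class's component weights
    (isochrony keeps its single component's weight)."""
    out = {}
    for label, idx in model.anchor_set_.cyclic_classes.items():
        out[label] = float(np.mean(model.weights_[list(idx)]))
    return out


def explained_variance(model: ConstrainedCategoryGMM, prior: DiscretePrior) -> float:
    """Squared Pearson correlation of model and data densities on the grid.

    Returns NaN (with a warning) if either gridded density is constant.
    """
    q = model.density(prior.grid.centers)
    p = prior.p
    if np.std(q) == 0 or np.std(p) == 0:
        warnings.warn("zero-variance grid density; explained variance undefined")
        return float("nan")
    r = np.corrcoef(q, p)[0, 1]
    return float(r**2)


def predict_category(
    model: ConstrainedCategoryGMM, points: np.ndarray
) -> np.ndarray:
    """Predicted category proportion triples, shape (n, 3)."""
    idx = model.predict_category(points)
    return model.anchor_set_.proportions[idx]


def category_map_distance(
    predicted: np.ndarray, reference: np.ndarray
) -> float:
    """Mean L2 distance between assigned category ratio triples.

    Both maps must assign a proportion triple to every evaluation point.
    """
    a = np.asarray(predicted, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("maps must be matching (n, 3) proportion arrays")
    if np.any(np.isnan(a)) or np.any(np.isnan(b)):
        raise ValueError("missing category assignment at an evaluation point")
    return float(np.mean(np.linalg.norm(a - b, axis=1)))


def build_reference_map(
    table,
    eval_points: np.ndarray,
    kernel_width: float = 0.03,
) -> np.ndarray:
    """Modal category at each evaluation point from labelled judgements.

    ``table`` is a DataFrame with columns stim_p1..stim_p3 (stimulus
    proportions), cat_p1..cat_p3 (chosen category proportions) and count.
    Each distinct category's choice counts are interpolated over the
    triangle with an isotropic Gaussian kernel of width ``kernel_width``;
    the category with the largest interpolated weight wins at each point.
    """
    import pandas as pd

    df = pd.DataFrame(table)
    if len(df) == 0:
        raise ValueError("empty category-judgement table")
    stim = rs.project_many(df[["stim_p1", "stim_p2", "stim_p3"]].to_numpy(float))
    cats = df[["cat_p1", "cat_p2", "cat_p3"]].to_numpy(float)
    counts = df["count"].to_numpy(float)
    labels, inverse = np.unique(cats.round(12), axis=0, return_inverse=True)
    pts = np.atleast_2d(np.asarray(eval_points, dtype=float))
    d2 = np.sum((pts[:, None, :] - stim[None, :, :]) ** 2, axis=2)
    kern = counts * np.exp(-0.5 * d2 / kernel_width**2)
    scores = np.zeros((len(pts), len(labels)))
    for j in range(len(labels)):
        scores[:, j] = kern[:, inverse == j].sum(axis=1)
    return labels[np.argmax(scores, axis=1)]
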