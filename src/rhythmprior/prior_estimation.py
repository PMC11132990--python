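"""Kernel density estimation of the rhythm prior on a triangle grid.

The prior over rhythms is estimated from the fifth-iteration reproductions:
each completed trial contributes one Gaussian kernel whose mean and
covariance are computed empirically from the (up to ten) repetitions of the
rhythm within that iteration, regularized on the diagonal.  Kernels are
averaged across trials and represented on a grid of square bins (0.006
triangle units, i.e. 12 ms at the 2,000 ms period) covering the full
triangle, then renormalized to sum to one.

Trials whose fifth-iteration mean falls outside the inner triangular region
of producible rhythms (all proportions > f = 0.15) are excluded before
kernel construction.
"""

from __future__ import annotations

import functools
import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import rhythm_space as rs

__all__ = [
    "TriangleGrid",
    "triangle_grid",
    "DiscretePrior",
    "trial_kernel",
    "gaussian_on_grid",
    "TrianglePriorKDE",
    "estimate_prior",
    "normalize_vs_uniform",
    "density_from_histogram",
]


@dataclass(frozen=True)
class TriangleGrid:
    """Square-bin grid restricted to the full rhythm triangle.

    ``centers`` holds the (B, 2) bin centres; ``ix``/``iy`` are each bin's
    integer lattice coordinates within the bounding box, for embedding grid
    vectors back into a rectangular image.
    """

    bin_width: float
    centers: np.ndarray
    ix: np.ndarray
    iy: np.ndarray
    nx: int
    ny: int

    @property
    def n_bins(self) -> int:
        return len(self.centers)

    def inner_mask(self, f: float = 0.15) -> np.ndarray:
        return rs.in_inner_triangle_many(self.centers, f)

    def to_image(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        img = np.full((self.ny, self.nx), fill)
        img[self.iy, self.ix] = values
        return img

    def from_image(self, img: np.ndarray) -> np.ndarray:
        return img[self.iy, self.ix]

    def bin_index_of(self, points: np.ndarray) -> np.ndarray:
        """Index into ``centers`` of the bin containing each point (-1 if none)."""
        pts = np.atleast_2d(points)
        jx = np.floor(pts[:, 0] / self.bin_width).astype(int)
        jy = np.floor(pts[:, 1] / self.bin_width).astype(int)
        lookup = np.full((self.ny, self.nx), -1, dtype=int)
        lookup[self.iy, self.ix] = np.arange(self.n_bins)
        ok = (jx >= 0) & (jx < self.nx) & (jy >= 0) & (jy < self.ny)
        out = np.full(len(pts), -1, dtype=int)
        out[ok] = lookup[jy[ok], jx[ok]]
        return out


@functools.lru_cache(maxsize=8)
def triangle_grid(bin_width: float = 0.006) -> TriangleGrid:
    """Bin centres of a ``bin_width`` grid inside the full triangle."""
    nx = int(np.ceil(1.0 / bin_width))
    ny = int(np.ceil((rs.SQRT3 / 2.0) / bin_width))
    cx = (np.arange(nx) + 0.5) * bin_width
    cy = (np.arange(ny) + 0.5) * bin_width
    gx, gy = np.meshgrid(cx, cy)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    bary = rs.barycentric_many(pts)
    inside = np.all(bary >= 0.0, axis=1)
    jx, jy = np.meshgrid(np.arange(nx), np.arange(ny))
    return TriangleGrid(
        bin_width=bin_width,
        centers=pts[inside],
        ix=jx.ravel()[inside],
        iy=jy.ravel()[inside],
        nx=nx,
        ny=ny,
    )


@dataclass
class DiscretePrior:
    """A binned probability distribution over the rhythm triangle."""

    grid: TriangleGrid
    p: np.ndarray
    f: float = 0.15
    n_trials: int = 0

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (self.grid.n_bins,):
            raise ValueError("probability vector does not match the grid")

    @property
    def inner_mask(self) -> np.ndarray:
        return self.grid.inner_mask(self.f)

    def same_grid(self, other: "DiscretePrior") -> bool:
        return (
            self.grid.bin_width == other.grid.bin_width
            and self.grid.n_bins == other.grid.n_bins
        )

    def to_tsv(self, path) -> None:
        header = (
            f"# bin_width={self.grid.bin_width!r}\tf={self.f!r}\t"
            f"n_trials={self.n_trials}\n"
        )
        buf = io.StringIO()
        buf.write(header)
        buf.write("bin_x\tbin_y\tprobability\tinner_flag\n")
        inner = self.inner_mask
        for (x, y), p, m in zip(self.grid.centers, self.p, inner):
            buf.write(f"{float(x)!r}\t{float(y)!r}\t{float(p)!r}\t{int(m)}\n")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_tsv(cls, path) -> "DiscretePrior":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError("missing prior header line")
            meta = dict(
                item.split("=", 1) for item in header.lstrip("#").strip().split("\t")
            )
            fh.readline()  # column names
            probs = [float(line.split("\t")[2]) for line in fh if line.strip()]
        grid = triangle_grid(float(meta["bin_width"]))
        return cls(
            grid=grid,
            p=np.array(probs),
            f=float(meta["f"]),
            n_trials=int(meta["n_trials"]),
        )


def trial_kernel(
    points: np.ndarray,
    gamma_ms: float = 15.0,
    period: float = 2000.0,
    gamma_as_sd: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical mean and regularized covariance of one trial's repetitions.

    ``gamma_ms`` is the regularizer added to the covariance diagonal.  By
    default it is treated as a standard deviation, contributing
    (gamma_ms / period)^2 in triangle units; set ``gamma_as_sd=False`` to
    add gamma_ms / period directly as a variance.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("trial has no repetition points")
    mean = pts.mean(axis=0)
    if pts.shape[0] > 1:
        cov = np.cov(pts.T, ddof=1)
    else:
        cov = np.zeros((2, 2))
    reg = (gamma_ms / period) ** 2 if gamma_as_sd else gamma_ms / period
    return mean, cov + reg * np.eye(2)


def gaussian_on_grid(
    mean: np.ndarray, cov: np.ndarray, centers: np.ndarray
) -> np.ndarray:
    """Bivariate normal pdf evaluated at grid centres."""
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[1, 0]
    inv = np.array([[cov[1, 1], -cov[0, 1]], [-cov[1, 0], cov[0, 0]]]) / det
    d = centers - mean
    q = inv[0, 0] * d[:, 0] ** 2 + 2 * inv[0, 1] * d[:, 0] * d[:, 1] + inv[1, 1] * d[:, 1] ** 2
    return np.exp(-0.5 * q) / (2.0 * np.pi * np.sqrt(det))


def _as_triangle_points(points: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] == 3:
        pts = rs.project_many(pts / pts.sum(axis=1, keepdims=True))
    return pts


class TrianglePriorKDE(BaseEstimator):
    """Trial-kernel density estimator of the rhythm prior.

    Parameters
    ----------
    bin_width : grid resolution in triangle units (0.006 for analysis,
        0.003 for display).
    f : inner-region fraction; trials whose fifth-iteration mean has any
        proportion <= f are excluded.
    gamma_ms : covariance regularizer (see :func:`trial_kernel`).
    period_ms : cycle duration used to convert gamma to triangle units.

    Attributes
    ----------
    prior_ : DiscretePrior
    trial_grids_ : (n_used, B) per-trial kernel evaluations, each row
        normalized to sum 1 over the grid (used by split-half bootstraps).
    trial_means_ : (n_used, 2) trial kernel means.
    n_used_ : trials retained after the inner-region exclusion.
    """

    def __init__(
        self,
        bin_width: float = 0.006,
        f: float = 0.15,
        gamma_ms: float = 15.0,
        period_ms: float = 2000.0,
        gamma_as_sd: bool = True,
    ):
        self.bin_width = bin_width
        self.f = f
        self.gamma_ms = gamma_ms
        self.period_ms = period_ms
        self.gamma_as_sd = gamma_as_sd

    def fit(self, X: Sequence[np.ndarray], y=None) -> "TrianglePriorKDE":
        """Fit from a sequence of per-trial repetition point arrays.

        Each element of ``X`` is an (n_i, 2) array of triangle coordinates
        or an (n_i, 3) array of proportion triples for one trial's
        fifth-iteration repetitions.
        """
        grid = triangle_grid(self.bin_width)
        rows, means = [], []
        for trial_points in X:
            pts = _as_triangle_points(trial_points)
            if pts.shape[0] == 0:
                continue
            mean, cov = trial_kernel(
                pts, self.gamma_ms, self.period_ms, self.gamma_as_sd
            )
            if not rs.in_inner_triangle(mean, self.f):
                continue
            g = gaussian_on_grid(mean, cov, grid.centers)
            total = g.sum()
            if total <= 0:
                continue
            rows.append(g / total)
            means.append(mean)
        if not rows:
            raise ValueError("no usable trials (all excluded or empty)")
        self.trial_grids_ = np.asarray(rows)
        self.trial_means_ = np.asarray(means)
        self.n_used_ = len(rows)
        p = self.trial_grids_.mean(axis=0)
        self.prior_ = DiscretePrior(grid=grid, p=p / p.sum(), f=self.f, n_trials=self.n_used_)
        return self

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        """Log of the estimated prior probability of the bin containing X."""
        idx = self.prior_.grid.bin_index_of(_as_triangle_points(X))
        out = np.full(len(idx), -np.inf)
        ok = idx >= 0
        with np.errstate(divide="ignore"):
            out[ok] = np.log(self.prior_.p[idx[ok]])
        return out


def estimate_prior(
    trials: Sequence[np.ndarray],
    f: float = 0.15,
    bin_width: float = 0.006,
    gamma_ms: float = 15.0,
    period: float = 2000.0,
) -> DiscretePrior:
    """Functional wrapper over :class:`TrianglePriorKDE`."""
    kde = TrianglePriorKDE(
        bin_width=bin_width, f=f, gamma_ms=gamma_ms, period_ms=period
    ).fit(trials)
    return kde.prior_


def normalize_vs_uniform(prior: DiscretePrior, clip: float | None = None) -> np.ndarray:
    """Pointwise density ratio against the uniform distribution over the
    inner region: P'(x) = P(x) / U(x); NaN outside the inner region.

    ``clip`` truncates large ratios for display only; the underlying
    probabilities are never modified.
    """
    inner = prior.inner_mask
    u = 1.0 / inner.sum()
    ratio = np.full(prior.grid.n_bins, np.nan)
    ratio[inner] = prior.p[inner] / u
    if clip is not None:
        ratio = np.minimum(ratio, clip)
    return ratio


def density_from_histogram(
    points: np.ndarray,
    grid: TriangleGrid,
    gamma_ms: float = 15.0,
    period: float = 2000.0,
) -> np.ndarray:
    """Fast KDE for null simulations: bin points, convolve with the
    regularizer-only Gaussian kernel, renormalize over the triangle.

    Approximates one kernel N(point, (gamma/period)^2 I) per point with the
    point rounded to its bin centre.  Used only for bootstrap null
    distributions; observed statistics use the exact per-trial kernels.
    """
    from scipy.ndimage import gaussian_filter

    pts = _as_triangle_points(points)
    idx = grid.bin_index_of(pts)
    idx = idx[idx >= 0]
    if len(idx) == 0:
        raise ValueError("no points fall inside the triangle grid")
    hist = np.zeros(grid.n_bins)
    np.add.at(hist, idx, 1.0)
    img = grid.to_image(hist, fill=0.0)
    sigma_bins = (gamma_ms / period) / grid.bin_width
    img = gaussian_filter(img, sigma=sigma_bins, mode="constant")
    p = grid.from_image(img)
    return p / p.sum()
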