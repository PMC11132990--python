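"""Cross-group structure: MDS on JSD matrices and PCA on gridded priors.

MDS minimizes metric stress (SMACOF) starting from the classical-scaling
solution, so the embedding is deterministic; its orientation is still
arbitrary up to rotation/reflection, and PCA component signs are likewise
arbitrary — downstream comparisons must be invariant to both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .prior_estimation import DiscretePrior

__all__ = [
    "GroupEmbedding",
    "mds",
    "pca_on_grids",
    "correlate_dims_with_weights",
    "CorrelationResult",
]


@dataclass
class GroupEmbedding:
    coords: np.ndarray  # (G, dims)
    stress: float
    method: str
    group_ids: list[str] | None = None

    def to_tsv(self, path) -> None:
        import pandas as pd

        ids = self.group_ids or [f"g{i}" for i in range(len(self.coords))]
        df = pd.DataFrame(self.coords, columns=[f"dim{i+1}" for i in range(self.coords.shape[1])])
        df.insert(0, "group_id", ids)
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def _classical_init(D: np.ndarray, dims: int) -> np.ndarray:
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def mds(
    distance_matrix: np.ndarray,
    dims: int = 2,
    group_ids: list[str] | None = None,
) -> GroupEmbedding:
    """Metric stress-majorization MDS with classical-scaling start."""
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0) or not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distances must be nonnegative with a zero diagonal")
    init = _classical_init(D, dims)
    if D.shape[0] <= dims:  # degenerate: classical solution is exact
        return GroupEmbedding(init, 0.0, "classical", group_ids)
    from sklearn.manifold import smacof

    coords, stress = smacof(
        D,
        metric=True,
        n_components=dims,
        init=init,
        n_init=1,
        max_iter=1000,
        eps=1e-9,
        random_state=0,
        normalized_stress=False,
    )
    return GroupEmbedding(coords, float(stress), "smacof", group_ids)


def pca_on_grids(
    priors: list[DiscretePrior] | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of gridded priors treated as pixel feature vectors.

    Features are mean-centred but not scaled (all share units).  Returns
    (components, projections, variance_share); component signs arbitrary.
    """
    if isinstance(priors, np.ndarray):
        X = np.asarray(priors, dtype=float)
    else:
        if len(priors) < 2:
            raise ValueError("need at least 2 priors")
        first = priors[0]
        if not all(p.same_grid(first) for p in priors[1:]):
            raise ValueError("priors live on different grids")
        X = np.vstack([p.p for p in priors])
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S**2
    share = var / var.sum() if var.sum() > 0 else var
    return Vt, U * S, share


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    ci_low: float
    ci_high: float
    r_rin: float
    n: int


def _rankit(x: np.ndarray) -> np.ndarray:
    ranks = sps.rankdata(x)
    return sps.norm.ppf((ranks - 0.5) / len(x))


def correlate_dims_with_weights(
    projection: np.ndarray,
    weights: np.ndarray,
    bonferroni: int = 1,
) -> CorrelationResult:
    """Pearson correlation with a rank-based inverse-normal (RIN) CI.

    Both vectors are rank-transformed to normal scores; the Fisher-z CI of
    their correlation gives robust bounds.  The reported r and p are the
    raw Pearson values (p multiplied by the Bonferroni factor, capped at 1).
    """
    x = np.asarray(projection, dtype=float)
    y = np.asarray(weights, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("projection and weights must be matched 1-D vectors")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), float("nan"),
                                 float("nan"), float("nan"), len(x))
    r, p = sps.pearsonr(x, y)
    rr = float(np.corrcoef(_rankit(x), _rankit(y))[0, 1])
    n = len(x)
    z = np.arctanh(np.clip(rr, -1 + 1e-12, 1 - 1e-12))
    half = 1.959963984540054 / np.sqrt(n - 3)
    return CorrelationResult(
        r=float(r),
        p_value=float(min(1.0, p * bonferroni)),
        ci_low=float(np.tanh(z - half)),
        ci_high=float(np.tanh(z + half)),
        r_rin=rr,
        n=n,
    )
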