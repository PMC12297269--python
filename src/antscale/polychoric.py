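"""Polychoric correlations for ordinal Likert items.

Two-step estimation: item thresholds come from the inverse-normal transform of
marginal cumulative proportions; each pairwise correlation then maximizes the
bivariate-normal contingency likelihood with thresholds held fixed.  This is
the first stage of the weighted-least-squares family of ordinal CFA
estimators.

The bivariate-normal rectangle probabilities use the single-integral identity

    Phi2(h, k; rho) = Phi(h) Phi(k)
        + (1 / 2 pi) * int_0^rho exp(-(h^2 - 2 h k r + k^2) / (2 (1 - r^2)))
                        / sqrt(1 - r^2) dr,

evaluated with Gauss-Legendre quadrature after the substitution ``r = sin t``
which removes the endpoint singularity.  Accuracy is far below the 1e-6
tolerance used for the correlation itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .scale import ResponseMatrix

__all__ = [
    "estimate_thresholds",
    "polychoric_pair",
    "polychoric_matrix",
    "PolychoricMatrix",
    "bvn_cdf",
]

RHO_BOUND = 0.999
#: thresholds beyond this are numerically indistinguishable from +/- infinity
_TAIL_CAP = 8.0

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)


@dataclass(frozen=True)
class PolychoricMatrix:
    """Symmetric positive-definite polychoric correlation matrix."""

    values: np.ndarray
    item_ids: tuple[str, ...]
    smoothing_applied: bool = False

    def submatrix(self, items: tuple[str, ...]) -> np.ndarray:
        idx = [self.item_ids.index(i) for i in items]
        return self.values[np.ix_(idx, idx)]


def estimate_thresholds(column: np.ndarray, n_categories: int) -> np.ndarray:
    """Thresholds on the latent standard-normal scale for one ordinal item.

    ``threshold_k = Phi^{-1}(P(X <= k))`` for ``k = 1..C-1``.  An interior
    cumulative proportion of exactly 0 or 1 (an empty boundary category)
    yields a ``-inf``/``+inf`` sentinel and a warning.
    """
    col = np.asarray(column)
    if col.size == 0:
        raise ValueError("empty column")
    if col.min() < 1 or col.max() > n_categories:
        raise ValueError("entries outside 1..C")
    counts = np.bincount(col.astype(np.int64), minlength=n_categories + 1)[1:]
    cum = np.cumsum(counts)[:-1] / col.size
    if np.any(cum <= 0) or np.any(cum >= 1):
        warnings.warn(
            "empty boundary category: infinite threshold sentinel(s) produced",
            RuntimeWarning,
            stacklevel=2,
        )
    return norm.ppf(cum)


def bvn_cdf(h: np.ndarray, k: np.ndarray, rho: float) -> np.ndarray:
    """Standard bivariate normal CDF ``P(X <= h, Y <= k)``, vectorized in h, k."""
    h = np.clip(np.asarray(h, dtype=float), -_TAIL_CAP, _TAIL_CAP)
    k = np.clip(np.asarray(k, dtype=float), -_TAIL_CAP, _TAIL_CAP)
    base = norm.cdf(h) * norm.cdf(k)
    if rho == 0.0:
        return base
    rho = float(np.clip(rho, -RHO_BOUND, RHO_BOUND))
    upper = np.arcsin(rho)
    t = 0.5 * upper * (_GL_NODES + 1.0)  # nodes on [0, arcsin rho]
    w = 0.5 * upper * _GL_WEIGHTS
    sin_t = np.sin(t)
    cos2_t = np.cos(t) ** 2
    hh = h[..., None]
    kk = k[..., None]
    integrand = np.exp(-(hh**2 - 2.0 * hh * kk * sin_t + kk**2) / (2.0 * cos2_t))
    return base + (integrand @ w) / (2.0 * np.pi)


def _cell_probabilities(tx: np.ndarray, ty: np.ndarray, rho: float) -> np.ndarray:
    ax = np.concatenate(([-np.inf], tx, [np.inf]))
    ay = np.concatenate(([-np.inf], ty, [np.inf]))
    grid = bvn_cdf(ax[:, None], ay[None, :], rho)
    cells = np.diff(np.diff(grid, axis=0), axis=1)
    return np.clip(cells, 1e-300, None)


def polychoric_pair(
    x: np.ndarray,
    y: np.ndarray,
    tx: np.ndarray,
    ty: np.ndarray,
    *,
    tol: float = 1e-6,
) -> float:
    """Maximum-likelihood polychoric correlation with thresholds fixed.

    Bounded scalar optimization of the contingency-table likelihood over
    ``rho`` in ``[-0.999, 0.999]``; deterministic given inputs.
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    cx, cy = len(tx) + 1, len(ty) + 1
    table = np.zeros((cx, cy))
    np.add.at(table, (x - 1, y - 1), 1.0)

    def neg_ll(rho: float) -> float:
        return -float(np.sum(table * np.log(_cell_probabilities(tx, ty, rho))))

    res = minimize_scalar(
        neg_ll, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
        options={"xatol": tol},
    )
    if not res.success:  # pragma: no cover - bounded Brent essentially always succeeds
        warnings.warn("polychoric optimizer did not converge; bound-clipped estimate",
                      RuntimeWarning, stacklevel=2)
    return float(np.clip(res.x, -RHO_BOUND, RHO_BOUND))


def polychoric_matrix(responses: ResponseMatrix) -> PolychoricMatrix:
    """All pairwise polychoric correlations of a response matrix.

    A column observed in a single category is degenerate and fatal.  If the
    smallest eigenvalue of the assembled matrix falls below 1e-8, eigenvalues
    are clipped there and the matrix rescaled to unit diagonal
    (``smoothing_applied`` is set).
    """
    p = responses.n_items
    C = int(responses.values.max())
    thresholds = []
    for j, item in enumerate(responses.item_ids):
        col = responses.values[:, j]
        if np.unique(col).size < 2:
            raise ValueError(f"item {item!r} is constant: polychoric undefined")
        thresholds.append(estimate_thresholds(col, C))
    R = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            r = polychoric_pair(
                responses.values[:, i], responses.values[:, j],
                thresholds[i], thresholds[j],
            )
            R[i, j] = R[j, i] = r
    smoothed = False
    eigval, eigvec = np.linalg.eigh(R)
    if eigval.min() < 1e-8:
        eigval = np.clip(eigval, 1e-8, None)
        R = (eigvec * eigval) @ eigvec.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        smoothed = True
    return PolychoricMatrix(R, responses.item_ids, smoothed)
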