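"""Simple-structure confirmatory factor analysis on a correlation matrix.

Each item loads on exactly one factor; residual variances are fixed at
``1 - lambda^2`` (standardized correlation-structure parameterization), and
factor correlations are free.  The fit minimizes the maximum-likelihood
discrepancy

    F(S, Sigma) = log|Sigma| - log|S| + tr(S Sigma^{-1}) - p

with ``Sigma = Lambda Phi Lambda' + diag(1 - lambda^2)``.  The test statistic
is ``T = (N - 1) F`` at the minimum; the baseline (independence) model sets
all correlations to zero.  CFI and RMSEA follow their standard definitions,
and McDonald's omega is computed per factor from the standardized loadings:

    omega = (sum lambda)^2 / ((sum lambda)^2 + sum (1 - lambda^2)).

Solutions with any ``|lambda| >= 1`` are Heywood cases, flagged and treated
as inadmissible by callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .scale import ScaleDefinition

__all__ = [
    "CfaFit",
    "model_df",
    "fit_cfa",
    "fit_indices",
    "omega",
    "loading_summary",
]

_RESID_FLOOR = 1e-4
_LAMBDA_BOUND = 1.2  # past 1 so Heywood cases are observable, residual floored
_PHI_BOUND = 0.995


@dataclass(frozen=True)
class CfaFit:
    """Converged (or flagged) CFA solution on a correlation matrix."""

    item_ids: tuple[str, ...]
    factors: tuple[str, ...]
    loadings: Mapping[str, float]
    factor_corr: np.ndarray
    stat_T: float
    df: int
    baseline_T: float
    baseline_df: int
    cfi: float
    rmsea: float
    omega_by_factor: Mapping[str, float]
    converged: bool
    heywood: bool
    n_obs: int
    discrepancy: float = field(default=float("nan"))

    @property
    def factor_corr_value(self) -> float:
        """The single factor correlation of a two-factor model."""
        if len(self.factors) != 2:
            raise ValueError("factor_corr_value is defined for two factors")
        return float(self.factor_corr[0, 1])

    def to_dict(self) -> dict:
        return {
            "items": list(self.item_ids),
            "factors": list(self.factors),
            "loadings": {k: float(v) for k, v in self.loadings.items()},
            "factor_corr": np.asarray(self.factor_corr).tolist(),
            "stat_T": self.stat_T,
            "df": self.df,
            "baseline_T": self.baseline_T,
            "baseline_df": self.baseline_df,
            "cfi": self.cfi,
            "rmsea": self.rmsea,
            "omega": {k: float(v) for k, v in self.omega_by_factor.items()},
            "converged": self.converged,
            "heywood": self.heywood,
            "n_obs": self.n_obs,
        }


def model_df(p: int, q: int) -> int:
    """Degrees of freedom of the correlation-structure model.

    ``p(p-1)/2`` distinct correlations minus ``p`` loadings minus ``q`` free
    factor correlations.  Negative df means the model is under-identified.
    """
    if p < 3:
        raise ValueError("need at least 3 items")
    if q < 0:
        raise ValueError("q must be non-negative")
    df = p * (p - 1) // 2 - p - q
    if df < 0:
        raise ValueError(f"under-identified model: df = {df}")
    return df


def fit_indices(
    stat_T: float, df: int, baseline_T: float, baseline_df: int, n_obs: int
) -> tuple[float, float]:
    """CFI and RMSEA from model and baseline test statistics.

    ``cfi = 1 - max(T - df, 0) / max(T_b - df_b, T - df, 0)`` (1 when the
    denominator vanishes, 0 when the baseline outperforms the model);
    ``rmsea = sqrt(max(T - df, 0) / (df (N - 1)))``.
    """
    if df <= 0:
        raise ValueError("df must be positive")
    num = max(stat_T - df, 0.0)
    den = max(baseline_T - baseline_df, stat_T - df, 0.0)
    cfi = 1.0 if den == 0.0 else 1.0 - num / den
    rmsea = float(np.sqrt(num / (df * (n_obs - 1))))
    return float(cfi), rmsea


def omega(loadings: Sequence[float]) -> float:
    """McDonald's omega from standardized loadings of one factor."""
    lam = np.asarray(loadings, dtype=float)
    if lam.size == 0:
        raise ValueError("no loadings")
    if np.any(np.abs(lam) >= 1.0):
        raise ValueError("Heywood loading (|lambda| >= 1): omega undefined")
    s = lam.sum()
    return float(s**2 / (s**2 + np.sum(1.0 - lam**2)))


def loading_summary(fit_or_loadings) -> tuple[float, float, float]:
    """(mean, min, max) of standardized loadings."""
    if isinstance(fit_or_loadings, CfaFit):
        lam = np.array(list(fit_or_loadings.loadings.values()), dtype=float)
    else:
        lam = np.asarray(list(fit_or_loadings), dtype=float)
    return float(lam.mean()), float(lam.min()), float(lam.max())


def _discrepancy_and_grad(params, S, fidx, K, logdet_S, iu):
    p = len(fidx)
    lam = params[:p]
    Phi = np.eye(K)
    if iu[0].size:
        Phi[iu] = params[p:]
        Phi[(iu[1], iu[0])] = params[p:]
    L = np.zeros((p, K))
    L[np.arange(p), fidx] = lam
    resid = 1.0 - lam**2
    floored = resid < _RESID_FLOOR
    resid = np.maximum(resid, _RESID_FLOOR)
    Sigma = L @ Phi @ L.T + np.diag(resid)
    try:
        c, low = cho_factor(Sigma, check_finite=False)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(params)
    logdet_Sigma = 2.0 * float(np.sum(np.log(np.diag(c))))
    Sigma_inv = cho_solve((c, low), np.eye(p), check_finite=False)
    F = logdet_Sigma - logdet_S + float(np.sum(Sigma_inv * S)) - p
    A = Sigma_inv - Sigma_inv @ S @ Sigma_inv
    M = A @ L @ Phi
    g_lam = 2.0 * M[np.arange(p), fidx] - 2.0 * lam * np.diag(A) * (~floored)
    if iu[0].size:
        B = L.T @ A @ L
        g_phi = 2.0 * B[iu]
        grad = np.concatenate([g_lam, g_phi])
    else:
        grad = g_lam
    return F, grad


def fit_cfa(
    corr: np.ndarray,
    scale: ScaleDefinition,
    n_obs: int,
    *,
    max_restarts: int = 3,
) -> CfaFit:
    """Fit the simple-structure model to a correlation matrix.

    ``corr`` must cover exactly ``scale.item_ids`` in order.  Starts at
    ``lambda = 0.7`` and factor correlations 0.5; on optimizer failure the
    start is jittered (deterministically) up to ``max_restarts`` times.
    """
    S = np.asarray(corr, dtype=float)
    p = scale.n_items
    if S.shape != (p, p):
        raise ValueError("correlation matrix does not match the scale's items")
    factors = scale.factors
    K = len(factors)
    fidx = np.array([factors.index(scale.factor_of[i]) for i in scale.item_ids])
    for f in factors:
        n_f = len(scale.items_in(f))
        if n_f < 2:
            raise ValueError(f"factor {f!r} has {n_f} item(s); at least 2 required")
        if n_f == 2 and K == 1:
            raise ValueError("a lone 2-item factor is under-identified")
    iu = np.triu_indices(K, 1)
    q = iu[0].size
    df = model_df(p, q)

    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("correlation matrix is not positive definite")

    x0 = np.concatenate([np.full(p, 0.7), np.full(q, 0.5)])
    bounds = [(-_LAMBDA_BOUND, _LAMBDA_BOUND)] * p + [(-_PHI_BOUND, _PHI_BOUND)] * q
    rng = np.random.default_rng(987654321)  # fixed: restarts stay deterministic
    best = None
    for attempt in range(max_restarts + 1):
        start = x0 if attempt == 0 else np.clip(
            x0 + rng.uniform(-0.25, 0.25, x0.size), -0.9, 0.9
        )
        res = minimize(
            _discrepancy_and_grad,
            start,
            args=(S, fidx, K, logdet_S, iu),
            method="L-BFGS-B",
            jac=True,
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
    assert best is not None
    lam = best.x[:p]
    # per-factor sign indeterminacy: report the positive orientation
    for k in range(K):
        mask = fidx == k
        if lam[mask].sum() < 0:
            lam[mask] = -lam[mask]
            if q:
                for j in range(q):
                    if iu[0][j] == k or iu[1][j] == k:
                        best.x[p + j] = -best.x[p + j]
    Phi = np.eye(K)
    if q:
        Phi[iu] = best.x[p:]
        Phi[(iu[1], iu[0])] = best.x[p:]
    # a residual variance at its floor means the solution sits on (or past)
    # the |lambda| = 1 boundary: an inadmissible Heywood case
    heywood = bool(np.any(np.abs(lam) >= np.sqrt(1.0 - _RESID_FLOOR)))
    lam_report = np.clip(lam, -0.999, 0.999)
    F = max(float(best.fun), 0.0)
    stat_T = (n_obs - 1) * F
    baseline_T = (n_obs - 1) * (-logdet_S)  # F(S, I) = -log|S| for unit-diagonal S
    baseline_df = p * (p - 1) // 2
    cfi, rmsea = fit_indices(stat_T, df, baseline_T, baseline_df, n_obs)
    omegas: dict[str, float] = {}
    if not heywood:
        for k, f in enumerate(factors):
            omegas[f] = omega(lam[fidx == k])
    return CfaFit(
        item_ids=scale.item_ids,
        factors=factors,
        loadings={i: float(l) for i, l in zip(scale.item_ids, lam_report)},
        factor_corr=Phi,
        stat_T=float(stat_T),
        df=df,
        baseline_T=float(baseline_T),
        baseline_df=baseline_df,
        cfi=cfi,
        rmsea=rmsea,
        omega_by_factor=omegas,
        converged=bool(best.success),
        heywood=heywood,
        n_obs=int(n_obs),
        discrepancy=F,
    )
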