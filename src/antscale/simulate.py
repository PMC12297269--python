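"""Ordinal response simulation from a simple-structure factor model.

Factor scores are drawn from a zero-mean multivariate normal with the factor
correlation matrix Phi; each latent item score is
``y* = lambda * f + sqrt(1 - lambda^2) * eps`` with independent standard
normal noise, then discretized into ``1..C`` by per-item thresholds.
Default thresholds are equal-probability quantile cuts, which keep every
category equally populated; a skewed preset is available because real
Likert items are rarely symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.stats import norm

from . import adbs
from .scale import ResponseMatrix, ScaleDefinition

__all__ = [
    "GeneratorSpec",
    "default_thresholds",
    "skewed_thresholds",
    "generate_responses",
    "paper_like_spec",
    "planted_optimum_spec",
    "scale_from_spec",
]


def default_thresholds(n_categories: int = 5) -> np.ndarray:
    """Equal-probability cuts: each category holds 1/C of the latent mass."""
    probs = np.arange(1, n_categories) / n_categories
    return norm.ppf(probs)


def skewed_thresholds(n_categories: int = 5, shift: float = 0.6) -> np.ndarray:
    """Right-shifted cuts emulating items most respondents rate low."""
    return default_thresholds(n_categories) + shift


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything needed to simulate one ordinal dataset."""

    loadings: Mapping[str, float]
    factor_of: Mapping[str, str]
    factor_corr: np.ndarray
    n_obs: int
    seed: int
    n_categories: int = 5
    thresholds: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, lam in self.loadings.items():
            if abs(lam) >= 1:
                raise ValueError(f"|loading| must be < 1 (item {i!r})")
        Phi = np.asarray(self.factor_corr, dtype=float)
        if not np.allclose(Phi, Phi.T) or not np.allclose(np.diag(Phi), 1.0):
            raise ValueError("factor_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(Phi).min() <= 0:
            raise ValueError("factor_corr must be positive definite")
        for i, t in self.thresholds.items():
            t = np.asarray(t)
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"thresholds must strictly increase (item {i!r})")

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(self.loadings)

    @property
    def factors(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for i in self.item_ids:
            seen.setdefault(self.factor_of[i], None)
        return tuple(seen)

    def thresholds_for(self, item: str) -> np.ndarray:
        if item in self.thresholds:
            return np.asarray(self.thresholds[item], dtype=float)
        return default_thresholds(self.n_categories)


def generate_responses(spec: GeneratorSpec) -> ResponseMatrix:
    """Simulate an ``n_obs x p`` integer response matrix, deterministic per seed.

    Factor scores are drawn first, then item noise in item-id order, so the
    stream of random draws (and hence the data) is pinned by the seed.
    """
    rng = np.random.default_rng(spec.seed)
    factors = spec.factors
    K = len(factors)
    chol = np.linalg.cholesky(np.asarray(spec.factor_corr, dtype=float))
    F = rng.standard_normal((spec.n_obs, K)) @ chol.T
    fcol = {f: k for k, f in enumerate(factors)}
    out = np.empty((spec.n_obs, len(spec.item_ids)), dtype=np.int64)
    for j, item in enumerate(spec.item_ids):
        lam = spec.loadings[item]
        eps = rng.standard_normal(spec.n_obs)
        y = lam * F[:, fcol[spec.factor_of[item]]] + np.sqrt(1 - lam**2) * eps
        out[:, j] = np.searchsorted(spec.thresholds_for(item), y) + 1
    return ResponseMatrix(out, spec.item_ids)


def scale_from_spec(
    spec: GeneratorSpec, select_counts: Mapping[str, int] | None = None
) -> ScaleDefinition:
    """The ScaleDefinition matching a generator spec (quota = pool size if
    not given)."""
    counts = dict(select_counts) if select_counts else {
        f: sum(1 for i in spec.item_ids if spec.factor_of[i] == f)
        for f in spec.factors
    }
    return ScaleDefinition(spec.item_ids, dict(spec.factor_of), counts,
                           spec.n_categories)


def paper_like_spec(n_obs: int = 2000, seed: int = 0) -> GeneratorSpec:
    """A two-factor pool emulating the published ADBS validation structure.

    26 items (13 pros of drinking, 13 cons), the published full-pool
    standardized loadings (0.25..0.94), and a pros-cons factor correlation
    of 0.56, on a 5-point response format.
    """
    return GeneratorSpec(
        loadings=dict(adbs.FULL_POOL_LOADINGS),
        factor_of=dict(adbs.FACTOR_OF),
        factor_corr=np.array([[1.0, adbs.FACTOR_CORRELATION],
                              [adbs.FACTOR_CORRELATION, 1.0]]),
        n_obs=n_obs,
        seed=seed,
    )


def planted_optimum_spec(
    pool_sizes: tuple[int, int] = (6, 6),
    quota: tuple[int, int] = (3, 3),
    high: float = 0.9,
    low: float = 0.3,
    factor_corr: float = 0.5,
    n_obs: int = 500,
    seed: int = 0,
) -> tuple[GeneratorSpec, ScaleDefinition, "frozenset[str]"]:
    """A pool whose best subset is known by construction.

    The first ``quota`` items of each factor load at ``high``; the rest at
    ``low``.  At large N the high-loading subset dominates every pheromone
    criterion.  Returns (spec, scale with the quotas, planted item set).
    """
    labels = ("pros", "cons")
    loadings: dict[str, float] = {}
    factor_of: dict[str, str] = {}
    planted: list[str] = []
    for f, size, k, prefix in zip(labels, pool_sizes, quota, ("p", "c")):
        for j in range(1, size + 1):
            item = f"{prefix}{j:02d}"
            loadings[item] = high if j <= k else low
            factor_of[item] = f
            if j <= k:
                planted.append(item)
    spec = GeneratorSpec(
        loadings=loadings,
        factor_of=factor_of,
        factor_corr=np.array([[1.0, factor_corr], [factor_corr, 1.0]]),
        n_obs=n_obs,
        seed=seed,
    )
    scale = ScaleDefinition(
        tuple(loadings), factor_of,
        {labels[0]: quota[0], labels[1]: quota[1]}, 5,
    )
    return spec, scale, frozenset(planted)
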