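"""The ant-colony search over item subsets.

Each "ant" samples one candidate short form: within every factor it draws the
quota of items sequentially without replacement, with probability
proportional to the items' pheromone levels tau.  Candidates are scored by
the pheromone objective (see :mod:`antscale.pheromone`) against a full-pool
reference fit.  After each iteration every tau decays multiplicatively by the
evaporation rate and the iteration-best candidate deposits its total
pheromone onto its members.  The loop stops when the best-so-far candidate
has not improved for ``patience`` consecutive iterations, or at
``max_iterations``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Mapping, MutableMapping

import numpy as np

from .cfa import CfaFit, fit_cfa
from .pheromone import PheromoneComponents, total_pheromone
from .polychoric import PolychoricMatrix, polychoric_matrix
from .scale import ItemSubset, ResponseMatrix, ScaleDefinition

__all__ = [
    "AcoConfig",
    "PheromoneState",
    "ReferenceFit",
    "SubsetEvaluation",
    "AcoRunResult",
    "TAU_MIN",
    "compute_reference",
    "sample_subset",
    "evaluate_subset",
    "update_pheromone",
    "run_aco",
    "run_many",
]

log = logging.getLogger(__name__)

TAU_MIN = 1e-6


@dataclass(frozen=True)
class AcoConfig:
    """Search parameters.

    Defaults sit in the regions where the search behaves consistently on
    two-factor Likert pools of this size: 60 ants, up to 50 iterations,
    evaporation 0.5, stagnation patience 15, and 5 independent runs seeded
    ``seed + r``.
    """

    n_ants: int = 60
    max_iterations: int = 50
    evaporation: float = 0.5
    patience: int = 15
    seed: int = 0
    n_runs: int = 5

    def __post_init__(self) -> None:
        if self.n_ants < 1:
            raise ValueError("n_ants must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")
        if not 0.0 < self.evaporation <= 1.0:
            raise ValueError("evaporation must be in (0, 1]")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be positive")


@dataclass
class PheromoneState:
    """Per-item pheromone levels tau driving ant sampling."""

    tau: MutableMapping[str, float]

    @classmethod
    def initial(cls, scale: ScaleDefinition, level: float = 1.0) -> "PheromoneState":
        # equal levels: the first iteration samples uniformly
        return cls({i: level for i in scale.item_ids})

    @classmethod
    def initial_for(cls, scale: ScaleDefinition, config: "AcoConfig") -> "PheromoneState":
        """Equal start at the steady-state pheromone ceiling.

        Under decay-then-deposit updates the pheromone of a persistently
        winning item converges to ``deposit / (1 - evaporation)``; with the
        objective bounded by 4 this gives ``4 / (1 - evaporation)``.  Starting
        every item at that ceiling keeps early iterations exploratory instead
        of letting the first deposit dominate sampling immediately (the
        max-min initialization of the ACO literature).  With evaporation 1
        (no decay) the ceiling is unbounded; fall back to the objective bound.
        """
        if config.evaporation < 1.0:
            level = 4.0 / (1.0 - config.evaporation)
        else:
            level = 4.0
        return cls({i: level for i in scale.item_ids})


@dataclass(frozen=True)
class ReferenceFit:
    """Full-pool anchor: CFA fit plus per-factor unit-weight sum scores."""

    fit: CfaFit
    sum_scores: Mapping[str, np.ndarray]

    @property
    def factor_corr(self) -> np.ndarray:
        return self.fit.factor_corr


@dataclass(frozen=True)
class SubsetEvaluation:
    subset: ItemSubset
    fit: CfaFit | None
    components: PheromoneComponents

    @property
    def phi_total(self) -> float:
        return self.components.phi_total

    def to_dict(self) -> dict:
        return {
            "subset": {f: list(its) for f, its in self.subset.by_factor.items()},
            "fit": self.fit.to_dict() if self.fit is not None else None,
            "components": self.components.to_dict(),
        }


@dataclass(frozen=True)
class AcoRunResult:
    best: SubsetEvaluation
    trace: tuple[dict[str, Any], ...]
    iterations_executed: int
    converged_early: bool
    seed: int

    def to_dict(self) -> dict:
        return {
            "best": self.best.to_dict(),
            "iterations_executed": self.iterations_executed,
            "converged_early": self.converged_early,
            "seed": self.seed,
        }


def compute_reference(
    data: ResponseMatrix,
    scale: ScaleDefinition,
    corr: PolychoricMatrix | None = None,
) -> ReferenceFit:
    """Fit the full item pool and store per-factor full-scale sum scores."""
    if corr is None:
        corr = polychoric_matrix(data)
    fit = fit_cfa(corr.submatrix(scale.item_ids), scale.restrict(scale.item_ids),
                  data.n_obs)
    if not fit.converged:
        raise RuntimeError("reference (full-pool) CFA did not converge")
    sums = {
        f: data.subset(scale.items_in(f)).values.sum(axis=1).astype(float)
        for f in scale.factors
    }
    return ReferenceFit(fit, sums)


def sample_subset(
    state: PheromoneState, scale: ScaleDefinition, rng: np.random.Generator
) -> ItemSubset:
    """Draw one candidate: per factor, quota items without replacement,
    each draw proportional to tau over the remaining candidates."""
    by_factor: dict[str, tuple[str, ...]] = {}
    for f in scale.factors:
        cand = list(scale.items_in(f))
        w = np.array([state.tau[i] for i in cand], dtype=float)
        chosen: list[str] = []
        for _ in range(scale.select_counts[f]):
            probs = w / w.sum()
            j = int(rng.choice(len(cand), p=probs))
            chosen.append(cand.pop(j))
            w = np.delete(w, j)
        by_factor[f] = tuple(chosen)
    return ItemSubset(by_factor)


def evaluate_subset(
    subset: ItemSubset,
    data: ResponseMatrix,
    corr: PolychoricMatrix,
    reference: ReferenceFit,
) -> SubsetEvaluation:
    """Score one candidate against the full-pool reference.

    Fits the subset CFA on the corresponding rows/columns of the (already
    estimated) polychoric matrix, computes per-factor omega, Pearson
    correlations between short-form and full-form unit-weight sum scores on
    the raw responses, and the factor-correlation deviation from the
    reference; non-converged or Heywood fits are infeasible (phi_total 0).
    """
    items = subset.all_items
    sub_scale = _subset_scale(subset, n_categories=int(data.values.max()))
    fit = fit_cfa(corr.submatrix(items), sub_scale, data.n_obs)
    if not fit.converged or fit.heywood:
        reason = "heywood" if fit.heywood else "non-converged"
        return SubsetEvaluation(
            subset, fit, total_pheromone(0, 0, [0], [0], 0, feasible=False,
                                         reason=reason)
        )
    factors = sub_scale.factors
    cors = []
    for f in factors:
        short = data.subset(subset.by_factor[f]).values.sum(axis=1).astype(float)
        full = reference.sum_scores[f]
        cors.append(float(np.corrcoef(short, full)[0, 1]))
    K = len(factors)
    if K >= 2:
        iu = np.triu_indices(K, 1)
        diff = float(np.max(np.abs(fit.factor_corr[iu] - reference.factor_corr[iu])))
    else:
        diff = 0.0
    comps = total_pheromone(
        fit.cfi, fit.rmsea,
        [fit.omega_by_factor[f] for f in factors],
        cors, diff,
    )
    return SubsetEvaluation(subset, fit, comps)


def _subset_scale(subset: ItemSubset, n_categories: int) -> ScaleDefinition:
    factor_of = {i: f for f, its in subset.by_factor.items() for i in its}
    counts = {f: len(its) for f, its in subset.by_factor.items()}
    return ScaleDefinition(tuple(sorted(subset.all_items)), factor_of, counts,
                           n_categories=max(n_categories, 2))


def update_pheromone(
    state: PheromoneState,
    iteration_best: SubsetEvaluation,
    evaporation: float,
) -> PheromoneState:
    """Multiplicative decay everywhere, additive deposit on the iteration
    best's members, then the tau floor."""
    deposit = iteration_best.phi_total
    members = set(iteration_best.subset.all_items)
    new_tau = {}
    for item, t in state.tau.items():
        t = evaporation * t
        if item in members:
            t += deposit
        new_tau[item] = max(t, TAU_MIN)
    return PheromoneState(new_tau)


def run_aco(
    data: ResponseMatrix,
    scale: ScaleDefinition,
    config: AcoConfig,
    *,
    corr: PolychoricMatrix | None = None,
    reference: ReferenceFit | None = None,
    cache: MutableMapping[tuple[str, ...], SubsetEvaluation] | None = None,
) -> AcoRunResult:
    """One ant-colony run; deterministic for a given seed.

    Identical subsets sampled within (or across) iterations are evaluated
    once via the cache keyed by the sorted item tuple.  Ties for the
    iteration best and best-so-far break toward the lexicographically
    smallest sorted item tuple; the best-so-far is replaced only on strict
    improvement.
    """
    if corr is None:
        corr = polychoric_matrix(data)
    if reference is None:
        reference = compute_reference(data, scale, corr)
    if cache is None:
        cache = {}
    rng = np.random.default_rng(config.seed)
    state = PheromoneState.initial_for(scale, config)
    best: SubsetEvaluation | None = None
    trace: list[dict[str, Any]] = []
    stagnation = 0
    converged_early = False
    iterations = 0
    for it in range(1, config.max_iterations + 1):
        iterations = it
        seen: dict[tuple[str, ...], SubsetEvaluation] = {}
        for _ in range(config.n_ants):
            subset = sample_subset(state, scale, rng)
            k = subset.key
            if k in seen:
                continue
            if k not in cache:
                cache[k] = evaluate_subset(subset, data, corr, reference)
            seen[k] = cache[k]
        # iteration best: highest phi_total, lexicographic key on ties
        it_best = max(seen.values(), key=lambda e: (e.phi_total,
                                                    _neg_key(e.subset.key)))
        improved = False
        if best is None or it_best.phi_total > best.phi_total:
            best = it_best
            improved = True
        log.info("iteration %d: best phi %.5f (so far %.5f)",
                 it, it_best.phi_total, best.phi_total)
        trace.append({
            "iteration": it,
            "iteration_best_phi": it_best.phi_total,
            "best_phi": best.phi_total,
            "best_items": list(best.subset.key),
            "n_unique_subsets": len(seen),
        })
        state = update_pheromone(state, it_best, config.evaporation)
        stagnation = 0 if improved else stagnation + 1
        if stagnation >= config.patience:
            converged_early = it < config.max_iterations
            break
    assert best is not None
    return AcoRunResult(best, tuple(trace), iterations, converged_early,
                        config.seed)


class _neg_key:
    """Orders lexicographically *smaller* item tuples as *larger* for max()."""

    __slots__ = ("k",)

    def __init__(self, k: tuple[str, ...]) -> None:
        self.k = k

    def __lt__(self, other: "_neg_key") -> bool:
        return self.k > other.k

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _neg_key) and self.k == other.k


def run_many(
    data: ResponseMatrix,
    scale: ScaleDefinition,
    config: AcoConfig,
    *,
    corr: PolychoricMatrix | None = None,
    reference: ReferenceFit | None = None,
    share_cache: bool = True,
) -> list[AcoRunResult]:
    """``config.n_runs`` independent runs with seeds ``seed + r``.

    The polychoric matrix and reference fit are computed once; subset
    evaluations are deterministic given the data, so the evaluation cache may
    be shared across runs (pure memoization).
    """
    if corr is None:
        corr = polychoric_matrix(data)
    if reference is None:
        reference = compute_reference(data, scale, corr)
    cache: dict[tuple[str, ...], SubsetEvaluation] | None = {} if share_cache else None
    results = []
    for r in range(config.n_runs):
        cfg = AcoConfig(
            n_ants=config.n_ants,
            max_iterations=config.max_iterations,
            evaporation=config.evaporation,
            patience=config.patience,
            seed=config.seed + r,
            n_runs=1,
        )
        results.append(
            run_aco(data, scale, cfg, corr=corr, reference=reference,
                    cache=cache if share_cache else {})
        )
    return results
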