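"""Aggregating runs into final scales; comparison baselines and reports.

Two aggregation rules turn a batch of independent ACO runs into a short form:

* **best-pheromone (ACO-P)** — the subset of the run whose best candidate has
  the highest total pheromone across all runs;
* **consensus (ACO-C)** — every item selected in at least a threshold
  fraction (default 60%) of the per-run best subsets.  The consensus set can
  have unequal factor sizes; no re-balancing is applied.

The classical baseline keeps, per factor, the quota items with the highest
full-pool loadings.  ``comparison_report`` evaluates any labeled collection
of subsets through the identical pipeline the ants use, for a like-for-like
table.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aco import (
    AcoRunResult,
    ReferenceFit,
    SubsetEvaluation,
    evaluate_subset,
)
from .polychoric import PolychoricMatrix
from .scale import ItemSubset, ResponseMatrix, ScaleDefinition

__all__ = [
    "ConsensusResult",
    "select_aco_p",
    "select_aco_c",
    "consensus",
    "baseline_top_loadings",
    "evaluate_fixed_subset",
    "enumerate_subsets",
    "exhaustive_search",
    "comparison_report",
]


@dataclass(frozen=True)
class ConsensusResult:
    """ACO-P / ACO-C aggregation of a batch of runs."""

    aco_p: ItemSubset
    aco_c: tuple[str, ...]
    frequency: Mapping[str, int]
    n_runs: int
    threshold: float
    per_run_best: tuple[SubsetEvaluation, ...]

    def to_dict(self) -> dict:
        return {
            "aco_p": {f: list(its) for f, its in self.aco_p.by_factor.items()},
            "aco_c": list(self.aco_c),
            "frequency": dict(self.frequency),
            "n_runs": self.n_runs,
            "threshold": self.threshold,
            "per_run_best_phi": [e.phi_total for e in self.per_run_best],
        }


def select_aco_p(run_results: Sequence[AcoRunResult]) -> ItemSubset:
    """The subset of the run with the overall highest pheromone.

    Ties break toward the lexicographically smallest sorted item tuple.
    """
    if not run_results:
        raise ValueError("no runs")
    feasible = [r for r in run_results if r.best.phi_total > 0]
    if not feasible:
        raise RuntimeError("all runs produced infeasible best subsets")
    best_phi = max(r.best.phi_total for r in feasible)
    winners = [r.best.subset for r in feasible if r.best.phi_total == best_phi]
    return min(winners, key=lambda s: s.key)


def select_aco_c(
    run_results: Sequence[AcoRunResult], threshold: float = 0.6
) -> tuple[tuple[str, ...], dict[str, int]]:
    """Items selected in at least ``threshold`` of the per-run best subsets.

    Returns the sorted consensus item tuple and the full frequency map.
    """
    if len(run_results) < 2:
        raise ValueError("consensus needs at least 2 runs")
    counts: Counter[str] = Counter()
    for r in run_results:
        counts.update(r.best.subset.all_items)
    n = len(run_results)
    chosen = tuple(sorted(i for i, c in counts.items() if c / n >= threshold))
    if not chosen:
        warnings.warn("empty consensus set at this threshold", RuntimeWarning,
                      stacklevel=2)
    return chosen, dict(counts)


def consensus(
    run_results: Sequence[AcoRunResult], threshold: float = 0.6
) -> ConsensusResult:
    chosen, counts = select_aco_c(run_results, threshold)
    return ConsensusResult(
        aco_p=select_aco_p(run_results),
        aco_c=chosen,
        frequency=counts,
        n_runs=len(run_results),
        threshold=threshold,
        per_run_best=tuple(r.best for r in run_results),
    )


def subset_from_items(items: Iterable[str], scale: ScaleDefinition) -> ItemSubset:
    """Group a flat item collection by the scale's factor membership."""
    by_factor: dict[str, list[str]] = {}
    for i in items:
        by_factor.setdefault(scale.factor_of[i], []).append(i)
    return ItemSubset({f: tuple(its) for f, its in by_factor.items()})


def baseline_top_loadings(
    reference: ReferenceFit, scale: ScaleDefinition
) -> ItemSubset:
    """Per factor, the quota items with the highest full-pool loadings
    (ties break lexicographically by item id)."""
    if not reference.fit.converged:
        raise ValueError("reference fit did not converge")
    lam = reference.fit.loadings
    by_factor = {}
    for f in scale.factors:
        pool = sorted(scale.items_in(f), key=lambda i: (-lam[i], i))
        by_factor[f] = tuple(pool[: scale.select_counts[f]])
    return ItemSubset(by_factor)


def evaluate_fixed_subset(
    subset: ItemSubset,
    data: ResponseMatrix,
    corr: PolychoricMatrix,
    reference: ReferenceFit,
) -> SubsetEvaluation:
    """Score an externally given subset through the ants' pipeline."""
    subset.validate_against(_pool_scale(data, subset), quotas=False)
    return evaluate_subset(subset, data, corr, reference)


def _pool_scale(data: ResponseMatrix, subset: ItemSubset) -> ScaleDefinition:
    # permissive container scale: every subset item assigned to its own factor
    factor_of = {i: f for f, its in subset.by_factor.items() for i in its}
    ids = tuple(i for i in data.item_ids if i in factor_of)
    counts = {f: len(its) for f, its in subset.by_factor.items()}
    return ScaleDefinition(ids, factor_of, counts,
                           n_categories=int(data.values.max()))


def enumerate_subsets(scale: ScaleDefinition) -> list[ItemSubset]:
    """All quota-respecting subsets, in deterministic lexicographic order."""
    per_factor = []
    for f in scale.factors:
        combos = itertools.combinations(sorted(scale.items_in(f)),
                                        scale.select_counts[f])
        per_factor.append([(f, c) for c in combos])
    out = []
    for combo in itertools.product(*per_factor):
        out.append(ItemSubset({f: its for f, its in combo}))
    return out


def exhaustive_search(
    data: ResponseMatrix,
    scale: ScaleDefinition,
    corr: PolychoricMatrix,
    reference: ReferenceFit,
) -> tuple[SubsetEvaluation, list[SubsetEvaluation]]:
    """Evaluate every candidate subset (the brute-force oracle).

    Returns the best evaluation (ties lexicographic) and the full list.
    """
    evals = [evaluate_subset(s, data, corr, reference)
             for s in enumerate_subsets(scale)]
    best = max(evals, key=lambda e: e.phi_total)
    ties = [e for e in evals if e.phi_total == best.phi_total]
    best = min(ties, key=lambda e: e.subset.key)
    return best, evals


def comparison_report(
    evaluations: Sequence[tuple[str, SubsetEvaluation]]
) -> pd.DataFrame:
    """One row per labeled scale: test statistic, df, CFI, RMSEA, per-factor
    omega, loading summaries, factor correlation, and total pheromone.

    Values are carried at full precision; round only when rendering.
    """
    if not evaluations:
        raise ValueError("no evaluations to report")
    rows = []
    for label, ev in evaluations:
        fit = ev.fit
        row: dict[str, object] = {"scale": label}
        if fit is None:
            rows.append(row)
            continue
        row.update({
            "stat_T": fit.stat_T,
            "df": fit.df,
            "cfi": fit.cfi,
            "rmsea": fit.rmsea,
        })
        for f, w in fit.omega_by_factor.items():
            row[f"omega_{f}"] = w
        lam = np.array(list(fit.loadings.values()))
        row["loading_mean"] = float(lam.mean())
        row["loading_min"] = float(lam.min())
        row["loading_max"] = float(lam.max())
        if len(fit.factors) == 2:
            row["factor_corr"] = fit.factor_corr_value
        row["phi_total"] = ev.phi_total
        rows.append(row)
    return pd.DataFrame(rows).set_index("scale")


def render_report(df: pd.DataFrame) -> str:
    """Human-readable text table (3-decimal rounding at render time only)."""
    return df.round(3).to_string()
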