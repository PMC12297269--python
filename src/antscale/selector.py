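"""scikit-learn estimator surface for ant-colony item selection.

:class:`AntColonyItemSelector` is a feature selector in the sklearn sense:
``fit(X)`` runs the full pipeline (polychoric matrix, full-pool reference
CFA, multiple ACO runs, consensus aggregation) and ``transform(X)`` keeps
the columns of the best-pheromone short form.  It composes with sklearn
pipelines and model selection; all heavy lifting lives in the functional
modules it wraps.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .aco import AcoConfig, compute_reference, run_many
from .io import responses_from_dataframe
from .polychoric import polychoric_matrix
from .scale import ResponseMatrix, ScaleDefinition
from .selection import baseline_top_loadings, consensus

__all__ = ["AntColonyItemSelector"]


class AntColonyItemSelector(SelectorMixin, BaseEstimator):
    """Select a short form from a Likert item pool by ant-colony search.

    Parameters
    ----------
    factors : mapping of factor label -> sequence of item ids
        The item pool with its factor structure.
    select : mapping of factor label -> int
        Items to keep per factor.
    n_categories : int, default=5
        Number of ordered response categories (integers ``1..C``).
    n_ants, max_iterations, evaporation, patience : search parameters
        See :class:`antscale.aco.AcoConfig`.
    n_runs : int, default=5
        Independent runs aggregated into the final selection.
    consensus_threshold : float, default=0.6
        Minimum selection fraction for the consensus (ACO-C) item set.
    random_state : int, default=0
        Base seed; run ``r`` uses ``random_state + r``.

    Attributes
    ----------
    selected_items_ : tuple of str
        The best-pheromone (ACO-P) short form, sorted.
    consensus_items_ : tuple of str
        The consensus (ACO-C) item set (may violate quotas).
    best_score_ : float
        Total pheromone of the selected subset.
    runs_ : list of AcoRunResult
    consensus_ : ConsensusResult
    reference_ : ReferenceFit
        Full-pool CFA fit and per-factor sum scores.
    baseline_items_ : tuple of str
        The highest-loading baseline selection, for comparison.
    """

    def __init__(
        self,
        factors: Mapping[str, Sequence[str]] | None = None,
        select: Mapping[str, int] | None = None,
        *,
        n_categories: int = 5,
        n_ants: int = 60,
        max_iterations: int = 50,
        evaporation: float = 0.5,
        patience: int = 15,
        n_runs: int = 5,
        consensus_threshold: float = 0.6,
        random_state: int = 0,
    ) -> None:
        self.factors = factors
        self.select = select
        self.n_categories = n_categories
        self.n_ants = n_ants
        self.max_iterations = max_iterations
        self.evaporation = evaporation
        self.patience = patience
        self.n_runs = n_runs
        self.consensus_threshold = consensus_threshold
        self.random_state = random_state

    def _build_scale(self, feature_names: Sequence[str]) -> ScaleDefinition:
        if self.factors is None or self.select is None:
            raise ValueError("factors and select must be provided")
        factor_of = {str(i): str(f) for f, its in self.factors.items()
                     for i in its}
        item_ids = tuple(i for i in feature_names if i in factor_of)
        if len(item_ids) != len(factor_of):
            missing = sorted(set(factor_of) - set(item_ids))
            raise ValueError(f"input data lacks columns for items: {missing}")
        return ScaleDefinition(
            item_ids, factor_of,
            {str(f): int(k) for f, k in self.select.items()},
            self.n_categories,
        )

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            frame = X
        else:
            X = np.asarray(X)
            if self.factors is None:
                raise ValueError("factors must be provided")
            names = [i for f in self.factors for i in self.factors[f]]
            if X.shape[1] != len(names):
                raise ValueError(
                    "array input must have one column per pool item, in "
                    "factor-definition order"
                )
            frame = pd.DataFrame(X, columns=names)
        scale = self._build_scale(names)
        data: ResponseMatrix = responses_from_dataframe(frame, scale)
        corr = polychoric_matrix(data)
        reference = compute_reference(data, scale, corr)
        config = AcoConfig(
            n_ants=self.n_ants,
            max_iterations=self.max_iterations,
            evaporation=self.evaporation,
            patience=self.patience,
            seed=self.random_state,
            n_runs=self.n_runs,
        )
        runs = run_many(data, scale, config, corr=corr, reference=reference)
        agg = consensus(runs, self.consensus_threshold)

        self.n_features_in_ = len(names)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.scale_ = scale
        self.polychoric_ = corr
        self.reference_ = reference
        self.runs_ = runs
        self.consensus_ = agg
        self.selected_items_ = agg.aco_p.key
        self.consensus_items_ = agg.aco_c
        self.best_score_ = max(r.best.phi_total for r in runs)
        self.baseline_items_ = baseline_top_loadings(reference, scale).key
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "selected_items_")
        keep = set(self.selected_items_)
        return np.array([n in keep for n in self.feature_names_in_], dtype=bool)
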