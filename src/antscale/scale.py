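"""Core data types for short-scale construction.

A questionnaire is described by a :class:`ScaleDefinition`: which items exist,
which factor each item measures, and how many items the short form should keep
per factor.  Respondent data lives in a :class:`ResponseMatrix` of integer
Likert categories.  Candidate short forms are :class:`ItemSubset` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = ["ScaleDefinition", "ResponseMatrix", "ItemSubset"]


@dataclass(frozen=True)
class ScaleDefinition:
    """Item pool, factor membership, and per-factor selection quota.

    Parameters
    ----------
    item_ids : tuple of str
        Ordered unique item identifiers.  All tie-breaks downstream are
        lexicographic over these opaque strings.
    factor_of : mapping of item id -> factor label
        Every item belongs to exactly one factor.
    select_counts : mapping of factor label -> int
        Number of items the short form keeps from each factor;
        ``1 <= quota <= pool size``.
    n_categories : int
        Number of ordered response categories ``C`` (categories are the
        consecutive integers ``1..C``), default 5.
    """

    item_ids: tuple[str, ...]
    factor_of: Mapping[str, str]
    select_counts: Mapping[str, int]
    n_categories: int = 5

    def __post_init__(self) -> None:
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError("duplicate item ids in scale definition")
        if self.n_categories < 2:
            raise ValueError("n_categories must be >= 2")
        missing = [i for i in self.item_ids if i not in self.factor_of]
        if missing:
            raise ValueError(f"items without factor assignment: {missing}")
        extra = set(self.factor_of) - set(self.item_ids)
        if extra:
            raise ValueError(f"factor_of mentions unknown items: {sorted(extra)}")
        for f, k in self.select_counts.items():
            pool = self.items_in(f)
            if not pool:
                raise ValueError(f"factor {f!r} has no items")
            if not 1 <= k <= len(pool):
                raise ValueError(
                    f"quota {k} for factor {f!r} outside 1..{len(pool)}"
                )
        unknown = set(self.select_counts) - set(self.factors)
        if unknown:
            raise ValueError(f"select_counts for unknown factors: {sorted(unknown)}")
        # latent identifiability: >= 2 factors, or one factor with >= 3 items kept
        if len(self.factors) == 1:
            (f,) = self.factors
            if self.select_counts.get(f, len(self.items_in(f))) < 3:
                raise ValueError(
                    "a single-factor model needs at least 3 items for identification"
                )

    @property
    def factors(self) -> tuple[str, ...]:
        """Factor labels in order of first appearance along ``item_ids``."""
        seen: dict[str, None] = {}
        for i in self.item_ids:
            seen.setdefault(self.factor_of[i], None)
        return tuple(seen)

    def items_in(self, factor: str) -> tuple[str, ...]:
        return tuple(i for i in self.item_ids if self.factor_of[i] == factor)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def restrict(self, items: Iterable[str]) -> "ScaleDefinition":
        """A sub-scale over ``items`` (quota = pool size per factor)."""
        keep = set(items)
        unknown = keep - set(self.item_ids)
        if unknown:
            raise ValueError(f"unknown items: {sorted(unknown)}")
        ids = tuple(i for i in self.item_ids if i in keep)
        fac = {i: self.factor_of[i] for i in ids}
        counts: dict[str, int] = {}
        for i in ids:
            counts[fac[i]] = counts.get(fac[i], 0) + 1
        return ScaleDefinition(ids, fac, counts, self.n_categories)


@dataclass(frozen=True)
class ResponseMatrix:
    """Complete-case integer Likert responses, columns aligned to a scale.

    ``values`` is an ``N x p`` integer array with entries in ``1..C``;
    ``item_ids`` labels the columns; ``n_dropped`` counts rows removed by
    listwise deletion during reading.
    """

    values: np.ndarray
    item_ids: tuple[str, ...]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("responses must be a 2-D array")
        if v.shape[1] != len(self.item_ids):
            raise ValueError("column count does not match item_ids")
        if v.shape[0] == 0:
            raise ValueError("no complete response rows")
        object.__setattr__(self, "values", v.astype(np.int64, copy=False))

    @property
    def n_obs(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_items(self) -> int:
        return int(self.values.shape[1])

    def column(self, item_id: str) -> np.ndarray:
        return self.values[:, self.item_ids.index(item_id)]

    def subset(self, items: Iterable[str]) -> "ResponseMatrix":
        items = tuple(items)
        idx = [self.item_ids.index(i) for i in items]
        return ResponseMatrix(self.values[:, idx], items, self.n_dropped)


@dataclass(frozen=True)
class ItemSubset:
    """A candidate short form: per factor, the chosen item ids.

    ``by_factor`` maps factor label to a sorted tuple of item ids.  The
    hashable ``key`` (sorted tuple of all members) identifies the subset for
    caching and tie-breaking.
    """

    by_factor: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm = {f: tuple(sorted(its)) for f, its in self.by_factor.items()}
        all_items = [i for its in norm.values() for i in its]
        if len(set(all_items)) != len(all_items):
            raise ValueError("item appears in more than one factor of the subset")
        object.__setattr__(self, "by_factor", norm)

    @property
    def key(self) -> tuple[str, ...]:
        return tuple(sorted(i for its in self.by_factor.values() for i in its))

    @property
    def all_items(self) -> tuple[str, ...]:
        return self.key

    def __len__(self) -> int:
        return len(self.key)

    def __hash__(self) -> int:  # by_factor is normalised, so key is canonical
        return hash(self.key)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ItemSubset):
            return NotImplemented
        return dict(self.by_factor) == dict(other.by_factor)

    def validate_against(self, scale: ScaleDefinition, quotas: bool = True) -> None:
        for f, its in self.by_factor.items():
            pool = set(scale.items_in(f))
            stray = set(its) - pool
            if stray:
                raise ValueError(f"items {sorted(stray)} not in factor {f!r}")
            if quotas and len(its) != scale.select_counts[f]:
                raise ValueError(
                    f"factor {f!r}: got {len(its)} items, quota is "
                    f"{scale.select_counts[f]}"
                )
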