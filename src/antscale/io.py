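"""Reading response matrices and scale definitions; trace serialization.

Responses are CSV (UTF-8, header row of item ids, one respondent per row).
Scale definitions are YAML or JSON with ``factors`` (label -> item list) and
``select`` (label -> count).  Run traces are JSON-lines.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .scale import ResponseMatrix, ScaleDefinition

__all__ = [
    "read_responses",
    "responses_from_dataframe",
    "read_scale_definition",
    "write_responses",
    "write_scale_definition",
    "write_trace",
    "read_trace",
]

log = logging.getLogger(__name__)


def responses_from_dataframe(df: pd.DataFrame, scale: ScaleDefinition) -> ResponseMatrix:
    """Validate a DataFrame of Likert answers against ``scale``.

    Columns are re-aligned to ``scale.item_ids``; rows with any missing,
    non-integer, or out-of-range entry are dropped (listwise deletion).
    """
    missing = [i for i in scale.item_ids if i not in df.columns]
    if missing:
        raise ValueError(f"response data lacks columns for items: {missing}")
    sub = df[list(scale.item_ids)].apply(pd.to_numeric, errors="coerce")
    arr = sub.to_numpy(dtype=float)
    ok = np.isfinite(arr)
    ok &= np.where(ok, np.mod(np.where(ok, arr, 0.0), 1.0) == 0, False)
    ok &= (arr >= 1) & (arr <= scale.n_categories)
    keep = ok.all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("listwise deletion dropped %d of %d rows", n_dropped, len(keep))
    if not keep.any():
        raise ValueError("no complete response rows remain after listwise deletion")
    return ResponseMatrix(arr[keep].astype(np.int64), scale.item_ids, n_dropped)


def read_responses(path: str | Path, scale: ScaleDefinition) -> ResponseMatrix:
    """Read a response CSV and apply listwise deletion (see module docs)."""
    df = pd.read_csv(path)
    return responses_from_dataframe(df, scale)


def write_responses(responses: ResponseMatrix, path: str | Path) -> None:
    pd.DataFrame(responses.values, columns=list(responses.item_ids)).to_csv(
        path, index=False
    )


def read_scale_definition(path: str | Path) -> ScaleDefinition:
    """Read a YAML/JSON scale definition.

    Expected keys: ``factors`` (factor label -> list of item ids), ``select``
    (factor label -> number of items to keep), optional ``n_categories``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "factors" not in raw:
        raise ValueError(f"{path}: expected a mapping with a 'factors' key")
    factors = raw["factors"]
    select = raw.get("select", {})
    n_categories = int(raw.get("n_categories", 5))
    item_ids: list[str] = []
    factor_of: dict[str, str] = {}
    for label, items in factors.items():
        for item in items:
            item = str(item)
            if item in factor_of:
                raise ValueError(
                    f"item {item!r} listed under both {factor_of[item]!r} and {label!r}"
                )
            factor_of[item] = str(label)
            item_ids.append(item)
    counts = {str(f): int(k) for f, k in select.items()}
    for f in factors:
        counts.setdefault(str(f), len(factors[f]))
    return ScaleDefinition(tuple(item_ids), factor_of, counts, n_categories)


def write_scale_definition(scale: ScaleDefinition, path: str | Path) -> None:
    doc = {
        "factors": {f: list(scale.items_in(f)) for f in scale.factors},
        "select": {f: int(scale.select_counts[f]) for f in scale.factors},
        "n_categories": scale.n_categories,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_trace(records: Iterable[dict[str, Any]], path: str | Path) -> None:
    """Write per-iteration run records as JSON-lines (round-trip safe)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_trace(path: str | Path) -> list[dict[str, Any]]:
    out: list[dict[str, Any]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(json.loads(line))
    return out
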