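"""Shared fixtures: small scales, synthetic datasets, and reference fits.

The heavier fixtures (planted-optimum dataset with its polychoric matrix,
reference fit, and exhaustive enumeration) are session-scoped so the search,
consensus, and acceptance tests reuse one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from antscale.aco import compute_reference
from antscale.polychoric import polychoric_matrix
from antscale.scale import ScaleDefinition
from antscale.selection import exhaustive_search
from antscale.simulate import generate_responses, planted_optimum_spec

ACO_P_PROS = [0.77, 0.86, 0.87, 0.73, 0.68]
ACO_P_CONS = [0.85, 0.97, 0.93, 0.74, 0.47]


@pytest.fixture(scope="session")
def small_scale() -> ScaleDefinition:
    """Ten items, two factors, quota 3 + 3."""
    ids = tuple(f"a{k}" for k in range(5)) + tuple(f"b{k}" for k in range(5))
    fac = {i: ("f1" if i.startswith("a") else "f2") for i in ids}
    return ScaleDefinition(ids, fac, {"f1": 3, "f2": 3})


@pytest.fixture(scope="session")
def implied_matrix_10():
    """Model-implied correlation matrix from published ACO-P loadings,
    factor correlation 0.56; the generating parameters ride along."""
    lam = np.array(ACO_P_PROS + ACO_P_CONS)
    fidx = np.array([0] * 5 + [1] * 5)
    Phi = np.array([[1.0, 0.56], [0.56, 1.0]])
    L = np.zeros((10, 2))
    L[np.arange(10), fidx] = lam
    S = L @ Phi @ L.T + np.diag(1 - lam**2)
    ids = tuple(f"i{k:02d}" for k in range(10))
    scale = ScaleDefinition(
        ids,
        {i: ("pros" if k < 5 else "cons") for k, i in enumerate(ids)},
        {"pros": 5, "cons": 5},
    )
    return S, scale, lam, 0.56


@pytest.fixture(scope="session")
def planted():
    """Planted-optimum pool (6+6 choose 3+3) at N=500 with everything the
    search needs: data, polychoric matrix, reference fit, exhaustive best."""
    spec, scale, planted_items = planted_optimum_spec(n_obs=500, seed=42)
    data = generate_responses(spec)
    corr = polychoric_matrix(data)
    reference = compute_reference(data, scale, corr)
    best, evals = exhaustive_search(data, scale, corr, reference)
    return {
        "spec": spec,
        "scale": scale,
        "planted_items": planted_items,
        "data": data,
        "corr": corr,
        "reference": reference,
        "exhaustive_best": best,
        "all_evaluations": evals,
    }
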