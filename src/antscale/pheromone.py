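"""The pheromone objective: sigmoid-transformed quality criteria.

Each psychometric criterion is pushed through a logistic function centred
near its conventional cut-off, so that a candidate short form earns a value
in (0, 1) per criterion:

    phi_CFI   = 1 / (1 + exp(95 - 100 CFI))            (midpoint CFI = 0.95)
    phi_RMSEA = 1 - 1 / (1 + exp(5 - 100 RMSEA))       (midpoint RMSEA = 0.05)
    phi_Fit   = (phi_CFI + phi_RMSEA) / 2
    phi_Rel   = 1 / (1 + exp(9 - 10 omega))            (midpoint omega = 0.90)
    phi_Corr  = 1 / (1 + exp(85 - 100 cor))            (midpoint cor = 0.85)
    phi_Fc    = 1 - 1 / (1 + exp(3 - 100 diff))        (midpoint diff = 0.03)

The overall pheromone is the sum phi_Fit + phi_Rel + phi_Corr + phi_Fc,
bounded in (0, 4).  Reliability aggregates across factors by the arithmetic
mean of per-factor sigmoids; the sum-score correlation criterion takes the
minimum correlation across factors before the sigmoid (so "at least 0.85"
binds per subscale); the factor-correlation criterion uses the maximum
absolute deviation from the full-scale factor correlations.  Inadmissible
candidates (non-converged or Heywood fits) receive a total of exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "PheromoneComponents",
    "phi_cfi",
    "phi_rmsea",
    "phi_fit",
    "phi_rel",
    "phi_corr",
    "phi_fc",
    "total_pheromone",
]


def _sigmoid(z: float) -> float:
    # numerically safe logistic
    if z >= 0:
        return 1.0 / (1.0 + np.exp(-z))
    e = np.exp(z)
    return float(e / (1.0 + e))


def phi_cfi(cfi: float) -> float:
    """Model-fit reward increasing in CFI; 0.5 at CFI = 0.95."""
    return _sigmoid(100.0 * cfi - 95.0)


def phi_rmsea(rmsea: float) -> float:
    """Model-fit reward decreasing in RMSEA; 0.5 at RMSEA = 0.05.

    Computed as the equivalent ``sigmoid(5 - 100 rmsea)`` so the value stays
    strictly positive instead of rounding to 0 for large RMSEA.
    """
    return _sigmoid(5.0 - 100.0 * rmsea)


def phi_fit(phi_cfi_value: float, phi_rmsea_value: float) -> float:
    """Equal-weight mean of the two fit-index rewards."""
    return 0.5 * (phi_cfi_value + phi_rmsea_value)


def phi_rel(omegas: Iterable[float] | float) -> float:
    """Reliability reward; mean over factors of sigmoids centred at omega = 0.9."""
    vals = np.atleast_1d(np.asarray(omegas, dtype=float))
    if vals.size == 0:
        raise ValueError("no omega values")
    return float(np.mean([_sigmoid(10.0 * w - 9.0) for w in vals]))


def phi_corr(correlations: Iterable[float] | float) -> float:
    """Full-vs-short sum-score agreement; sigmoid of the minimum correlation."""
    vals = np.atleast_1d(np.asarray(correlations, dtype=float))
    if vals.size == 0:
        raise ValueError("no correlations")
    return _sigmoid(100.0 * float(vals.min()) - 85.0)


def phi_fc(max_abs_diff: float) -> float:
    """Factor-correlation preservation; 0.5 at an absolute difference of 0.03."""
    if max_abs_diff < 0:
        raise ValueError("difference must be non-negative")
    return _sigmoid(3.0 - 100.0 * max_abs_diff)  # = 1 - sigmoid(100 diff - 3)


@dataclass(frozen=True)
class PheromoneComponents:
    """The criterion rewards and their sum (the ACO objective)."""

    phi_cfi: float
    phi_rmsea: float
    phi_fit: float
    phi_rel: float
    phi_corr: float
    phi_fc: float
    phi_total: float
    feasible: bool = True
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "phi_cfi": self.phi_cfi,
            "phi_rmsea": self.phi_rmsea,
            "phi_fit": self.phi_fit,
            "phi_rel": self.phi_rel,
            "phi_corr": self.phi_corr,
            "phi_fc": self.phi_fc,
            "phi_total": self.phi_total,
            "feasible": self.feasible,
            "reason": self.reason,
        }


def total_pheromone(
    cfi: float,
    rmsea: float,
    omegas: Iterable[float],
    correlations: Iterable[float],
    max_abs_diff: float,
    *,
    feasible: bool = True,
    reason: str = "",
    extra: float | None = None,
) -> PheromoneComponents:
    """Assemble all components; infeasible candidates get phi_total = 0.

    ``extra`` is an optional additional (0, 1)-valued criterion term a caller
    may add to the sum (a hook for study-specific criteria).
    """
    if not feasible:
        return PheromoneComponents(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                                   feasible=False, reason=reason or "infeasible")
    a = phi_cfi(cfi)
    b = phi_rmsea(rmsea)
    fit = phi_fit(a, b)
    rel = phi_rel(omegas)
    cor = phi_corr(correlations)
    fc = phi_fc(max_abs_diff)
    total = fit + rel + cor + fc
    if extra is not None:
        if not 0.0 < extra < 1.0:
            raise ValueError("extra criterion term must lie in (0, 1)")
        total += extra
    return PheromoneComponents(a, b, fit, rel, cor, fc, float(total))
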