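"""Published psychometric values of the German Alcohol Decisional Balance
Scale (ADBS).

The ADBS measures the perceived pros and cons of drinking on a 5-point
importance scale; the German validation pool holds 26 items (13 pros, 13
cons).  The constants below are the published standardized full-pool
loadings, the per-scale loadings of the established short forms, and the
pros-cons factor correlation.  They serve two purposes: as worked inputs for
reliability and loading-summary computations, and as the loading profile the
synthetic generator emulates (the respondent-level data are not public).
"""

from __future__ import annotations

__all__ = [
    "FACTOR_OF",
    "FULL_POOL_LOADINGS",
    "ORIGINAL_SHORT_LOADINGS",
    "ACO_P_LOADINGS",
    "ACO_C_LOADINGS",
    "FACTOR_LOADING_SCALE_LOADINGS",
    "FACTOR_CORRELATION",
    "PROS",
    "CONS",
]

#: factor membership of the 26-item pool ("item01".."item26")
FACTOR_OF: dict[str, str] = {
    "item01": "pros", "item02": "pros", "item03": "cons", "item04": "pros",
    "item05": "cons", "item06": "cons", "item07": "pros", "item08": "cons",
    "item09": "pros", "item10": "cons", "item11": "cons", "item12": "cons",
    "item13": "cons", "item14": "pros", "item15": "cons", "item16": "pros",
    "item17": "pros", "item18": "cons", "item19": "pros", "item20": "pros",
    "item21": "cons", "item22": "pros", "item23": "pros", "item24": "cons",
    "item25": "cons", "item26": "pros",
}

PROS: tuple[str, ...] = tuple(i for i, f in FACTOR_OF.items() if f == "pros")
CONS: tuple[str, ...] = tuple(i for i, f in FACTOR_OF.items() if f == "cons")

#: published standardized loadings of the full 26-item pool
FULL_POOL_LOADINGS: dict[str, float] = {
    "item01": 0.83, "item02": 0.77, "item03": 0.79, "item04": 0.86,
    "item05": 0.82, "item06": 0.61, "item07": 0.83, "item08": 0.85,
    "item09": 0.71, "item10": 0.76, "item11": 0.70, "item12": 0.25,
    "item13": 0.31, "item14": 0.74, "item15": 0.78, "item16": 0.86,
    "item17": 0.69, "item18": 0.88, "item19": 0.94, "item20": 0.92,
    "item21": 0.74, "item22": 0.82, "item23": 0.70, "item24": 0.43,
    "item25": 0.55, "item26": 0.56,
}

#: published loadings of the established 10-item short scale
ORIGINAL_SHORT_LOADINGS: dict[str, float] = {
    "item01": 0.85, "item07": 0.92, "item09": 0.86, "item14": 0.56,
    "item22": 0.49,                                             # pros
    "item15": 0.64, "item18": 0.74, "item21": 0.72, "item24": 0.70,
    "item25": 0.71,                                             # cons
}

#: published loadings of the best-pheromone (ACO-P) 10-item scale
ACO_P_LOADINGS: dict[str, float] = {
    "item02": 0.77, "item16": 0.86, "item17": 0.87, "item20": 0.73,
    "item22": 0.68,                                             # pros
    "item10": 0.85, "item11": 0.97, "item12": 0.93, "item13": 0.74,
    "item24": 0.47,                                             # cons
}

#: published loadings of the consensus (ACO-C) 11-item scale (5 pros, 6 cons)
ACO_C_LOADINGS: dict[str, float] = {
    "item02": 0.79, "item07": 0.75, "item17": 0.87, "item19": 0.83,
    "item20": 0.80,                                             # pros
    "item08": 0.68, "item10": 0.88, "item11": 0.97, "item12": 0.92,
    "item15": 0.82, "item24": 0.49,                             # cons
}

#: published loadings of the highest-loading baseline 10-item scale
FACTOR_LOADING_SCALE_LOADINGS: dict[str, float] = {
    "item01": 0.85, "item07": 0.89, "item09": 0.84, "item16": 0.79,
    "item17": 0.85,                                             # pros
    "item06": 0.85, "item10": 0.89, "item11": 0.96, "item12": 0.92,
    "item15": 0.82,                                             # cons
}

#: published pros-cons latent correlation of the full pool
FACTOR_CORRELATION: float = 0.56


def loadings_by_factor(loadings: dict[str, float]) -> dict[str, list[float]]:
    """Split a loading map into per-factor loading lists (pros/cons order)."""
    out: dict[str, list[float]] = {"pros": [], "cons": []}
    for item in sorted(loadings):
        out[FACTOR_OF[item]].append(loadings[item])
    return out
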