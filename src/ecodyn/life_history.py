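"""Smith-Fretwell seed size/number trade-off.

A parent with total reproductive budget R divides it into n = R/I offspring
of per-offspring investment I.  Offspring fitness is zero below a minimum
viable investment I_min and saturates beyond it:

    W(I) = W_max * (I - I_min) / (I - I_min + c)     for I > I_min

(a shifted Michaelis-Menten curve with half-saturation scale c).  Parent
fitness F(I) = (R/I) W(I) is maximised where the tangent from the origin
touches W, giving the closed-form optimum

    I* = I_min + sqrt(I_min * c),

independent of both the budget R and the fitness ceiling W_max.
"""

from __future__ import annotations

import math

__all__ = ["DEFAULT_PARAMS", "offspring_fitness", "parent_fitness", "optimal_investment"]

DEFAULT_PARAMS = {"R": 100.0, "I_min": 1.0, "c": 4.0, "W_max": 1.0}


def _check(params) -> dict:
    p = dict(DEFAULT_PARAMS)
    p.update(params or {})
    extra = set(p) - set(DEFAULT_PARAMS)
    if extra:
        raise ValueError(f"unknown parameter(s) {sorted(extra)}")
    for k, v in p.items():
        if not (v > 0 and math.isfinite(v)):
            raise ValueError(f"parameter {k!r} must be positive and finite")
    return p


def offspring_fitness(I: float, params=None) -> float:
    """Fitness of a single offspring given per-offspring investment I."""
    p = _check(params)
    if I < 0:
        raise ValueError("investment must be nonnegative")
    if I <= p["I_min"]:
        return 0.0
    x = I - p["I_min"]
    return p["W_max"] * x / (x + p["c"])


def parent_fitness(I: float, params=None) -> float:
    """F(I) = (R/I) * W(I): offspring number times offspring fitness."""
    p = _check(params)
    if I <= 0:
        raise ValueError("investment must be positive")
    return (p["R"] / I) * offspring_fitness(I, p)


def optimal_investment(params=None) -> dict:
    """Optimal per-offspring investment and the resulting parent fitness.

    Uses the closed form I* = I_min + sqrt(I_min * c); returns the optimum,
    the offspring number R/I*, and parent fitness at the optimum.
    """
    p = _check(params)
    I_star = p["I_min"] + math.sqrt(p["I_min"] * p["c"])
    n = p["R"] / I_star
    return {
        "I_star": I_star,
        "n_offspring": n,
        "parent_fitness": n * offspring_fitness(I_star, p),
    }
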