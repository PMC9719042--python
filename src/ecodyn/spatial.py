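"""Landscape ecology: island biogeography and source-sink metapopulations.

Island biogeography (MacArthur-Wilson): species richness S on an island fed
from a mainland pool of P species.  Immigration declines linearly as the
pool is exhausted and extinction rises linearly with richness; distance D
and area A enter as exponential modifiers, so far islands receive fewer
immigrants and small islands lose species faster:

    lambda(S) = I_max * exp(-phi*D) * (1 - S/P)
    mu(S)     = E_max * exp(-eps*A) * (S/P)

dS/dt = lambda - mu is linear, with equilibrium richness S* = P I'/(I'+E')
and turnover T* = I'E'/(I'+E') where I', E' are the distance/area-modified
maximal rates.

Source-sink (Pulliam): discrete annual accounting.  The source grows by
lambda1 per year up to a breeding-site ceiling N*; the surplus emigrates to
a sink habitat where the population declines by lambda2 < 1 per year but is
topped up by immigration.  Once the source sits at its ceiling the sink
equilibrates at n2* = N*(lambda1 - 1)/(1 - lambda2).
"""

from __future__ import annotations

import math

import numpy as np

from .core import DomainError, ModelSpec, ParamSpec, Trajectory, integrate_ode, iterate_map, validate_params

__all__ = [
    "island_spec",
    "island_rates",
    "island_equilibrium",
    "run_island",
    "source_sink_spec",
    "run_source_sink",
    "sink_equilibrium",
]


def _island_schema():
    inf = math.inf
    return {
        "P": ParamSpec(100.0, 1.0, inf, "mainland species pool"),
        "I_max": ParamSpec(1.0, 0.0, inf, "maximal immigration rate (species/time)"),
        "E_max": ParamSpec(0.25, 0.0, inf, "maximal extinction rate (species/time)"),
        "D": ParamSpec(0.0, 0.0, inf, "island distance from mainland (km)"),
        "A": ParamSpec(0.0, 0.0, inf, "island area (km^2)"),
        "phi": ParamSpec(0.01, 0.0, inf, "distance decay of immigration (1/km)"),
        "eps": ParamSpec(0.01, 0.0, inf, "area decay of extinction (1/km^2)"),
    }


def _modified_rates(p):
    return p["I_max"] * math.exp(-p["phi"] * p["D"]), p["E_max"] * math.exp(-p["eps"] * p["A"])


def _island_rhs(t, y, p):
    Ieff, Eeff = _modified_rates(p)
    S = y[0]
    return np.array([Ieff * (1.0 - S / p["P"]) - Eeff * S / p["P"]])


def island_spec() -> ModelSpec:
    return ModelSpec(
        id="island-biogeo",
        kind="continuous",
        state_names=["S"],
        param_schema=_island_schema(),
        dynamics=_island_rhs,
        closed_forms={
            "solution": lambda t, p, S0: _island_solution(t, p, S0),
            "equilibria": lambda p: [{"S": island_equilibrium(p)["S_star"]}],
        },
    )


def _island_solution(t, p, S0):
    Ieff, Eeff = _modified_rates(p)
    S_star = p["P"] * Ieff / (Ieff + Eeff)
    rate = (Ieff + Eeff) / p["P"]
    return S_star + (S0 - S_star) * np.exp(-rate * np.asarray(t, dtype=float))


def island_rates(params, S: float) -> dict:
    """Immigration and extinction rates at richness S."""
    p = validate_params(island_spec(), params)
    if not (0.0 <= S <= p["P"]):
        raise DomainError(f"S={S} outside [0, P={p['P']}]")
    Ieff, Eeff = _modified_rates(p)
    return {"immigration": Ieff * (1.0 - S / p["P"]), "extinction": Eeff * S / p["P"]}


def island_equilibrium(params) -> dict:
    """Equilibrium richness S* and species turnover T* = lambda(S*)."""
    p = validate_params(island_spec(), params)
    Ieff, Eeff = _modified_rates(p)
    if Ieff + Eeff <= 0:
        raise DomainError("degenerate island: no immigration and no extinction")
    S_star = p["P"] * Ieff / (Ieff + Eeff)
    return {"S_star": S_star, "turnover": Ieff * Eeff / (Ieff + Eeff)}


def run_island(params, S0: float, t_end: float, **kw) -> Trajectory:
    spec = island_spec()
    p = validate_params(spec, params)
    if not (0.0 <= S0 <= p["P"]):
        raise DomainError(f"S0={S0} outside [0, P={p['P']}]")
    return integrate_ode(spec, p, {"S": S0}, t_end, **kw)


# ----------------------------------------------------------------- source-sink

def _source_sink_map(y, p):
    n1, n2 = y
    grown = p["lambda1"] * n1
    surplus = max(grown - p["N_star"], 0.0)
    return np.array([min(grown, p["N_star"]), p["lambda2"] * n2 + surplus])


def source_sink_spec() -> ModelSpec:
    inf = math.inf
    return ModelSpec(
        id="source-sink",
        kind="discrete",
        state_names=["n1", "n2"],
        param_schema={
            "lambda1": ParamSpec(1.2, 0.0, inf, "source annual growth factor"),
            "lambda2": ParamSpec(0.8, 0.0, inf, "sink annual growth factor"),
            "N_star": ParamSpec(100.0, 1e-12, inf, "source breeding-site ceiling"),
        },
        dynamics=_source_sink_map,
    )


def run_source_sink(params, init, T: int) -> Trajectory:
    """Annual source-sink projection; flags regimes with no sink equilibrium."""
    spec = source_sink_spec()
    p = validate_params(spec, params)
    traj = iterate_map(spec, p, init, T)
    if p["lambda2"] >= 1.0:
        traj.meta["no_sink_equilibrium"] = True
    return traj


def sink_equilibrium(params) -> float | None:
    """n2* = N*(lambda1 - 1)/(1 - lambda2), or None when it does not exist.

    Requires a saturated source (lambda1 > 1) and a true sink (lambda2 < 1).
    """
    p = validate_params(source_sink_spec(), params)
    if p["lambda2"] >= 1.0 or p["lambda1"] <= 1.0:
        return None
    return p["N_star"] * (p["lambda1"] - 1.0) / (1.0 - p["lambda2"])
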