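"""Compartment models of infectious-disease dynamics.

All variants use frequency-dependent transmission beta*S*I/N, so beta keeps
the same interpretation (contacts per unit time times infection probability)
regardless of population size:

    sir             dS = -bSI/N            dI = bSI/N - gI     dR = gI
    sis             dS = -bSI/N + gI       dI = bSI/N - gI
    seir            dS = -bSI/N   dE = bSI/N - sE   dI = sE - gI   dR = gI
    sir_demography  sir plus births mu*N into S and deaths mu from every
                    compartment (constant population size)

R0 = beta/gamma for sir/sis/seir, beta/(gamma + mu) with demography.  For
the simple epidemic, the final attack rate z solves z = 1 - exp(-R0 z).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

from .core import DomainError, ModelSpec, ParamSpec, SchemaError, Trajectory, integrate_ode, validate_params

__all__ = ["EPI_VARIANTS", "compartment_spec", "run_compartment", "r0", "final_size"]

EPI_VARIANTS = ("sir", "sis", "seir", "sir_demography")


def _rhs(variant):
    def sir(t, y, p):
        S, I, R = y
        inf = p["beta"] * S * I / p["N"]
        return np.array([-inf, inf - p["gamma"] * I, p["gamma"] * I])

    def sis(t, y, p):
        S, I = y
        inf = p["beta"] * S * I / p["N"]
        return np.array([-inf + p["gamma"] * I, inf - p["gamma"] * I])

    def seir(t, y, p):
        S, E, I, R = y
        inf = p["beta"] * S * I / p["N"]
        return np.array([-inf, inf - p["sigma"] * E, p["sigma"] * E - p["gamma"] * I, p["gamma"] * I])

    def sir_demography(t, y, p):
        S, I, R = y
        inf = p["beta"] * S * I / p["N"]
        mu = p["mu"]
        return np.array(
            [mu * p["N"] - inf - mu * S, inf - p["gamma"] * I - mu * I, p["gamma"] * I - mu * R]
        )

    return {"sir": sir, "sis": sis, "seir": seir, "sir_demography": sir_demography}[variant]


_STATES = {
    "sir": ["S", "I", "R"],
    "sis": ["S", "I"],
    "seir": ["S", "E", "I", "R"],
    "sir_demography": ["S", "I", "R"],
}


def compartment_spec(variant: str = "sir") -> ModelSpec:
    if variant not in EPI_VARIANTS:
        raise KeyError(f"unknown compartment-model variant {variant!r}")
    inf = math.inf
    schema = {
        "beta": ParamSpec(0.4, 0.0, inf, "transmission rate (1/time)"),
        "gamma": ParamSpec(0.2, 0.0, inf, "recovery rate (1/time)"),
        "N": ParamSpec(1000.0, 1e-12, inf, "total population size"),
    }
    if variant == "seir":
        schema["sigma"] = ParamSpec(0.5, 0.0, inf, "incubation rate (1/time)")
    if variant == "sir_demography":
        schema["mu"] = ParamSpec(0.01, 0.0, inf, "per-capita birth/death rate (1/time)")
    return ModelSpec(
        id="infectious-disease",
        variant=variant,
        kind="continuous",
        state_names=_STATES[variant],
        param_schema=schema,
        dynamics=_rhs(variant),
    )


def run_compartment(variant, params, init, t_end, **kw) -> Trajectory:
    """Simulate a compartment model; initial compartments must sum to N."""
    spec = compartment_spec(variant)
    p = validate_params(spec, params)
    total = sum(float(init.get(s, 0.0)) for s in spec.state_names)
    if abs(total - p["N"]) > 1e-9 * p["N"]:
        raise SchemaError(
            f"initial compartments sum to {total}, expected N={p['N']}"
        )
    init = {s: float(init.get(s, 0.0)) for s in spec.state_names}
    return integrate_ode(spec, p, init, t_end, **kw)


def r0(variant, params) -> float:
    """Basic reproduction number of a variant.

    beta/gamma for sir, sis and seir (incubation delays but does not remove
    infections); beta/(gamma + mu) when demographic turnover shortens the
    infectious period.
    """
    p = validate_params(compartment_spec(variant), params)
    denom = p["gamma"] + (p["mu"] if variant == "sir_demography" else 0.0)
    if denom <= 0:
        raise DomainError("R0 undefined: zero removal rate")
    return p["beta"] / denom


def final_size(R0: float) -> float:
    """Final attack rate of a simple epidemic: the root of z = 1 - exp(-R0 z).

    Returns the nonzero root for R0 > 1 and 0 otherwise, located by Brent's
    method to 1e-10.
    """
    if R0 < 0:
        raise DomainError("R0 must be nonnegative")
    if R0 <= 1.0:
        return 0.0
    g = lambda z: z - (1.0 - math.exp(-R0 * z))
    # g(eps) < 0 just above zero, g(1) > 0; nonzero root lies between
    lo = 1e-12
    while g(lo) > 0:
        lo /= 10.0
    return float(brentq(g, lo, 1.0, xtol=1e-10, rtol=8.9e-16))
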