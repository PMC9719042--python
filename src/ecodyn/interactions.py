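"""Two-species interaction models.

Lotka-Volterra competition:
    dNi/dt = ri Ni (1 - (Ni + aij Nj) / Ki)

Facultative mutualism with self-limitation (linear Lotka-Volterra form):
    dNi/dt = ri Ni (Ki - Ni + bij Nj) / Ki
which has a stable interior equilibrium N1* = (K1 + b12 K2)/(1 - b12 b21)
when b12 b21 < 1 and grows without bound otherwise.

Predator-prey, four variants built from two switches — logistic prey
growth and a Holling type II functional response aH/(1 + a T_h H):
    lv                    dH/dt = rH - aHP,          dP/dt = eaHP - dP
    logistic_prey         prey growth rH(1 - H/K)
    type2                 predation aHP/(1 + a T_h H) in both equations
    rosenzweig_macarthur  both modifications
"""

from __future__ import annotations

import math

import numpy as np

from .core import (
    DomainError,
    ModelSpec,
    ParamSpec,
    SchemaError,
    Trajectory,
    integrate_ode,
    validate_params,
)

__all__ = [
    "PREDPREY_VARIANTS",
    "lv_competition_spec",
    "mutualism_spec",
    "predprey_spec",
    "run_lvcomp",
    "lvcomp_outcome",
    "run_mutualism",
    "run_predprey",
    "predprey_isoclines",
    "lv_conserved_quantity",
]

PREDPREY_VARIANTS = ("lv", "logistic_prey", "type2", "rosenzweig_macarthur")

#: tolerance on the K/alpha inequalities used to classify competition outcomes
OUTCOME_TOL = 1e-9


# ---------------------------------------------------------------- competition

def _lvcomp_rhs(t, y, p):
    N1, N2 = y
    dN1 = p["r1"] * N1 * (1.0 - (N1 + p["a12"] * N2) / p["K1"])
    dN2 = p["r2"] * N2 * (1.0 - (N2 + p["a21"] * N1) / p["K2"])
    return np.array([dN1, dN2])


def _lvcomp_equilibria(p):
    eqs = [{"N1": 0.0, "N2": 0.0}, {"N1": p["K1"], "N2": 0.0}, {"N1": 0.0, "N2": p["K2"]}]
    denom = 1.0 - p["a12"] * p["a21"]
    if abs(denom) > OUTCOME_TOL:
        n1 = (p["K1"] - p["a12"] * p["K2"]) / denom
        n2 = (p["K2"] - p["a21"] * p["K1"]) / denom
        if n1 > 0 and n2 > 0:
            eqs.append({"N1": n1, "N2": n2})
    return eqs


def lv_competition_spec() -> ModelSpec:
    inf = math.inf
    return ModelSpec(
        id="lv-competition",
        kind="continuous",
        state_names=["N1", "N2"],
        param_schema={
            "r1": ParamSpec(1.0, 0.0, inf, "species 1 growth rate (1/time)"),
            "r2": ParamSpec(1.0, 0.0, inf, "species 2 growth rate (1/time)"),
            "K1": ParamSpec(100.0, 1e-12, inf, "species 1 carrying capacity"),
            "K2": ParamSpec(100.0, 1e-12, inf, "species 2 carrying capacity"),
            "a12": ParamSpec(0.5, 0.0, inf, "effect of species 2 on species 1"),
            "a21": ParamSpec(0.5, 0.0, inf, "effect of species 1 on species 2"),
        },
        dynamics=_lvcomp_rhs,
        closed_forms={
            "equilibria": _lvcomp_equilibria,
            "nullclines": lambda p: {
                "N1": lambda n1: (p["K1"] - n1) / p["a12"] if p["a12"] > 0 else None,
                "N2": lambda n1: p["K2"] - p["a21"] * n1,
            },
        },
    )


def run_lvcomp(params, init, t_end, **kw) -> Trajectory:
    return integrate_ode(lv_competition_spec(), params, init, t_end, **kw)


def lvcomp_outcome(params) -> dict:
    """Equilibria and the classical competition outcome.

    Classified by the K/alpha invasion inequalities: species 1 invades a
    species-2 monoculture iff K1 > a12 K2, and symmetrically.  Both
    invadable -> stable coexistence; neither -> priority effect (interior
    saddle); one -> that species wins.  Ties within ``OUTCOME_TOL`` are
    flagged degenerate.
    """
    p = validate_params(lv_competition_spec(), params)
    eqs = _lvcomp_equilibria(p)
    inv1 = p["K1"] - p["a12"] * p["K2"]  # >0: sp1 invades sp2 monoculture
    inv2 = p["K2"] - p["a21"] * p["K1"]
    degenerate = abs(inv1) <= OUTCOME_TOL or abs(inv2) <= OUTCOME_TOL
    if inv1 > OUTCOME_TOL and inv2 > OUTCOME_TOL:
        outcome = "coexistence"
    elif inv1 < -OUTCOME_TOL and inv2 < -OUTCOME_TOL:
        outcome = "priority_effect"
    elif inv1 > OUTCOME_TOL:
        outcome = "sp1_wins"
    elif inv2 > OUTCOME_TOL:
        outcome = "sp2_wins"
    else:
        outcome = "degenerate"
    return {"equilibria": eqs, "outcome": outcome, "degenerate": degenerate}


# ------------------------------------------------------------------ mutualism

def _mutualism_rhs(t, y, p):
    N1, N2 = y
    dN1 = p["r1"] * N1 * (p["K1"] - N1 + p["b12"] * N2) / p["K1"]
    dN2 = p["r2"] * N2 * (p["K2"] - N2 + p["b21"] * N1) / p["K2"]
    return np.array([dN1, dN2])


def _mutualism_equilibria(p):
    eqs = [{"N1": 0.0, "N2": 0.0}, {"N1": p["K1"], "N2": 0.0}, {"N1": 0.0, "N2": p["K2"]}]
    denom = 1.0 - p["b12"] * p["b21"]
    if denom > 0:
        eqs.append(
            {
                "N1": (p["K1"] + p["b12"] * p["K2"]) / denom,
                "N2": (p["K2"] + p["b21"] * p["K1"]) / denom,
            }
        )
    return eqs


def mutualism_spec() -> ModelSpec:
    inf = math.inf
    return ModelSpec(
        id="mutualism",
        kind="continuous",
        state_names=["N1", "N2"],
        param_schema={
            "r1": ParamSpec(0.5, 0.0, inf, "species 1 growth rate (1/time)"),
            "r2": ParamSpec(0.5, 0.0, inf, "species 2 growth rate (1/time)"),
            "K1": ParamSpec(100.0, 1e-12, inf, "species 1 carrying capacity"),
            "K2": ParamSpec(100.0, 1e-12, inf, "species 2 carrying capacity"),
            "b12": ParamSpec(0.3, 0.0, inf, "benefit of species 2 to species 1"),
            "b21": ParamSpec(0.3, 0.0, inf, "benefit of species 1 to species 2"),
        },
        dynamics=_mutualism_rhs,
        closed_forms={"equilibria": _mutualism_equilibria},
    )


def run_mutualism(params, init, t_end, **kw) -> Trajectory:
    """Simulate the mutualism model, flagging unbounded parameter regimes.

    When b12*b21 >= 1 no interior equilibrium exists and both populations
    grow without bound; the run is permitted but the trajectory metadata
    carries an ``unbounded`` flag, and integration stops early (divergence)
    if any state exceeds 1e6 * max(K1, K2).
    """
    spec = mutualism_spec()
    p = validate_params(spec, params)
    unbounded = p["b12"] * p["b21"] >= 1.0
    cap = 1e6 * max(p["K1"], p["K2"])
    traj = None
    diverged = False
    try:
        traj = integrate_ode(spec, p, init, t_end, **kw)
        if traj.states.max() > cap:
            diverged = True
    except Exception:
        if not unbounded:
            raise
        diverged = True
        # retry on a shorter horizon so a flagged, truncated run is returned
        t_short = t_end
        while traj is None and t_short > 1e-3:
            t_short /= 4.0
            try:
                traj = integrate_ode(spec, p, init, t_short, **kw)
            except Exception:
                continue
        if traj is None:
            raise
    traj.meta["unbounded"] = bool(unbounded)
    traj.meta["diverged"] = bool(diverged)
    if unbounded:
        traj.meta["note"] = "unbounded (orgy of mutual benefaction)"
    return traj


# --------------------------------------------------------------- predator-prey

def _predprey_rhs(variant):
    logistic = variant in ("logistic_prey", "rosenzweig_macarthur")
    type2 = variant in ("type2", "rosenzweig_macarthur")

    def rhs(t, y, p):
        H, P = y
        growth = p["r"] * H * (1.0 - H / p["K"]) if logistic else p["r"] * H
        attack = p["a"] * H / (1.0 + p["a"] * p["T_h"] * H) if type2 else p["a"] * H
        return np.array([growth - attack * P, p["e"] * attack * P - p["d"] * P])

    return rhs


def _predprey_equilibria(variant):
    def eqs(p):
        out = [{"H": 0.0, "P": 0.0}]
        logistic = variant in ("logistic_prey", "rosenzweig_macarthur")
        type2 = variant in ("type2", "rosenzweig_macarthur")
        if logistic:
            out.append({"H": p["K"], "P": 0.0})
        if type2:
            denom = p["a"] * (p["e"] - p["d"] * p["T_h"])
            if denom <= 0:
                return out
            H = p["d"] / denom
        else:
            H = p["d"] / (p["e"] * p["a"])
        fr = p["a"] * H / (1.0 + p["a"] * p["T_h"] * H) if type2 else p["a"] * H
        growth = p["r"] * H * (1.0 - H / p["K"]) if logistic else p["r"] * H
        P = growth / fr
        if P > 0:
            out.append({"H": H, "P": P})
        return out

    return eqs


def predprey_spec(variant: str = "lv") -> ModelSpec:
    """Spec for one predator-prey variant; K and T_h required only where used."""
    if variant not in PREDPREY_VARIANTS:
        raise KeyError(f"unknown predator-prey variant {variant!r}")
    inf = math.inf
    schema = {
        "r": ParamSpec(0.5, 0.0, inf, "prey growth rate (1/time)"),
        "a": ParamSpec(0.1, 0.0, inf, "attack rate (1/(predator*time))"),
        "e": ParamSpec(0.2, 0.0, 1.0, "conversion efficiency"),
        "d": ParamSpec(0.3, 0.0, inf, "predator death rate (1/time)"),
    }
    if variant in ("logistic_prey", "rosenzweig_macarthur"):
        schema["K"] = ParamSpec(math.nan, 1e-12, inf, "prey carrying capacity")
    if variant in ("type2", "rosenzweig_macarthur"):
        schema["T_h"] = ParamSpec(math.nan, 0.0, inf, "handling time")
    return ModelSpec(
        id="predator-prey",
        variant=variant,
        kind="continuous",
        state_names=["H", "P"],
        param_schema=schema,
        dynamics=_predprey_rhs(variant),
        closed_forms={"equilibria": _predprey_equilibria(variant)},
    )


def run_predprey(variant, params, init, t_end, **kw) -> Trajectory:
    spec = predprey_spec(variant)
    params = dict(params or {})
    for name, ps in spec.param_schema.items():
        if math.isnan(ps.default) and name not in params:
            raise SchemaError(
                f"variant {variant!r} requires parameter {name!r}", param=name
            )
    return integrate_ode(spec, params, init, t_end, **kw)


def predprey_isoclines(variant, params) -> dict:
    """Analytic zero-growth isoclines of a predator-prey variant.

    Returns ``prey_isocline`` (P as a function of H along dH/dt = 0) and
    ``predator_isocline`` (the vertical line H = const along dP/dt = 0, as
    a float, or None when e <= d*T_h leaves no predator isocline in the
    positive quadrant).
    """
    spec = predprey_spec(variant)
    p = validate_params(spec, params)
    if any(math.isnan(v) for v in p.values()):
        missing = [k for k, v in p.items() if math.isnan(v)]
        raise SchemaError(f"variant {variant!r} requires parameter {missing[0]!r}", param=missing[0])
    logistic = variant in ("logistic_prey", "rosenzweig_macarthur")
    type2 = variant in ("type2", "rosenzweig_macarthur")

    def prey_iso(H):
        H = np.asarray(H, dtype=float)
        growth = p["r"] * (1.0 - H / p["K"]) if logistic else np.full_like(H, p["r"])
        fr_per_H = p["a"] / (1.0 + p["a"] * p["T_h"] * H) if type2 else p["a"]
        return growth / fr_per_H

    if type2:
        denom = p["a"] * (p["e"] - p["d"] * p["T_h"])
        H_star = p["d"] / denom if denom > 0 else None
    else:
        H_star = p["d"] / (p["e"] * p["a"])
    return {"prey_isocline": prey_iso, "predator_isocline": H_star}


def lv_conserved_quantity(traj: Trajectory, params) -> np.ndarray:
    """V = e·a·H − d·ln H + a·P − r·ln P, the classic LV first integral.

    Constant along exact trajectories of the ``lv`` variant; its relative
    drift measures integration error.
    """
    p = validate_params(predprey_spec("lv"), params)
    H, P = traj["H"], traj["P"]
    if np.any(H <= 0) or np.any(P <= 0):
        raise DomainError("conserved quantity requires strictly positive H and P")
    return p["e"] * p["a"] * H - p["d"] * np.log(H) + p["a"] * P - p["r"] * np.log(P)
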