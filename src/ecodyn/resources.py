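"""Consumer-resource competition.

Abiotic (Tilman) model: two consumers N1, N2 on two essential abiotic
resources R1, R2.  Growth is Liebig's law of the minimum over Monod terms,

    mu_i(R1, R2) = min_j( r_i * Rj / (k_ij + Rj) ),
    dNi/dt = Ni (mu_i - m_i),
    dRj/dt = a (Sj - Rj) - sum_i c_ij * mu_i * Ni,

with semi-chemostat resource supply toward the supply point Sj.  The
R* value k_ij * m_i / (r_i - m_i) is the resource level at which consumer
i's growth on resource j exactly balances its mortality; the consumer with
the lower R* on the limiting resource excludes the other.

Biotic model: two consumers on one logistically growing resource with
Holling type I/II functional responses f_i(R) = a_i R / (1 + a_i h_i R).
"""

from __future__ import annotations

import math

import numpy as np

from .core import ModelSpec, ParamSpec, Trajectory, integrate_ode, validate_params

__all__ = [
    "abiotic_comp_spec",
    "biotic_comp_spec",
    "run_abiotic_comp",
    "run_biotic_comp",
    "compute_rstar",
    "functional_response_curve",
]


def _monod_mins(y, p):
    """Per-consumer realized growth rates under Liebig's minimum."""
    R1, R2 = y[2], y[3]
    mu = np.empty(2)
    for i, sp in enumerate(("1", "2")):
        g1 = p[f"r{sp}"] * R1 / (p[f"k{sp}1"] + R1)
        g2 = p[f"r{sp}"] * R2 / (p[f"k{sp}2"] + R2)
        mu[i] = min(g1, g2)
    return mu


def _abiotic_rhs(t, y, p):
    N1, N2, R1, R2 = y
    mu = _monod_mins(y, p)
    dN1 = N1 * (mu[0] - p["m1"])
    dN2 = N2 * (mu[1] - p["m2"])
    dR1 = p["a"] * (p["S1"] - R1) - p["c11"] * mu[0] * N1 - p["c21"] * mu[1] * N2
    dR2 = p["a"] * (p["S2"] - R2) - p["c12"] * mu[0] * N1 - p["c22"] * mu[1] * N2
    return np.array([dN1, dN2, dR1, dR2])


def abiotic_comp_spec() -> ModelSpec:
    inf = math.inf
    schema = {
        "r1": ParamSpec(1.6, 1e-12, inf, "consumer 1 max growth rate (1/time)"),
        "r2": ParamSpec(1.0, 1e-12, inf, "consumer 2 max growth rate (1/time)"),
        "m1": ParamSpec(0.2, 1e-12, inf, "consumer 1 mortality (1/time)"),
        "m2": ParamSpec(0.2, 1e-12, inf, "consumer 2 mortality (1/time)"),
        "k11": ParamSpec(18.0, 1e-12, inf, "half-saturation, consumer 1 on R1"),
        "k12": ParamSpec(4.0, 1e-12, inf, "half-saturation, consumer 1 on R2"),
        "k21": ParamSpec(2.0, 1e-12, inf, "half-saturation, consumer 2 on R1"),
        "k22": ParamSpec(14.0, 1e-12, inf, "half-saturation, consumer 2 on R2"),
        "c11": ParamSpec(0.25, 0.0, inf, "consumption of R1 per consumer-1 birth"),
        "c12": ParamSpec(0.08, 0.0, inf, "consumption of R2 per consumer-1 birth"),
        "c21": ParamSpec(0.1, 0.0, inf, "consumption of R1 per consumer-2 birth"),
        "c22": ParamSpec(0.2, 0.0, inf, "consumption of R2 per consumer-2 birth"),
        "S1": ParamSpec(20.0, 0.0, inf, "supply point of R1"),
        "S2": ParamSpec(20.0, 0.0, inf, "supply point of R2"),
        "a": ParamSpec(0.5, 1e-12, inf, "resource turnover rate (1/time)"),
    }
    return ModelSpec(
        id="abiotic-comp",
        kind="continuous",
        state_names=["N1", "N2", "R1", "R2"],
        param_schema=schema,
        dynamics=_abiotic_rhs,
    )


def run_abiotic_comp(params, init, t_end, rel_tol: float = 1e-9, **kw) -> Trajectory:
    """Simulate the essential-resource competition model.

    The Liebig min() makes the right-hand side nondifferentiable where the
    limiting resource switches, so the default solver tolerance is
    tightened to 1e-9 for this model.
    """
    return integrate_ode(abiotic_comp_spec(), params, init, t_end, rel_tol=rel_tol, **kw)


def compute_rstar(params) -> dict:
    """R* matrix: R*[i][j] = k_ij * m_i / (r_i - m_i).

    A consumer with r_i <= m_i cannot persist on any resource level; its
    row is +inf and it is listed under the ``nonviable`` flag.
    """
    p = validate_params(abiotic_comp_spec(), params)
    R = np.empty((2, 2))
    nonviable = []
    for i, sp in enumerate(("1", "2")):
        denom = p[f"r{sp}"] - p[f"m{sp}"]
        if denom <= 0:
            R[i, :] = np.inf
            nonviable.append(f"N{sp}")
        else:
            for j in range(2):
                R[i, j] = p[f"k{sp}{j + 1}"] * p[f"m{sp}"] / denom
    return {"rstar": R, "nonviable": nonviable}


def _biotic_rhs(t, y, p):
    R, N1, N2 = y
    f1 = p["a1"] * R / (1.0 + p["a1"] * p["h1"] * R)
    f2 = p["a2"] * R / (1.0 + p["a2"] * p["h2"] * R)
    dR = p["r"] * R * (1.0 - R / p["K"]) - f1 * N1 - f2 * N2
    dN1 = p["e1"] * f1 * N1 - p["d1"] * N1
    dN2 = p["e2"] * f2 * N2 - p["d2"] * N2
    return np.array([dR, dN1, dN2])


def biotic_comp_spec() -> ModelSpec:
    inf = math.inf
    schema = {
        "r": ParamSpec(1.0, 0.0, inf, "resource intrinsic growth rate (1/time)"),
        "K": ParamSpec(100.0, 1e-12, inf, "resource carrying capacity"),
        "a1": ParamSpec(0.02, 0.0, inf, "consumer 1 attack rate"),
        "a2": ParamSpec(0.02, 0.0, inf, "consumer 2 attack rate"),
        "h1": ParamSpec(0.0, 0.0, inf, "consumer 1 handling time (0 = type I)"),
        "h2": ParamSpec(0.1, 0.0, inf, "consumer 2 handling time (0 = type I)"),
        "e1": ParamSpec(0.4, 0.0, 1.0, "consumer 1 conversion efficiency"),
        "e2": ParamSpec(0.4, 0.0, 1.0, "consumer 2 conversion efficiency"),
        "d1": ParamSpec(0.1, 0.0, inf, "consumer 1 mortality (1/time)"),
        "d2": ParamSpec(0.1, 0.0, inf, "consumer 2 mortality (1/time)"),
    }
    return ModelSpec(
        id="biotic-comp",
        kind="continuous",
        state_names=["R", "N1", "N2"],
        param_schema=schema,
        dynamics=_biotic_rhs,
    )


def run_biotic_comp(params, init, t_end, **kw) -> Trajectory:
    return integrate_ode(biotic_comp_spec(), params, init, t_end, **kw)


def functional_response_curve(a: float, h: float, R_grid) -> np.ndarray:
    """Evaluate f(R) = aR/(1 + ahR) on a grid; returns an (R, f) table.

    Type I when h = 0 (a straight line of slope a); type II otherwise,
    saturating at 1/h.
    """
    if a < 0 or h < 0:
        raise ValueError("a and h must be nonnegative")
    R = np.asarray(R_grid, dtype=float)
    f = a * R / (1.0 + a * h * R)
    return np.column_stack([R, f])
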