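"""Single-species population growth in continuous and discrete time.

Continuous: exponential dN/dt = rN and logistic dN/dt = rN(1 - N/K).
Discrete: geometric N' = lambda*N, discrete logistic N' = N + rN(1 - N/K),
Beverton-Holt N' = RN / (1 + ((R-1)/K) N) and Ricker N' = N exp(r(1 - N/K)).
The Beverton-Holt map is parameterised so that K is its nontrivial fixed
point, keeping the meaning of K uniform across models.

Also provides cobweb-diagram staircases for the discrete maps.
"""

from __future__ import annotations

import math

import numpy as np

from .core import DomainError, ModelSpec, ParamSpec, validate_params

__all__ = ["SINGLE_POP_KINDS", "make_single_pop_spec", "cobweb"]

SINGLE_POP_KINDS = (
    "exp_cont",
    "logistic_cont",
    "exp_disc",
    "logistic_disc",
    "beverton_holt",
    "ricker",
)


def _logistic_solution(t, p, N0):
    """K / (1 + ((K - N0)/N0) e^{-rt}) — closed-form logistic solution."""
    t = np.asarray(t, dtype=float)
    K, r = p["K"], p["r"]
    if N0 == 0:
        return np.zeros_like(t)
    return K / (1.0 + ((K - N0) / N0) * np.exp(-r * t))


def make_single_pop_spec(kind: str) -> ModelSpec:
    """Build the spec for one of the six single-population model kinds."""
    if kind == "exp_cont":
        return ModelSpec(
            id="single-pop-continuous",
            variant="exponential",
            kind="continuous",
            state_names=["N"],
            param_schema={"r": ParamSpec(0.5, -math.inf, math.inf, "intrinsic growth rate (1/time)")},
            dynamics=lambda t, y, p: np.array([p["r"] * y[0]]),
            closed_forms={
                "solution": lambda t, p, N0: N0 * np.exp(p["r"] * np.asarray(t, dtype=float)),
                "equilibria": lambda p: [{"N": 0.0}],
            },
        )
    if kind == "logistic_cont":
        return ModelSpec(
            id="single-pop-continuous",
            variant="logistic",
            kind="continuous",
            state_names=["N"],
            param_schema={
                "r": ParamSpec(0.5, -math.inf, math.inf, "intrinsic growth rate (1/time)"),
                "K": ParamSpec(100.0, 1e-12, math.inf, "carrying capacity (individuals)"),
            },
            dynamics=lambda t, y, p: np.array([p["r"] * y[0] * (1.0 - y[0] / p["K"])]),
            closed_forms={
                "solution": _logistic_solution,
                "equilibria": lambda p: [{"N": 0.0}, {"N": p["K"]}],
            },
        )
    if kind == "exp_disc":
        return ModelSpec(
            id="single-pop-discrete",
            variant="exponential",
            kind="discrete",
            state_names=["N"],
            param_schema={"lam": ParamSpec(1.5, 0.0, math.inf, "per-step growth factor")},
            dynamics=lambda y, p: np.array([p["lam"] * y[0]]),
            closed_forms={"equilibria": lambda p: [{"N": 0.0}]},
        )
    if kind == "logistic_disc":
        return ModelSpec(
            id="single-pop-discrete",
            variant="logistic",
            kind="discrete",
            state_names=["N"],
            param_schema={
                "r": ParamSpec(0.5, -math.inf, math.inf, "per-step growth increment"),
                "K": ParamSpec(100.0, 1e-12, math.inf, "carrying capacity"),
            },
            dynamics=lambda y, p: np.array([y[0] + p["r"] * y[0] * (1.0 - y[0] / p["K"])]),
            closed_forms={"equilibria": lambda p: [{"N": 0.0}, {"N": p["K"]}]},
        )
    if kind == "beverton_holt":
        return ModelSpec(
            id="single-pop-discrete",
            variant="beverton-holt",
            kind="discrete",
            state_names=["N"],
            param_schema={
                "R": ParamSpec(2.0, 1e-12, math.inf, "per-step growth factor"),
                "K": ParamSpec(100.0, 1e-12, math.inf, "nontrivial fixed point"),
            },
            dynamics=lambda y, p: np.array(
                [p["R"] * y[0] / (1.0 + ((p["R"] - 1.0) / p["K"]) * y[0])]
            ),
            closed_forms={"equilibria": lambda p: [{"N": 0.0}, {"N": p["K"]}]},
        )
    if kind == "ricker":
        return ModelSpec(
            id="single-pop-discrete",
            variant="ricker",
            kind="discrete",
            state_names=["N"],
            param_schema={
                "r": ParamSpec(0.5, -math.inf, math.inf, "per-step growth rate"),
                "K": ParamSpec(100.0, 1e-12, math.inf, "carrying capacity"),
            },
            dynamics=lambda y, p: np.array([y[0] * math.exp(p["r"] * (1.0 - y[0] / p["K"]))]),
            closed_forms={"equilibria": lambda p: [{"N": 0.0}, {"N": p["K"]}]},
        )
    raise KeyError(f"unknown single-population model kind {kind!r}")


def cobweb(spec: ModelSpec, params, N0: float, n_steps: int) -> list[tuple[float, float]]:
    """Cobweb staircase for a one-state discrete map.

    Returns the ordered path (N0, N0) -> (N0, f(N0)) -> (f(N0), f(N0)) -> ...
    with ``2*n_steps + 1`` points.  Every second point projected to its x
    coordinate recovers the plain iteration sequence.
    """
    if spec.kind != "discrete":
        raise TypeError("cobweb requires a discrete map")
    if spec.n_states != 1:
        raise TypeError("cobweb requires a single-state map")
    if n_steps < 0:
        raise DomainError("n_steps must be >= 0")
    p = validate_params(spec, params)
    pts = [(float(N0), float(N0))]
    x = float(N0)
    for _ in range(n_steps):
        y = float(spec.dynamics(np.array([x]), p)[0])
        pts.append((x, y))
        pts.append((y, y))
        x = y
    return pts
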