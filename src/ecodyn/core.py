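"""Generic simulation engine: model specs, parameter validation, ODE
integration and discrete-map iteration.

Every model in the package is described by a :class:`ModelSpec` — an ordered
list of state names, a parameter schema (bounds + defaults), and either a
continuous-time derivative rule or a discrete-time update map.  The two
engine entry points, :func:`integrate_ode` and :func:`iterate_map`, turn a
spec plus a parameter set and initial state into a :class:`Trajectory`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "ParamSpec",
    "ModelSpec",
    "Trajectory",
    "SchemaError",
    "DomainError",
    "IntegrationError",
    "validate_params",
    "validate_init",
    "integrate_ode",
    "iterate_map",
]

#: states within this distance of zero are clamped to exactly zero
EPS_CLAMP = 1e-12
#: a state this far below zero signals a mis-specified model and raises
HARD_NEGATIVE = -1e-9


class SchemaError(ValueError):
    """A parameter is missing, non-finite, or outside its declared bounds."""

    def __init__(self, message: str, param: str | None = None):
        super().__init__(message)
        self.param = param


class DomainError(ValueError):
    """An input is outside the mathematical domain of an operation."""


class IntegrationError(RuntimeError):
    """The ODE solver failed; ``last_time`` is the last successful time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


@dataclass(frozen=True)
class ParamSpec:
    """Bounds and default for one named parameter.

    Bounds are closed; use ``math.inf`` for an unbounded side.
    """

    default: float
    lower: float = 0.0
    upper: float = math.inf
    doc: str = ""


@dataclass
class ModelSpec:
    """Registry entry binding a model family/variant to its dynamics.

    Parameters
    ----------
    id
        Model family identifier (e.g. ``"predator-prey"``).
    kind
        ``"continuous"`` (derivative rule) or ``"discrete"`` (update map).
    state_names
        Ordered state-variable names; trajectory columns use this order.
    param_schema
        Mapping name -> :class:`ParamSpec`.
    dynamics
        ``f(t, y, p) -> dy/dt`` for continuous specs, ``f(y, p) -> y_next``
        for discrete specs, where ``y`` is an ndarray in ``state_names``
        order and ``p`` a validated parameter dict.
    closed_forms
        Optional registry of analytic helpers (solutions, equilibria,
        nullclines) keyed by name; each is checked numerically in tests.
    """

    id: str
    kind: str
    state_names: list[str]
    param_schema: dict[str, ParamSpec]
    dynamics: Callable
    variant: str | None = None
    closed_forms: dict[str, Callable] = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.state_names)


def validate_params(spec: ModelSpec, params: Mapping[str, float] | None) -> dict[str, float]:
    """Validate ``params`` against the spec schema, filling defaults.

    Raises :class:`SchemaError` naming the offending parameter if a value
    is unknown, non-finite, or out of bounds.
    """
    params = dict(params or {})
    out: dict[str, float] = {}
    for name in params:
        if name not in spec.param_schema:
            raise SchemaError(f"unknown parameter {name!r} for model {spec.id!r}", param=name)
    for name, ps in spec.param_schema.items():
        if name not in params and math.isnan(ps.default):
            raise SchemaError(
                f"missing required parameter {name!r} for model {spec.id!r}", param=name
            )
        value = float(params.get(name, ps.default))
        if not math.isfinite(value):
            raise SchemaError(f"parameter {name!r} must be finite, got {value}", param=name)
        if not (ps.lower <= value <= ps.upper):
            raise SchemaError(
                f"parameter {name!r}={value} outside bounds [{ps.lower}, {ps.upper}]",
                param=name,
            )
        out[name] = value
    return out


def validate_init(spec: ModelSpec, init: Mapping[str, float]) -> np.ndarray:
    """Validate an initial state against the spec; returns an ordered array."""
    extra = set(init) - set(spec.state_names)
    if extra:
        raise SchemaError(f"unknown state name(s) {sorted(extra)} for model {spec.id!r}")
    missing = set(spec.state_names) - set(init)
    if missing:
        raise SchemaError(f"missing initial state(s) {sorted(missing)} for model {spec.id!r}")
    y0 = np.array([float(init[s]) for s in spec.state_names], dtype=float)
    if not np.all(np.isfinite(y0)):
        raise SchemaError("initial state must be finite")
    if np.any(y0 < 0):
        raise SchemaError("initial state must be nonnegative")
    return y0


@dataclass
class Trajectory:
    """Time grid plus per-state abundance matrix with run metadata."""

    time: np.ndarray
    states: np.ndarray
    state_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        if self.states.shape[0] != self.time.shape[0]:
            raise ValueError("states row count must equal time-grid length")
        if self.states.shape[1] != len(self.state_names):
            raise ValueError("states column count must equal number of state names")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.state_names.index(name)]

    def final(self) -> dict[str, float]:
        """Last state as a name -> value mapping."""
        return dict(zip(self.state_names, self.states[-1]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.state_names)
        df.insert(0, "time", self.time)
        return df

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write ``time,<state1>,...`` CSV at 10 significant digits, with
        run metadata in a ``.json`` sidecar."""
        self.to_frame().to_csv(path, index=False, float_format="%.10g")
        if sidecar:
            with open(str(path) + ".json", "w") as fh:
                json.dump(self.meta, fh, indent=2, default=str)


def _make_meta(spec: ModelSpec, params: dict, extra: dict | None = None) -> dict:
    meta = {"model": spec.id, "variant": spec.variant, "params": dict(params)}
    if extra:
        meta.update(extra)
    return meta


def integrate_ode(
    spec: ModelSpec,
    params: Mapping[str, float] | None,
    init: Mapping[str, float],
    t_end: float,
    dt_out: float = 0.1,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
) -> Trajectory:
    """Integrate a continuous-time spec, sampling at ``t = 0, dt_out, ..., t_end``.

    Adaptive RK45 with dense output resampled onto the user grid.  States
    within ``EPS_CLAMP`` of zero are clamped to zero; a state falling below
    ``HARD_NEGATIVE`` raises :class:`IntegrationError` (a negative abundance
    of that size signals a mis-specified model, not round-off).
    """
    if spec.kind != "continuous":
        raise TypeError(f"model {spec.id!r} is not a continuous-time model")
    if t_end <= 0:
        raise DomainError("t_end must be > 0")
    if dt_out <= 0:
        raise DomainError("dt_out must be > 0")
    p = validate_params(spec, params)
    y0 = validate_init(spec, init)

    n = int(round(t_end / dt_out))
    t_eval = np.arange(n + 1) * dt_out
    if t_eval[-1] < t_end - 1e-12 * max(1.0, t_end):
        t_eval = np.append(t_eval, t_end)
    t_eval[-1] = min(t_eval[-1], t_end)

    sol = solve_ivp(
        spec.dynamics,
        (0.0, float(t_end)),
        y0,
        method="RK45",
        t_eval=t_eval,
        rtol=rel_tol,
        atol=abs_tol,
        args=(p,),
        dense_output=False,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(f"integration failed: {sol.message}", last_time=last)

    states = sol.y.T.copy()
    low = states.min()
    if low < HARD_NEGATIVE:
        t_bad = float(sol.t[np.argmax(np.any(states < HARD_NEGATIVE, axis=1))])
        raise IntegrationError(
            f"state fell to {low:.3e} (below {HARD_NEGATIVE}); model misspecification",
            last_time=t_bad,
        )
    states[np.abs(states) < EPS_CLAMP] = 0.0
    states[(states < 0) & (states >= HARD_NEGATIVE)] = 0.0

    return Trajectory(
        time=sol.t,
        states=states,
        state_names=list(spec.state_names),
        meta=_make_meta(spec, p, {"t_end": t_end, "dt_out": dt_out, "rel_tol": rel_tol}),
    )


def iterate_map(
    spec: ModelSpec,
    params: Mapping[str, float] | None,
    init: Mapping[str, float],
    n_steps: int,
) -> Trajectory:
    """Iterate a discrete-time spec for ``n_steps`` steps (``n_steps + 1`` rows).

    Exact floating-point arithmetic, no clamping: a population hitting zero
    is extinct exactly, and reruns are bit-identical.
    """
    if spec.kind != "discrete":
        raise TypeError(f"model {spec.id!r} is not a discrete-time model")
    if n_steps < 0:
        raise DomainError("n_steps must be >= 0")
    p = validate_params(spec, params)
    y = validate_init(spec, init)

    rows = np.empty((n_steps + 1, spec.n_states), dtype=float)
    rows[0] = y
    for t in range(n_steps):
        y = np.asarray(spec.dynamics(y, p), dtype=float)
        rows[t + 1] = y

    return Trajectory(
        time=np.arange(n_steps + 1, dtype=float),
        states=rows,
        state_names=list(spec.state_names),
        meta=_make_meta(spec, p, {"n_steps": n_steps}),
    )
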