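"""Cross-model phase-plane analysis.

Vector fields, nullclines, equilibrium finding (closed forms plus
multi-start Newton), linear stability classification by Jacobian
eigenvalues, and the Rosenzweig-MacArthur enrichment threshold — the prey
carrying capacity at which the coexistence equilibrium crosses the hump of
the prey isocline and loses stability (the paradox of enrichment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root

from .core import DomainError, ModelSpec, validate_params
from .interactions import predprey_spec

__all__ = [
    "EquilibriumReport",
    "vector_field",
    "nullclines",
    "find_equilibria",
    "jacobian",
    "classify_equilibrium",
    "peak_amplitudes",
    "rm_enrichment_threshold",
]

#: eigenvalue real parts within this of zero are treated as marginal
TAU_EIG = 1e-7
#: equilibria closer than this in L-infinity norm are merged
MERGE_TOL = 1e-6


@dataclass
class EquilibriumReport:
    """An equilibrium state with its eigenvalues and stability class."""

    state: dict[str, float]
    eigenvalues: np.ndarray
    classification: str
    marginal: bool = False
    meta: dict = field(default_factory=dict)


def _rhs_at(spec: ModelSpec, p: dict, y: np.ndarray) -> np.ndarray:
    return np.asarray(spec.dynamics(0.0, y, p), dtype=float)


def vector_field(spec, params, x_state: str, y_state: str, x_grid, y_grid, fixed=None):
    """Evaluate (dx/dt, dy/dt) on a rectangular grid over two chosen states.

    Other states are held at the values in ``fixed``.  Returns an array of
    rows (x, y, dx/dt, dy/dt); arrows are exact derivatives — any
    normalisation is a rendering concern.
    """
    if spec.kind != "continuous":
        raise TypeError("vector fields require a continuous-time model")
    p = validate_params(spec, params)
    fixed = dict(fixed or {})
    ix = spec.state_names.index(x_state)
    iy = spec.state_names.index(y_state)
    base = np.zeros(spec.n_states)
    for name, value in fixed.items():
        base[spec.state_names.index(name)] = value
    rows = []
    for xv in np.asarray(x_grid, dtype=float):
        for yv in np.asarray(y_grid, dtype=float):
            y0 = base.copy()
            y0[ix], y0[iy] = xv, yv
            d = _rhs_at(spec, p, y0)
            rows.append((xv, yv, d[ix], d[iy]))
    return np.array(rows)


def nullclines(spec, params, state_index: int, x_state: str, y_state: str,
               x_grid, y_grid, fixed=None, tol: float = 1e-8):
    """Zero-contours of one state's derivative in a two-state window.

    Uses the spec's registered closed forms when available for the model;
    otherwise locates sign changes of the chosen derivative along each grid
    column by bisection (to ``tol`` in state units).  Returns a list of
    curves, each an (n, 2) array of (x, y) points.
    """
    if spec.kind != "continuous":
        raise TypeError("nullclines require a continuous-time model")
    p = validate_params(spec, params)
    fixed = dict(fixed or {})
    ix = spec.state_names.index(x_state)
    iy = spec.state_names.index(y_state)
    base = np.zeros(spec.n_states)
    for name, value in fixed.items():
        base[spec.state_names.index(name)] = value

    def f(xv, yv):
        y0 = base.copy()
        y0[ix], y0[iy] = xv, yv
        return _rhs_at(spec, p, y0)[state_index]

    xs = np.asarray(x_grid, dtype=float)
    ys = np.asarray(y_grid, dtype=float)

    def scan(fixed_vals, scan_vals, g, orient):
        pts = []
        for fv in fixed_vals:
            vals = np.array([g(fv, sv) for sv in scan_vals])
            for k in range(len(scan_vals) - 1):
                a, b = vals[k], vals[k + 1]
                if a == 0.0:
                    pts.append((fv, scan_vals[k]))
                elif a * b < 0:
                    lo, hi = scan_vals[k], scan_vals[k + 1]
                    flo = a
                    while hi - lo > tol:
                        mid = 0.5 * (lo + hi)
                        fm = g(fv, mid)
                        if flo * fm <= 0:
                            hi = mid
                        else:
                            lo, flo = mid, fm
                    pts.append((fv, 0.5 * (lo + hi)))
        if orient == "col":
            return pts
        return [(y, x) for x, y in pts]

    # bisect along grid columns (x fixed) and rows (y fixed) so that both
    # near-horizontal and near-vertical contour branches are captured
    points = scan(xs, ys, f, "col") + scan(ys, xs, lambda yv, xv: f(xv, yv), "row")
    if not points:
        return []
    return [np.array(points)]


def find_equilibria(spec, params, box, n_starts: int = 8) -> list[dict]:
    """Equilibria inside a state-space box.

    Union of the spec's registered closed-form equilibria and damped-Newton
    roots started from an ``n_starts`` x ... lattice over the box; duplicates
    merged at L-infinity distance below ``MERGE_TOL``.  Every returned point
    has derivative magnitude below 1e-9.

    ``box`` maps each state name to (lo, hi).
    """
    if spec.kind != "continuous":
        raise TypeError("equilibrium search requires a continuous-time model")
    p = validate_params(spec, params)
    lo = np.array([box[s][0] for s in spec.state_names], dtype=float)
    hi = np.array([box[s][1] for s in spec.state_names], dtype=float)

    found: list[np.ndarray] = []

    def consider(y):
        y = np.asarray(y, dtype=float)
        if np.any(y < lo - MERGE_TOL) or np.any(y > hi + MERGE_TOL):
            return
        if np.max(np.abs(_rhs_at(spec, p, y))) >= 1e-9:
            return
        for prev in found:
            if np.max(np.abs(prev - y)) < MERGE_TOL:
                return
        found.append(np.clip(y, lo, hi))

    eq_form = spec.closed_forms.get("equilibria")
    if eq_form is not None:
        for eq in eq_form(p):
            consider([eq[s] for s in spec.state_names])

    grids = [np.linspace(l, h, n_starts) for l, h in zip(lo, hi)]
    mesh = np.meshgrid(*grids, indexing="ij")
    starts = np.column_stack([m.ravel() for m in mesh])
    fun = lambda y: _rhs_at(spec, p, y)
    for y0 in starts:
        sol = root(fun, y0, method="hybr", tol=1e-12)
        if sol.success:
            consider(sol.x)

    return [dict(zip(spec.state_names, y)) for y in found]


def jacobian(spec, params, eq, h_scale: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian at a state point.

    Step per coordinate: max(h_scale, h_scale * |x|).  Analytic closed-form
    Jacobians registered on the spec (key ``"jacobian"``) take precedence.
    """
    p = validate_params(spec, params)
    y = np.array([eq[s] for s in spec.state_names], dtype=float)
    jac_form = spec.closed_forms.get("jacobian")
    if jac_form is not None:
        return np.asarray(jac_form(p, y), dtype=float)
    n = spec.n_states
    J = np.empty((n, n))
    for j in range(n):
        h = max(h_scale, h_scale * abs(y[j]))
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        J[:, j] = (_rhs_at(spec, p, yp) - _rhs_at(spec, p, ym)) / (2 * h)
    return J


def classify_equilibrium(spec, params, eq, tau: float = TAU_EIG) -> EquilibriumReport:
    """Linear stability classification of an equilibrium.

    Eigenvalues of the Jacobian decide the class: all real parts negative ->
    stable node/spiral, all positive -> unstable node/spiral, mixed signs ->
    saddle.  Real parts within ``tau`` of zero with nonzero imaginary parts
    are reported as ``center`` with a marginal flag (a weakly damped spiral
    is numerically indistinguishable from a true center); all-zero-ish ->
    ``nonhyperbolic``.
    """
    p = validate_params(spec, params)
    y = np.array([eq[s] for s in spec.state_names], dtype=float)
    resid = np.max(np.abs(_rhs_at(spec, p, y)))
    if resid >= 1e-8:
        raise DomainError(f"not an equilibrium: |dy/dt| = {resid:.3e} >= 1e-8")
    eigs = np.linalg.eigvals(jacobian(spec, p, eq))
    re, im = eigs.real, eigs.imag
    has_imag = np.any(np.abs(im) > tau)
    marginal = np.any(np.abs(re) <= tau)
    if np.all(re < -tau):
        cls = "stable_spiral" if has_imag else "stable_node"
    elif np.all(re > tau):
        cls = "unstable_spiral" if has_imag else "unstable_node"
    elif np.any(re > tau) and np.any(re < -tau):
        cls = "saddle"
    elif marginal and has_imag:
        cls = "center"
    else:
        cls = "nonhyperbolic"
    return EquilibriumReport(
        state=dict(zip(spec.state_names, y)),
        eigenvalues=eigs,
        classification=cls,
        marginal=bool(marginal),
    )


def peak_amplitudes(traj, state: str, reference: float, t_min: float = 0.0,
                    t_max: float = math.inf) -> np.ndarray:
    """Deviations of successive local maxima of one state from a reference.

    Finds strict local maxima of ``state`` on the sampled grid within
    ``[t_min, t_max]`` and returns |peak - reference| in time order — the
    standard diagnostic for damped versus growing oscillations around an
    equilibrium at ``reference``.
    """
    x = traj[state]
    mask = (traj.time >= t_min) & (traj.time <= t_max)
    x = x[mask]
    if x.size < 3:
        return np.array([])
    interior = x[1:-1]
    is_peak = (interior > x[:-2]) & (interior > x[2:])
    return np.abs(interior[is_peak] - reference)


def rm_enrichment_threshold(params) -> float:
    """Critical prey carrying capacity of the Rosenzweig-MacArthur model.

    The coexistence equilibrium sits at prey density H* = d/(a(e - d*T_h));
    the prey isocline peaks at H = K/2 - 1/(2 a T_h).  The equilibrium sits
    exactly on the hump — the Hopf bifurcation of the paradox of enrichment
    — at

        K_crit = 2 H* + 1/(a T_h).

    K below K_crit gives a stable equilibrium (damped oscillations); K above
    gives unstable oscillations onto a limit cycle.
    """
    spec = predprey_spec("rosenzweig_macarthur")
    params = dict(params)
    params.setdefault("K", 1.0)  # threshold does not depend on K itself
    p = validate_params(spec, params)
    denom = p["a"] * (p["e"] - p["d"] * p["T_h"])
    if denom <= 0:
        raise DomainError("no interior equilibrium: requires e > d * T_h")
    H_star = p["d"] / denom
    return 2.0 * H_star + 1.0 / (p["a"] * p["T_h"])
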