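"""Matplotlib rendering: time series, cobwebs, and phase portraits."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .core import ModelSpec, Trajectory
from .phase import nullclines, vector_field

__all__ = ["plot_timeseries", "plot_cobweb", "plot_portrait"]


def plot_timeseries(traj: Trajectory, path=None, ax=None):
    """Abundance of every state against time."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for name in traj.state_names:
        ax.plot(traj.time, traj[name], label=name)
    ax.set_xlabel("time")
    ax.set_ylabel("abundance")
    ax.legend(frameon=False)
    ax.set_title(str(traj.meta.get("model", "")))
    if path:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax


def plot_cobweb(points, map_fn=None, path=None, ax=None):
    """Cobweb staircase with the map curve and the identity line."""
    pts = np.asarray(points, dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    hi = max(pts.max() * 1.1, 1.0)
    xs = np.linspace(0, hi, 200)
    ax.plot(xs, xs, "k--", lw=0.8, label="identity")
    if map_fn is not None:
        ax.plot(xs, [map_fn(x) for x in xs], "C0", label="map")
    ax.plot(pts[:, 0], pts[:, 1], "C3", lw=1.0)
    ax.set_xlabel("N(t)")
    ax.set_ylabel("N(t+1)")
    ax.legend(frameon=False)
    if path:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax


def plot_portrait(
    traj: Trajectory,
    spec: ModelSpec,
    params=None,
    x_state=None,
    y_state=None,
    path=None,
    with_vector_field: bool = True,
    with_nullclines: bool = True,
    n_grid: int = 15,
    ax=None,
):
    """Phase portrait: trajectory overlay, nullclines, and vector field."""
    x_state = x_state or spec.state_names[0]
    y_state = y_state or spec.state_names[1]
    x, y = traj[x_state], traj[y_state]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    x_hi = max(x.max() * 1.2, 1.0)
    y_hi = max(y.max() * 1.2, 1.0)
    xs = np.linspace(0, x_hi, n_grid)
    ys = np.linspace(0, y_hi, n_grid)

    if with_vector_field and params is not None:
        vf = vector_field(spec, params, x_state, y_state, xs, ys)
        u, v = vf[:, 2], vf[:, 3]
        norm = np.hypot(u, v)
        norm[norm == 0] = 1.0
        ax.quiver(vf[:, 0], vf[:, 1], u / norm, v / norm, norm,
                  cmap="Greys", alpha=0.6, scale=30, width=0.003)
    if with_nullclines and params is not None:
        ix = spec.state_names.index(x_state)
        iy = spec.state_names.index(y_state)
        for idx, color, label in ((ix, "C3", f"d{x_state}/dt=0"), (iy, "C0", f"d{y_state}/dt=0")):
            for curve in nullclines(spec, params, idx, x_state, y_state,
                                    np.linspace(1e-6, x_hi, 60), np.linspace(0, y_hi, 120)):
                ax.plot(curve[:, 0], curve[:, 1], ".", color=color, ms=2, label=label)
                label = None
    ax.plot(x, y, "k", lw=1.2)
    ax.plot(x[0], y[0], "ko", ms=5)
    ax.set_xlabel(x_state)
    ax.set_ylabel(y_state)
    ax.set_xlim(0, x_hi)
    ax.set_ylim(0, y_hi)
    if ax.get_legend_handles_labels()[0]:
        ax.legend(frameon=False, loc="upper right")
    if path:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax
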