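"""Run configurations: YAML/JSON loading, validation, and execution.

A :class:`RunConfig` names a model family and variant, a parameter set, an
initial state, and a time specification — ``t_end``/``dt_out`` for
continuous models, ``n_steps`` for discrete ones — plus optional output
paths.  Configs round-trip through :func:`write_config`/:func:`load_config`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import epidemiology, interactions, life_history, registry, structured
from .core import SchemaError, Trajectory, integrate_ode, iterate_map

__all__ = ["RunConfig", "ConfigError", "load_config", "write_config", "execute"]

_KNOWN_KEYS = {
    "model", "variant", "params", "init", "t_end", "n_steps", "dt_out",
    "rel_tol", "leslie", "out", "plot", "portrait", "seed",
}

#: default Leslie matrix for structured-population runs (three age classes,
#: a standard teaching example)
DEFAULT_LESLIE = [[0.0, 1.0, 5.0], [0.5, 0.0, 0.0], [0.0, 0.3, 0.0]]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    model: str
    variant: str | None = None
    params: dict = field(default_factory=dict)
    init: dict = field(default_factory=dict)
    t_end: float | None = None
    n_steps: int | None = None
    dt_out: float = 0.1
    rel_tol: float = 1e-8
    leslie: list | None = None
    out: str | None = None
    plot: str | None = None
    portrait: str | None = None
    seed: int | None = None  # reserved; bundled models are deterministic

    def validate(self) -> "RunConfig":
        family = registry.get_family(self.model)  # raises KeyError if unknown
        if self.t_end is not None and self.n_steps is not None:
            raise ConfigError("set exactly one of t_end (continuous) or n_steps (discrete)")
        if family.kind == "continuous" and self.n_steps is not None:
            raise ConfigError(f"{self.model} is continuous-time; use t_end, not n_steps")
        if family.kind == "discrete" and self.t_end is not None:
            raise ConfigError(f"{self.model} is discrete-time; use n_steps, not t_end")
        return self


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration.

    Unknown keys are errors, never silently ignored.
    """
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"cannot parse {path}{line}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping with at least a model id")
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s) {sorted(unknown)}")
    if "model" not in data:
        raise ConfigError(f"{path}: model id required")
    return RunConfig(**data).validate()


def write_config(config: RunConfig, path) -> None:
    data = {k: v for k, v in asdict(config).items() if v not in (None, {}, [])}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def _defaults_init(spec) -> dict:
    """A generic positive initial state when the config provides none."""
    return {s: 10.0 for s in spec.state_names}


def execute(config: RunConfig):
    """Run a validated config and return its primary result.

    Trajectory-producing families return a :class:`Trajectory`; the
    Smith-Fretwell family returns a dict with the fitness curve and the
    optimum.  Output files declared in the config are written.
    """
    config.validate()
    model = config.model
    if model in registry.ALIASES:
        fam_id, default_variant = registry.ALIASES[model]
        family = registry.REGISTRY[fam_id]
        variant = config.variant or default_variant
    else:
        family = registry.get_family(model)
        variant = config.variant or family.default_variant or family.variants[0]

    if family.id == "structured-population":
        L = structured.LeslieMatrix(config.leslie if config.leslie is not None else DEFAULT_LESLIE)
        n0 = config.init or {f"age{i + 1}": 10.0 for i in range(L.size)}
        n_steps = config.n_steps if config.n_steps is not None else 50
        result = structured.project_structured(L, n0, n_steps)
    elif family.id == "smith-fretwell":
        import numpy as np

        opt = life_history.optimal_investment(config.params)
        p = dict(life_history.DEFAULT_PARAMS)
        p.update(config.params or {})
        grid = np.linspace(0.0, p["I_min"] + 10 * p["c"], 401)
        curve = [(float(I), life_history.offspring_fitness(I, config.params)) for I in grid]
        result = {"optimum": opt, "fitness_curve": curve, "params": p}
        if config.out:
            import pandas as pd

            pd.DataFrame(curve, columns=["I", "W"]).to_csv(
                config.out, index=False, float_format="%.10g"
            )
            with open(str(config.out) + ".json", "w") as fh:
                json.dump(opt, fh, indent=2)
        return result
    else:
        spec = registry.make_spec(model, variant)
        init = config.init or _defaults_init(spec)
        if family.id == "infectious-disease":
            init = dict(init)
            if not config.init:
                # default scenario: one infected in an otherwise susceptible population
                from .core import validate_params

                N = validate_params(spec, config.params)["N"]
                init = {s: 0.0 for s in spec.state_names}
                init["I"] = 1.0
                init["S"] = N - 1.0
            result = epidemiology.run_compartment(
                variant, config.params, init, config.t_end or 100.0,
                dt_out=config.dt_out, rel_tol=config.rel_tol,
            )
        elif family.id == "mutualism":
            result = interactions.run_mutualism(
                config.params, init, config.t_end or 100.0,
                dt_out=config.dt_out, rel_tol=config.rel_tol,
            )
        elif spec.kind == "discrete":
            result = iterate_map(spec, config.params, init,
                                 config.n_steps if config.n_steps is not None else 100)
        else:
            # NaN-defaulted (required) parameters surface as SchemaError here
            result = integrate_ode(
                spec, config.params, init, config.t_end or 100.0,
                dt_out=config.dt_out, rel_tol=config.rel_tol,
            )

    if isinstance(result, Trajectory) and config.out:
        result.to_csv(config.out)
    return result
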