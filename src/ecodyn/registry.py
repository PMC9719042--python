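"""Registry of the twelve model families and their variants.

Each family corresponds to one interactive model suite: single-species
growth in continuous and in discrete time, structured (Leslie-matrix)
growth, mutualism, Lotka-Volterra competition, predator-prey dynamics,
competition for abiotic and for a biotic resource, infectious-disease
compartment models, island biogeography, the Smith-Fretwell seed size/number
trade-off, and source-sink metapopulation dynamics.

Families whose dynamics fit the generic spec machinery expose
``make_spec(variant)``; the two that do not (Leslie projection, whose
parameter is a matrix, and Smith-Fretwell, which is a static optimisation)
are marked ``special`` and handled by their own modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from . import epidemiology, interactions, resources, single_population, spatial
from .core import ModelSpec

__all__ = ["ModelFamily", "REGISTRY", "ALIASES", "get_family", "make_spec", "list_models"]


@dataclass(frozen=True)
class ModelFamily:
    id: str
    label: str
    kind: str  # continuous | discrete | special
    variants: tuple[str, ...]
    make_spec: Callable[[str], ModelSpec] | None = None
    default_variant: str | None = None
    notes: str = ""

    @property
    def param_summary(self) -> str:
        if self.make_spec is None:
            return self.notes
        spec = self.make_spec(self.default_variant or self.variants[0])
        return ", ".join(spec.param_schema)


def _single_cont(variant):
    return single_population.make_single_pop_spec(
        {"exponential": "exp_cont", "logistic": "logistic_cont"}[variant]
    )


def _single_disc(variant):
    return single_population.make_single_pop_spec(
        {
            "exponential": "exp_disc",
            "logistic": "logistic_disc",
            "beverton-holt": "beverton_holt",
            "ricker": "ricker",
        }[variant]
    )


def _one(make):
    return lambda variant=None: make()


REGISTRY: dict[str, ModelFamily] = {
    f.id: f
    for f in [
        ModelFamily(
            "single-pop-continuous",
            "Population dynamics in continuous time",
            "continuous",
            ("exponential", "logistic"),
            _single_cont,
            "logistic",
        ),
        ModelFamily(
            "single-pop-discrete",
            "Population dynamics in discrete time",
            "discrete",
            ("exponential", "logistic", "beverton-holt", "ricker"),
            _single_disc,
            "logistic",
        ),
        ModelFamily(
            "structured-population",
            "Structured population growth",
            "special",
            ("leslie",),
            None,
            notes="Leslie matrix (fecundities + survivals)",
        ),
        ModelFamily(
            "mutualism",
            "Mutualism",
            "continuous",
            ("lv",),
            _one(interactions.mutualism_spec),
        ),
        ModelFamily(
            "lv-competition",
            "Lotka-Volterra competition",
            "continuous",
            ("lv",),
            _one(interactions.lv_competition_spec),
        ),
        ModelFamily(
            "predator-prey",
            "Predator-prey dynamics",
            "continuous",
            interactions.PREDPREY_VARIANTS,
            interactions.predprey_spec,
            "lv",
        ),
        ModelFamily(
            "abiotic-comp",
            "Competition for abiotic resources",
            "continuous",
            ("tilman",),
            _one(resources.abiotic_comp_spec),
        ),
        ModelFamily(
            "biotic-comp",
            "Competition for a biotic resource",
            "continuous",
            ("default",),
            _one(resources.biotic_comp_spec),
        ),
        ModelFamily(
            "infectious-disease",
            "Compartment models of infectious disease dynamics",
            "continuous",
            epidemiology.EPI_VARIANTS,
            epidemiology.compartment_spec,
            "sir",
        ),
        ModelFamily(
            "island-biogeo",
            "Island biogeography",
            "continuous",
            ("macarthur-wilson",),
            _one(spatial.island_spec),
        ),
        ModelFamily(
            "smith-fretwell",
            "Smith-Fretwell model (seed size/number trade-off)",
            "special",
            ("default",),
            None,
            notes="R, I_min, c, W_max",
        ),
        ModelFamily(
            "source-sink",
            "Metapopulation dynamics (source-sink)",
            "discrete",
            ("pulliam",),
            _one(spatial.source_sink_spec),
        ),
    ]
}

#: shorthand CLI ids mapping to (family, variant)
ALIASES: dict[str, tuple[str, str]] = {
    "exp-cont": ("single-pop-continuous", "exponential"),
    "logistic-cont": ("single-pop-continuous", "logistic"),
    "exp-disc": ("single-pop-discrete", "exponential"),
    "logistic-disc": ("single-pop-discrete", "logistic"),
    "beverton-holt": ("single-pop-discrete", "beverton-holt"),
    "ricker": ("single-pop-discrete", "ricker"),
    "predprey": ("predator-prey", "lv"),
    "sir": ("infectious-disease", "sir"),
}


def get_family(model_id: str) -> ModelFamily:
    if model_id in REGISTRY:
        return REGISTRY[model_id]
    if model_id in ALIASES:
        return REGISTRY[ALIASES[model_id][0]]
    raise KeyError(f"unknown model id {model_id!r}")


def make_spec(model_id: str, variant: str | None = None) -> ModelSpec:
    """Resolve a model id (family or alias) and variant to a ModelSpec."""
    if model_id in ALIASES:
        fam_id, default_variant = ALIASES[model_id]
        family = REGISTRY[fam_id]
        variant = variant or default_variant
    else:
        family = get_family(model_id)
        variant = variant or family.default_variant or family.variants[0]
    if family.make_spec is None:
        raise TypeError(f"model family {family.id!r} has no generic spec; use its module API")
    if variant not in family.variants:
        # accept hyphenated spellings of underscore variants (CLI friendliness)
        alt = variant.replace("-", "_")
        if alt in family.variants:
            variant = alt
        else:
            raise KeyError(f"unknown variant {variant!r} for family {family.id!r}")
    return family.make_spec(variant)


def list_models() -> list[dict]:
    """One row per model family, with variants and parameter summary."""
    return [
        {
            "id": f.id,
            "label": f.label,
            "kind": f.kind,
            "variants": list(f.variants),
            "params": f.param_summary,
        }
        for f in REGISTRY.values()
    ]
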