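"""Model configuration: schema, validation, loading.

A model configuration is a structured-text (YAML) document with four
sections:

``species``
    Ordered list of compartment names tracked by the base network.  The
    three drug compartments (``D_alpha``, ``D_12``, ``D_10``) are implicit
    and always appended after the listed species.

``params``
    Mapping of rate-constant name to value (per week) with a provenance
    tag: ``nominal`` (shipped order-of-magnitude value), ``transcribed``
    (transcribed from the published base-network source) or ``user``.

``terms``
    The base-network rate laws, as a registry of additive terms.  Four
    kinds are supported: ``constant`` (zeroth-order source *k*),
    ``linear`` (*k·X*), ``hill`` (saturating modulation *k·X/(ζ+Y)*,
    where ``Y`` may equal ``X`` for Michaelis–Menten saturation) and
    ``decay`` (first-order loss *−k·X* of the target itself).

``drug_params``
    Binding/neutralization, conversion and clearance rates of the three
    interventions.

The rate laws of TNF-α (``I_alpha``), IL-12 (``I_12``) and IL-10
(``I_10``), including their coupling to the drug compartments, are built
in (see :mod:`ibdsim.model`); a species listed in ``replace_builtin``
has its built-in law dropped in favour of registry terms, which is how an
alternative reading of the IL-10 production law can be swapped in.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "ConfigError",
    "ParamSpec",
    "TermSpec",
    "ModelConfig",
    "CaseSpec",
    "DoseSpec",
    "load_model_config",
    "load_yaml",
    "apply_overrides",
]

#: species that the built-in cytokine/drug rate laws reference and that must
#: therefore be present in every configuration
REQUIRED_SPECIES = (
    "M1", "M2", "Th1", "Treg", "I_alpha", "I_12", "I_10", "I_gamma", "I_2",
)

#: rate constants consumed by the built-in cytokine rate laws
REQUIRED_PARAMS = (
    "v_alpha_M", "v_alpha_1", "delta_alpha",
    "v_12M", "zeta_10", "delta_12",
    "v_10M", "v_10r", "n_2r", "zeta_2", "delta_10",
)

#: drug compartments, appended (in this order) after the configured species
DRUG_COMPARTMENTS = ("D_alpha", "D_12", "D_10")

DRUG_PARAM_NAMES = (
    "sigma_D_alpha", "delta_D_alpha",
    "sigma_D_12", "delta_D_12",
    "v_D10", "delta_D_10",
)

#: species whose rate laws (with drug coupling) are hard-wired
BUILTIN_SPECIES = ("I_alpha", "I_12", "I_10")


class ConfigError(ValueError):
    """Raised when a configuration document fails schema validation."""


class ParamSpec(BaseModel):
    """A rate constant with provenance."""

    model_config = ConfigDict(frozen=True)

    value: float = Field(ge=0.0, description="rate constant, per week")
    provenance: Literal["nominal", "transcribed", "user"] = "nominal"


class TermSpec(BaseModel):
    """One additive term of a registry species' rate law."""

    model_config = ConfigDict(frozen=True)

    target: str
    kind: Literal["constant", "linear", "hill", "decay"]
    rate: str
    source: Optional[str] = None
    modulator: Optional[str] = None
    zeta: Optional[str] = None

    @model_validator(mode="after")
    def _check_fields_for_kind(self) -> "TermSpec":
        need = {
            "constant": (),
            "linear": ("source",),
            "hill": ("source", "modulator", "zeta"),
            "decay": (),
        }[self.kind]
        for f in need:
            if getattr(self, f) is None:
                raise ValueError(f"{self.kind} term on {self.target!r} requires {f!r}")
        return self


class DoseSpec(BaseModel):
    """Nominal per-infusion magnitude: rate (conc/week) over a duration (weeks)."""

    model_config = ConfigDict(frozen=True)

    rate: float = Field(gt=0.0)
    duration: float = Field(gt=0.0)
    provenance: Literal["nominal", "transcribed", "user"] = "nominal"


class ModelConfig(BaseModel):
    """Validated full-model configuration (base network + drug parameters)."""

    model_config = ConfigDict(frozen=True)

    name: str = "model"
    species: tuple[str, ...]
    params: dict[str, ParamSpec]
    terms: tuple[TermSpec, ...]
    drug_params: dict[str, ParamSpec]
    replace_builtin: tuple[str, ...] = ()

    @field_validator("params", "drug_params", mode="before")
    @classmethod
    def _coerce_bare_numbers(cls, v):
        if isinstance(v, dict):
            return {
                k: ({"value": float(x)} if isinstance(x, (int, float)) else x)
                for k, x in v.items()
            }
        return v

    @model_validator(mode="after")
    def _cross_check(self) -> "ModelConfig":
        sp = self.species
        if len(set(sp)) != len(sp):
            raise ValueError("species names must be unique")
        for name in REQUIRED_SPECIES:
            if name not in sp:
                raise ValueError(f"required species {name!r} missing")
        for name in DRUG_COMPARTMENTS:
            if name in sp:
                raise ValueError(f"{name!r} is an implicit drug compartment; do not list it")
        for name in REQUIRED_PARAMS:
            if name not in self.params:
                raise ValueError(f"required parameter {name!r} missing")
        for name in ("zeta_10", "zeta_2"):
            if self.params[name].value <= 0.0:
                raise ValueError(f"{name} must be > 0")
        missing = [n for n in DRUG_PARAM_NAMES if n not in self.drug_params]
        if missing:
            raise ValueError(f"drug parameters missing: {missing}")
        for name in self.replace_builtin:
            if name not in BUILTIN_SPECIES:
                raise ValueError(f"replace_builtin entry {name!r} is not a built-in species")
        spset = set(sp)
        for t in self.terms:
            if t.target not in spset:
                raise ValueError(f"term targets unknown species {t.target!r}")
            if t.target in BUILTIN_SPECIES and t.target not in self.replace_builtin:
                raise ValueError(
                    f"species {t.target!r} has a built-in rate law; "
                    "list it in replace_builtin to override"
                )
            for ref in (t.source, t.modulator):
                if ref is not None and ref not in spset and ref not in DRUG_COMPARTMENTS:
                    raise ValueError(f"term on {t.target!r} references unknown species {ref!r}")
            for pname in (t.rate, t.zeta):
                if pname is not None and pname not in self.params:
                    raise ValueError(f"term on {t.target!r} references unknown parameter {pname!r}")
            if t.zeta is not None and self.params[t.zeta].value <= 0.0:
                raise ValueError(f"half-saturation constant {t.zeta!r} must be > 0")
        targets_with_builtin_override = set(self.replace_builtin)
        for name in targets_with_builtin_override:
            if not any(t.target == name for t in self.terms):
                raise ValueError(f"replace_builtin lists {name!r} but no terms target it")
        return self

    def param_values(self) -> dict[str, float]:
        return {k: v.value for k, v in self.params.items()}

    def drug_param_values(self) -> dict[str, float]:
        return {k: v.value for k, v in self.drug_params.items()}


class CaseSpec(BaseModel):
    """A patient case: multiplicative overrides of a baseline configuration."""

    model_config = ConfigDict(frozen=True)

    name: str
    base: str = "healthy"
    overrides: dict[str, float] = {}
    provenance: Literal["nominal", "transcribed", "user"] = "nominal"
    note: str = ""

    @field_validator("overrides")
    @classmethod
    def _positive_factors(cls, v):
        for k, f in v.items():
            if not f > 0.0:
                raise ValueError(f"override factor for {k!r} must be > 0")
        return v


def load_yaml(path: Union[str, Path]) -> dict:
    with open(path, "r") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return doc


def load_model_config(source: Union[str, Path, dict]) -> ModelConfig:
    """Load and validate a model configuration from a YAML file or dict."""
    doc = load_yaml(source) if isinstance(source, (str, Path)) else source
    try:
        return ModelConfig.model_validate(doc)
    except Exception as exc:  # pydantic ValidationError or ValueError
        raise ConfigError(str(exc)) from exc


def apply_overrides(config: ModelConfig, factors: dict[str, float]) -> ModelConfig:
    """Return a new configuration with parameters scaled by multiplicative factors.

    Factors may address base-network parameters or drug parameters; unknown
    names raise :class:`ConfigError`.  Provenance of a scaled parameter is
    downgraded to ``nominal`` unless it was ``user``.
    """
    params = dict(config.params)
    drug_params = dict(config.drug_params)
    for name, factor in factors.items():
        if not factor > 0.0:
            raise ConfigError(f"override factor for {name!r} must be > 0")
        if name in params:
            old = params[name]
            params[name] = ParamSpec(value=old.value * factor, provenance=old.provenance)
        elif name in drug_params:
            old = drug_params[name]
            drug_params[name] = ParamSpec(value=old.value * factor, provenance=old.provenance)
        else:
            raise ConfigError(f"override addresses unknown parameter {name!r}")
    return config.model_copy(update={"params": params, "drug_params": drug_params})
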