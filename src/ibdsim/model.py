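"""State space, parameters and right-hand sides of the immune-network ODE system.

The model tracks macrophages (M1, M2), helper and regulatory T cells
(Th1, Th2, Th17, Treg) and their cytokines (TNF-α, IL-12, IL-10, IFN-γ,
IL-2, IL-4), all as concentrations (g/cm³, time in weeks), together with
three drug compartments:

``D_alpha``
    anti-TNF-α antibody; binds and neutralizes TNF-α by mass action
    (term σ·I·D, lost symmetrically from cytokine and antibody).
``D_12``
    anti-IL-12 antibody; same neutralization mechanism.
``D_10``
    recombinant IL-10; a fraction ``v_D10`` per week acts as endogenous
    IL-10 while the compartment clears at ``delta_D_10``.

State-vector order is fixed: the configured species in configuration
order, then ``D_alpha``, ``D_12``, ``D_10``.

The rate laws of the three drug-coupled cytokines are built in:

* dI_α/dt = v_αM·M1 + v_α1·Th1 − δ_α·I_α − σ_Dα·I_α·D_α
* dI_12/dt = v_12M·M1/(1 + I_10/ζ_10) − δ_12·I_12 − σ_D12·I_12·D_12
* dI_10/dt = v_10M·M2 + v_10r·[1 + n_2r·I_γ/(ζ_2 + I_2)]·Treg
  − δ_10·I_10 + v_D10·D_10

with antibody compartments dD/dt = v_M(t) − σ·I·D − δ_D·D and the
recombinant-cytokine compartment dD_10/dt = v_M(t) − δ_D10·D_10.  Note
the v_D10·D_10 source in I_10 has no matching sink in D_10; δ_D10 is
interpreted as total elimination including conversion (documented, not
"fixed").  All remaining species evolve under configurable registry
terms (see :mod:`ibdsim.config`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .config import (
    BUILTIN_SPECIES,
    DRUG_COMPARTMENTS,
    ModelConfig,
    apply_overrides,
    load_model_config,
)

__all__ = [
    "TherapyMode",
    "ImmuneState",
    "BaseParameters",
    "DrugParameters",
    "ImmuneModel",
    "rhs_tnf_alpha",
    "rhs_il12",
    "rhs_il10",
]


class TherapyMode(str, enum.Enum):
    """Which drug compartment receives the infusion v_M(t)."""

    NONE = "none"
    ANTI_TNF = "anti_tnf"
    ANTI_IL12 = "anti_il12"
    IL10 = "il10"

    @property
    def target_drug(self) -> Optional[str]:
        return {
            TherapyMode.NONE: None,
            TherapyMode.ANTI_TNF: "D_alpha",
            TherapyMode.ANTI_IL12: "D_12",
            TherapyMode.IL10: "D_10",
        }[self]

    @classmethod
    def parse(cls, text: str) -> "TherapyMode":
        return cls(text.strip().lower().replace("-", "_"))


def _check_nonnegative(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or value < 0.0:
        raise ValueError(f"{name} must be finite and >= 0, got {value}")
    return value


@dataclass(frozen=True)
class DrugParameters:
    """Binding/neutralization, conversion and clearance rates of the drugs.

    ``sigma_*`` are mass-action neutralization rates (1/(conc·week)),
    ``delta_*`` clearance rates (1/week) and ``v_D10`` the rate at which
    the recombinant drug acts as IL-10 (1/week).
    """

    sigma_D_alpha: float
    delta_D_alpha: float
    sigma_D_12: float
    delta_D_12: float
    v_D10: float
    delta_D_10: float

    def __post_init__(self):
        for f in self.__dataclass_fields__:
            _check_nonnegative(f, getattr(self, f))

    @classmethod
    def from_mapping(cls, m: Mapping[str, float]) -> "DrugParameters":
        return cls(**{f: float(m[f]) for f in cls.__dataclass_fields__})


@dataclass(frozen=True)
class BaseParameters:
    """Rate constants of the drug-coupled cytokine laws plus the open-ended
    map of base-network constants (``extra``) consumed by registry terms."""

    v_alpha_M: float
    v_alpha_1: float
    delta_alpha: float
    v_12M: float
    zeta_10: float
    delta_12: float
    v_10M: float
    v_10r: float
    n_2r: float
    zeta_2: float
    delta_10: float
    extra: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for f in self.__dataclass_fields__:
            if f == "extra":
                continue
            _check_nonnegative(f, getattr(self, f))
        for name in ("zeta_10", "zeta_2"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")
        for k, v in self.extra.items():
            _check_nonnegative(k, v)

    @classmethod
    def from_mapping(cls, m: Mapping[str, float]) -> "BaseParameters":
        named = {f for f in cls.__dataclass_fields__ if f != "extra"}
        return cls(
            **{f: float(m[f]) for f in named},
            extra={k: float(v) for k, v in m.items() if k not in named},
        )

    def __getitem__(self, name: str) -> float:
        if name in self.__dataclass_fields__ and name != "extra":
            return getattr(self, name)
        return self.extra[name]


class ImmuneState:
    """Concentrations of all compartments at one time point.

    Thin immutable wrapper around a name tuple and a value vector; the
    order matches the owning model's state-vector order.
    """

    __slots__ = ("names", "values", "_index")

    def __init__(self, names: Iterable[str], values: Iterable[float]):
        names = tuple(names)
        values = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                            dtype=float).copy()
        if len(names) != values.size:
            raise ValueError("names and values differ in length")
        if len(set(names)) != len(names):
            raise ValueError("compartment names must be unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("concentrations must be finite")
        if np.any(values < 0.0):
            bad = [n for n, v in zip(names, values) if v < 0.0]
            raise ValueError(f"negative concentration(s): {bad}")
        values.flags.writeable = False
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(names)})

    def __setattr__(self, *a):  # immutability
        raise AttributeError("ImmuneState is immutable")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self._index[name]])

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __len__(self) -> int:
        return len(self.names)

    def __repr__(self) -> str:
        pairs = ", ".join(f"{n}={v:.4g}" for n, v in zip(self.names, self.values))
        return f"ImmuneState({pairs})"

    def to_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names), name="concentration")

    def replace(self, **updates: float) -> "ImmuneState":
        d = self.to_dict()
        for k, v in updates.items():
            if k not in d:
                raise KeyError(k)
            d[k] = v
        return ImmuneState(self.names, [d[n] for n in self.names])

    @classmethod
    def from_dict(cls, names: Iterable[str], mapping: Mapping[str, float],
                  default: float = 0.0) -> "ImmuneState":
        names = tuple(names)
        return cls(names, [float(mapping.get(n, default)) for n in names])


# ---------------------------------------------------------------------------
# built-in drug-coupled rate laws (scalar/array kernels)
# ---------------------------------------------------------------------------

def _tnf_terms(I_alpha, D_alpha, M1, Th1, v_alpha_M, v_alpha_1, delta_alpha,
               sigma, delta_D, vM):
    bind = sigma * I_alpha * D_alpha
    dI = v_alpha_M * M1 + v_alpha_1 * Th1 - delta_alpha * I_alpha - bind
    dD = vM - bind - delta_D * D_alpha
    return dI, dD


def _il12_terms(I_12, D_12, M1, I_10, v_12M, zeta_10, delta_12, sigma, delta_D, vM):
    bind = sigma * I_12 * D_12
    dI = v_12M * M1 / (1.0 + I_10 / zeta_10) - delta_12 * I_12 - bind
    dD = vM - bind - delta_D * D_12
    return dI, dD


def _il10_terms(I_10, D_10, M2, Treg, I_gamma, I_2,
                v_10M, v_10r, n_2r, zeta_2, delta_10, v_D10, delta_D, vM):
    treg_production = v_10r * (1.0 + n_2r * I_gamma / (zeta_2 + I_2)) * Treg
    dI = v_10M * M2 + treg_production - delta_10 * I_10 + v_D10 * D_10
    dD = vM - delta_D * D_10
    return dI, dD


def _require_state(state: ImmuneState, names: Iterable[str]) -> dict[str, float]:
    out = {}
    for n in names:
        if n not in state:
            raise ValueError(f"state lacks compartment {n!r}")
        out[n] = state[n]
    return out


def rhs_tnf_alpha(state: ImmuneState, base: BaseParameters, drugs: DrugParameters,
                  vM: float = 0.0) -> tuple[float, float]:
    """Time derivatives (dI_α/dt, dD_α/dt) of TNF-α and its antibody.

    TNF-α is produced by M1 macrophages and Th1 cells, decays first-order
    and is neutralized by the antibody by mass action; the bound complex
    is lost symmetrically from both compartments.
    """
    _check_nonnegative("vM", vM)
    s = _require_state(state, ("I_alpha", "D_alpha", "M1", "Th1"))
    return _tnf_terms(s["I_alpha"], s["D_alpha"], s["M1"], s["Th1"],
                      base.v_alpha_M, base.v_alpha_1, base.delta_alpha,
                      drugs.sigma_D_alpha, drugs.delta_D_alpha, vM)


def rhs_il12(state: ImmuneState, base: BaseParameters, drugs: DrugParameters,
             vM: float = 0.0) -> tuple[float, float]:
    """Time derivatives (dI_12/dt, dD_12/dt) of IL-12 and its antibody.

    IL-12 is produced by M1 macrophages under saturating suppression by
    IL-10 (half-maximal at I_10 = ζ_10).
    """
    _check_nonnegative("vM", vM)
    if base.zeta_10 <= 0.0:
        raise ValueError("zeta_10 must be > 0")
    s = _require_state(state, ("I_12", "D_12", "M1", "I_10"))
    return _il12_terms(s["I_12"], s["D_12"], s["M1"], s["I_10"],
                       base.v_12M, base.zeta_10, base.delta_12,
                       drugs.sigma_D_12, drugs.delta_D_12, vM)


def rhs_il10(state: ImmuneState, base: BaseParameters, drugs: DrugParameters,
             vM: float = 0.0) -> tuple[float, float]:
    """Time derivatives (dI_10/dt, dD_10/dt) of IL-10 and the recombinant drug.

    IL-10 is produced by M2 macrophages and by Treg cells; IFN-γ aids and
    IL-2 interferes with the Treg-mediated production through the factor
    [1 + n_2r·I_γ/(ζ_2 + I_2)].  The injected recombinant compartment
    feeds I_10 at rate v_D10 and clears at δ_D10 (total elimination,
    including conversion).
    """
    _check_nonnegative("vM", vM)
    if base.zeta_2 <= 0.0:
        raise ValueError("zeta_2 must be > 0")
    s = _require_state(state, ("I_10", "D_10", "M2", "Treg", "I_gamma", "I_2"))
    return _il10_terms(s["I_10"], s["D_10"], s["M2"], s["Treg"],
                       s["I_gamma"], s["I_2"],
                       base.v_10M, base.v_10r, base.n_2r, base.zeta_2,
                       base.delta_10, drugs.v_D10, drugs.delta_D_10, vM)


# ---------------------------------------------------------------------------
# compiled model
# ---------------------------------------------------------------------------

class ImmuneModel:
    """A model configuration compiled for integration.

    Exposes the full right-hand side :meth:`rhs_full` over the fixed
    state order ``config.species + (D_alpha, D_12, D_10)``.
    """

    def __init__(self, config: Union[ModelConfig, dict]):
        if not isinstance(config, ModelConfig):
            config = load_model_config(config)
        self.config = config
        self.species: tuple[str, ...] = tuple(config.species)
        self.compartments: tuple[str, ...] = self.species + DRUG_COMPARTMENTS
        self.index = {n: i for i, n in enumerate(self.compartments)}
        self.n_species = len(self.species)
        self.n = len(self.compartments)
        self.params = config.param_values()
        self.drug_params = config.drug_param_values()
        self._compile_terms()
        self._ia = self.index["I_alpha"]
        self._i12 = self.index["I_12"]
        self._i10 = self.index["I_10"]
        self._da = self.index["D_alpha"]
        self._d12 = self.index["D_12"]
        self._d10 = self.index["D_10"]
        self._im1 = self.index["M1"]
        self._im2 = self.index["M2"]
        self._it1 = self.index["Th1"]
        self._itr = self.index["Treg"]
        self._ig = self.index["I_gamma"]
        self._i2 = self.index["I_2"]
        self._builtin_active = tuple(
            s for s in BUILTIN_SPECIES if s not in config.replace_builtin
        )

    def _compile_terms(self) -> None:
        p, ix = self.params, self.index
        groups: dict[str, list] = {"constant": [], "linear": [], "hill": [], "decay": []}
        for t in self.config.terms:
            groups[t.kind].append(t)
        c = groups["constant"]
        self._c_t = np.array([ix[t.target] for t in c], dtype=int)
        self._c_r = np.array([p[t.rate] for t in c])
        l = groups["linear"]
        self._l_t = np.array([ix[t.target] for t in l], dtype=int)
        self._l_s = np.array([ix[t.source] for t in l], dtype=int)
        self._l_r = np.array([p[t.rate] for t in l])
        h = groups["hill"]
        self._h_t = np.array([ix[t.target] for t in h], dtype=int)
        self._h_s = np.array([ix[t.source] for t in h], dtype=int)
        self._h_m = np.array([ix[t.modulator] for t in h], dtype=int)
        self._h_r = np.array([p[t.rate] for t in h])
        self._h_z = np.array([p[t.zeta] for t in h])
        d = groups["decay"]
        self._d_t = np.array([ix[t.target] for t in d], dtype=int)
        self._d_r = np.array([p[t.rate] for t in d])

    # -- parameter views ---------------------------------------------------
    @property
    def base_parameters(self) -> BaseParameters:
        return BaseParameters.from_mapping(self.params)

    @property
    def drug_parameters(self) -> DrugParameters:
        return DrugParameters.from_mapping(self.drug_params)

    def with_overrides(self, factors: Mapping[str, float]) -> "ImmuneModel":
        """New model with parameters scaled by multiplicative factors."""
        return ImmuneModel(apply_overrides(self.config, dict(factors)))

    def config_hash(self) -> str:
        """SHA-256 of the canonicalized configuration (reproducibility stamp)."""
        import hashlib
        import json

        doc = json.dumps(self.config.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()

    # -- state construction ------------------------------------------------
    def state(self, mapping_or_values, default: float = 0.0) -> ImmuneState:
        if isinstance(mapping_or_values, ImmuneState):
            return mapping_or_values
        if isinstance(mapping_or_values, Mapping):
            return ImmuneState.from_dict(self.compartments, mapping_or_values, default)
        return ImmuneState(self.compartments, mapping_or_values)

    def uniform_state(self, level: float = 1.0, drug_level: float = 0.0) -> ImmuneState:
        v = np.full(self.n, float(level))
        v[self.n_species:] = drug_level
        return ImmuneState(self.compartments, v)

    # -- right-hand sides --------------------------------------------------
    def rhs_registry(self, y: np.ndarray) -> np.ndarray:
        """Derivative contributions of the configured registry terms."""
        d = np.zeros(self.n)
        if self._c_t.size:
            np.add.at(d, self._c_t, self._c_r)
        if self._l_t.size:
            np.add.at(d, self._l_t, self._l_r * y[self._l_s])
        if self._h_t.size:
            np.add.at(d, self._h_t, self._h_r * y[self._h_s] / (self._h_z + y[self._h_m]))
        if self._d_t.size:
            np.add.at(d, self._d_t, -self._d_r * y[self._d_t])
        return d

    def rhs_full(self, t: float, y: np.ndarray,
                 mode: TherapyMode = TherapyMode.NONE,
                 infusion=None) -> np.ndarray:
        """Full derivative vector at time ``t`` (weeks).

        ``infusion`` is a callable ``t -> rate`` (or None for no dosing);
        its output is routed to the drug compartment selected by ``mode``,
        all other drug compartments evolve with v_M = 0.
        """
        p, q = self.params, self.drug_params
        vM = 0.0 if infusion is None else float(infusion(t))
        d = self.rhs_registry(y)
        vm_a = vM if mode is TherapyMode.ANTI_TNF else 0.0
        vm_12 = vM if mode is TherapyMode.ANTI_IL12 else 0.0
        vm_10 = vM if mode is TherapyMode.IL10 else 0.0
        if "I_alpha" in self._builtin_active:
            dI, dD = _tnf_terms(
                y[self._ia], y[self._da], y[self._im1], y[self._it1],
                p["v_alpha_M"], p["v_alpha_1"], p["delta_alpha"],
                q["sigma_D_alpha"], q["delta_D_alpha"], vm_a)
            d[self._ia] += dI
            d[self._da] += dD
        else:
            d[self._da] += vm_a - q["delta_D_alpha"] * y[self._da]
        if "I_12" in self._builtin_active:
            dI, dD = _il12_terms(
                y[self._i12], y[self._d12], y[self._im1], y[self._i10],
                p["v_12M"], p["zeta_10"], p["delta_12"],
                q["sigma_D_12"], q["delta_D_12"], vm_12)
            d[self._i12] += dI
            d[self._d12] += dD
        else:
            d[self._d12] += vm_12 - q["delta_D_12"] * y[self._d12]
        if "I_10" in self._builtin_active:
            dI, dD = _il10_terms(
                y[self._i10], y[self._d10], y[self._im2], y[self._itr],
                y[self._ig], y[self._i2],
                p["v_10M"], p["v_10r"], p["n_2r"], p["zeta_2"], p["delta_10"],
                q["v_D10"], q["delta_D_10"], vm_10)
            d[self._i10] += dI
            d[self._d10] += dD
        else:
            d[self._d10] += vm_10 - q["delta_D_10"] * y[self._d10]
        return d

    def rhs_state(self, state: ImmuneState, mode: TherapyMode = TherapyMode.NONE,
                  vM: float = 0.0, t: float = 0.0) -> np.ndarray:
        """Convenience wrapper of :meth:`rhs_full` on an :class:`ImmuneState`."""
        y = np.array([state[n] for n in self.compartments])
        return self.rhs_full(t, y, mode, (lambda _t: vM) if vM else None)
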