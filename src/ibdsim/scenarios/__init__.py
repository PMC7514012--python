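"""Patient-case scenarios: healthy baseline, four shipped disease cases, a
random synthetic-case generator, and nominal drug parameters.

The four cases follow the classic taxonomy of Th1/Th2 *pathway activity*
relative to healthy: case 1 Th1-high/Th2-low, case 2 Th1-low/Th2-high,
case 3 both high, case 4 both low.  Activity is read at steady state
through two observables:

* **Th1 axis — IFN-γ level.**  Th1 *cell* concentrations are elevated in
  every disease case (together with TNF-α, the hallmark pattern), so the
  cell count cannot carry the classification; the pathway's effector
  cytokine does.
* **Th2 axis — Th2 cell level** (IL-4 tracks it in the shipped sets).

Each shipped case overrides exactly ten parameters of the healthy
baseline, multiplicatively, all among the production rates of Th1, Th2
and their polarizing cytokines; the choice is documented in the scenario
files.  Because the published base network's numeric values are not
available here, all shipped values are *nominal* — tuned to reproduce
the qualitative sign patterns above, with a provenance slot for
transcribed values.

The synthetic generator emulates patient heterogeneity (every patient
has a unique immune system): it jitters a case's override factors with
multiplicative log-normal noise (median 1) and rejection-samples until
the steady state shows the case's sign pattern.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import yaml

from ..config import CaseSpec, DoseSpec, ModelConfig, load_model_config
from ..dosing import DoseSchedule, infliximab_schedule
from ..model import DrugParameters, ImmuneModel, ImmuneState
from ..simulate import SteadyStateError, steady_state

__all__ = [
    "PatientCase",
    "CASE_LABELS",
    "TAXONOMY",
    "SyntheticCaseError",
    "load_case",
    "case_model",
    "healthy_model",
    "healthy_config",
    "check_taxonomy",
    "generate_synthetic_case",
    "drug_nominals",
    "default_schedule",
]

CASE_LABELS = ("healthy", "case1", "case2", "case3", "case4")

#: (th1_activity_up, th2_activity_up) per case label
TAXONOMY = {
    "case1": (True, False),
    "case2": (False, True),
    "case3": (True, True),
    "case4": (False, False),
}


class SyntheticCaseError(RuntimeError):
    """Rejection budget exhausted before a draw matched the taxonomy."""


@dataclass(frozen=True)
class PatientCase:
    """A patient parameterization: multiplicative overrides of healthy."""

    label: str
    overrides: dict[str, float] = field(default_factory=dict)
    provenance: str = "nominal"
    note: str = ""

    def __post_init__(self):
        for k, f in self.overrides.items():
            if not f > 0.0:
                raise ValueError(f"override factor for {k!r} must be > 0")


def _read_scenario(name: str) -> dict:
    text = resources.files("ibdsim.scenarios").joinpath(f"{name}.yaml").read_text()
    return yaml.safe_load(text)


@functools.lru_cache(maxsize=None)
def healthy_config() -> ModelConfig:
    """The validated healthy-baseline configuration (cached)."""
    return load_model_config(_read_scenario("healthy"))


_healthy_config = healthy_config


@functools.lru_cache(maxsize=None)
def healthy_model() -> ImmuneModel:
    """The compiled healthy-baseline model (cached)."""
    return ImmuneModel(_healthy_config())


@functools.lru_cache(maxsize=None)
def load_case(label: str) -> PatientCase:
    """Load a shipped scenario by label (``healthy`` or ``case1..case4``)."""
    if label not in CASE_LABELS:
        raise KeyError(f"unknown case label {label!r}; expected one of {CASE_LABELS}")
    if label == "healthy":
        return PatientCase(label="healthy", overrides={}, provenance="nominal",
                           note="healthy baseline; all factors 1")
    spec = CaseSpec.model_validate(_read_scenario(label))
    return PatientCase(label=spec.name, overrides=dict(spec.overrides),
                       provenance=spec.provenance, note=spec.note.strip())


def case_model(case: PatientCase) -> ImmuneModel:
    """Compiled model for a case: healthy baseline with overrides applied."""
    if not case.overrides:
        return healthy_model()
    return healthy_model().with_overrides(case.overrides)


def check_taxonomy(case_ss: ImmuneState, healthy_ss: ImmuneState,
                   pattern: tuple[bool, bool]) -> bool:
    """True iff the steady state shows the (Th1-axis, Th2-axis) sign pattern.

    Th1 activity is read through IFN-γ, Th2 activity through the Th2
    cell level (strict inequalities against the healthy steady state).
    """
    th1_up, th2_up = pattern
    ok1 = (case_ss["I_gamma"] > healthy_ss["I_gamma"]) == th1_up
    ok2 = (case_ss["Th2"] > healthy_ss["Th2"]) == th2_up
    return bool(ok1 and ok2)


def generate_synthetic_case(taxonomy: str, seed: int, spread: float = 0.2,
                            *, max_draws: int = 1000,
                            healthy_ss: Optional[ImmuneState] = None,
                            ) -> PatientCase:
    """Draw a random patient of the given taxonomy (``case1``..``case4``).

    Each draw multiplies the case's nominal override factors by
    independent log-normal noise (median 1, log-scale s.d. ``spread``)
    and is accepted iff the resulting steady state satisfies the
    taxonomy's Th1/Th2 sign pattern.  Deterministic given
    (taxonomy, seed, spread).

    Raises
    ------
    SyntheticCaseError
        If ``max_draws`` draws are rejected; the message reports the
        acceptance rate observed so far.
    """
    if taxonomy not in TAXONOMY:
        raise KeyError(f"unknown taxonomy {taxonomy!r}; expected one of {tuple(TAXONOMY)}")
    if not spread > 0.0:
        raise ValueError("spread must be > 0")
    nominal = load_case(taxonomy).overrides
    pattern = TAXONOMY[taxonomy]
    base = healthy_model()
    if healthy_ss is None:
        healthy_ss = steady_state(base)
    rng = np.random.default_rng(seed)
    names = sorted(nominal)
    for draw in range(1, max_draws + 1):
        noise = rng.lognormal(mean=0.0, sigma=spread, size=len(names))
        factors = {n: nominal[n] * z for n, z in zip(names, noise)}
        model = base.with_overrides(factors)
        try:
            ss = steady_state(model, seed=healthy_ss)
        except SteadyStateError:
            continue
        if check_taxonomy(ss, healthy_ss, pattern):
            return PatientCase(
                label=f"synthetic:{seed}",
                overrides=factors,
                provenance="nominal",
                note=f"synthetic {taxonomy} draw (spread={spread}, draws={draw})",
            )
    raise SyntheticCaseError(
        f"no accepted draw for {taxonomy} in {max_draws} draws "
        f"(acceptance rate 0/{max_draws}); widen spread or check the baseline"
    )


def drug_nominals() -> tuple[DrugParameters, DoseSpec]:
    """Nominal drug parameters and per-infusion dose magnitude.

    Every value is nominal: binding/clearance rates and the infusion
    concentration scale are not pinned by published values.  The set is
    calibrated so that under the standard schedule the targeted
    cytokine's trajectory dips below its patient steady state.
    """
    drugs = DrugParameters.from_mapping(_healthy_config().drug_param_values())
    doc = _read_scenario("drugs")
    dose = DoseSpec.model_validate(doc["dose"])
    return drugs, dose


def default_schedule(horizon: float = 50.0) -> DoseSchedule:
    """Infliximab-style schedule with the nominal dose magnitude."""
    _, dose = drug_nominals()
    return infliximab_schedule(horizon, rate=dose.rate, duration=dose.duration)
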