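import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ibdsim import (
    ImmuneModel,
    case_model,
    healthy_model,
    load_case,
    steady_state,
)
from ibdsim.scenarios import healthy_config

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

CASE_LABELS = ("case1", "case2", "case3", "case4")


@pytest.fixture(scope="session")
def healthy():
    return healthy_model()


@pytest.fixture(scope="session")
def healthy_ss(healthy):
    return steady_state(healthy)


@pytest.fixture(scope="session")
def case_models():
    return {label: case_model(load_case(label)) for label in CASE_LABELS}


@pytest.fixture(scope="session")
def case_sss(case_models, healthy_ss):
    return {label: steady_state(m, seed=healthy_ss)
            for label, m in case_models.items()}


def modified_healthy(param_updates=None, drug_updates=None) -> ImmuneModel:
    """Healthy model with selected rate constants replaced (not scaled):
    lets tests switch terms off entirely (factor 0 is not a valid override)."""
    from ibdsim.config import ParamSpec

    cfg = healthy_config()
    params = dict(cfg.params)
    drugs = dict(cfg.drug_params)
    for name, value in (param_updates or {}).items():
        params[name] = ParamSpec(value=value, provenance="user")
    for name, value in (drug_updates or {}).items():
        drugs[name] = ParamSpec(value=value, provenance="user")
    return ImmuneModel(cfg.model_copy(update={"params": params, "drug_params": drugs}))
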