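"""Unit tests for the drug-coupled cytokine rate laws and the term registry."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ibdsim import (
    BaseParameters,
    DrugParameters,
    ImmuneModel,
    ImmuneState,
    TherapyMode,
    rhs_il10,
    rhs_il12,
    rhs_tnf_alpha,
)
from ibdsim.config import ConfigError, TermSpec, load_model_config
from ibdsim.scenarios import healthy_config

from conftest import modified_healthy

ALL_NAMES = ("M1", "M2", "Th1", "Treg", "I_alpha", "I_12", "I_10",
             "I_gamma", "I_2", "I_4", "D_alpha", "D_12", "D_10")


def base(**kw) -> BaseParameters:
    d = dict(v_alpha_M=0, v_alpha_1=0, delta_alpha=0, v_12M=0, zeta_10=1,
             delta_12=0, v_10M=0, v_10r=0, n_2r=0, zeta_2=1, delta_10=0)
    d.update(kw)
    return BaseParameters(**d)


def drugs(**kw) -> DrugParameters:
    d = dict(sigma_D_alpha=0, delta_D_alpha=0, sigma_D_12=0, delta_D_12=0,
             v_D10=0, delta_D_10=0)
    d.update(kw)
    return DrugParameters(**d)


def state(**kw) -> ImmuneState:
    return ImmuneState.from_dict(ALL_NAMES, kw, default=0.0)


class TestTnfAlphaLaw:
    def test_pure_decay(self):
        dI, _ = rhs_tnf_alpha(state(I_alpha=2), base(delta_alpha=0.5), drugs())
        assert dI == pytest.approx(-1.0)

    def test_symmetric_neutralization_loss(self):
        dI, dD = rhs_tnf_alpha(state(I_alpha=1, D_alpha=1), base(),
                               drugs(sigma_D_alpha=0.3))
        assert dI == pytest.approx(-0.3)
        assert dD == pytest.approx(-0.3)

    def test_production_minus_decay(self):
        dI, _ = rhs_tnf_alpha(
            state(M1=1, Th1=2, I_alpha=4),
            base(v_alpha_M=2, v_alpha_1=3, delta_alpha=1), drugs())
        assert dI == pytest.approx(4.0)  # 2*1 + 3*2 - 1*4

    @given(I=st.floats(0, 10), D=st.floats(0, 10), sigma=st.floats(0, 5))
    def test_binding_term_symmetric(self, I, D, sigma):
        """The mass-action binding term is lost equally from cytokine and
        antibody, so with production/decay off dI/dt == dD/dt."""
        dI, dD = rhs_tnf_alpha(state(I_alpha=I, D_alpha=D), base(),
                               drugs(sigma_D_alpha=sigma))
        assert dI == pytest.approx(dD, abs=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            ImmuneState.from_dict(ALL_NAMES, {"I_alpha": -1.0})


class TestIl12Law:
    def test_half_saturation_identity(self):
        p = base(v_12M=4, zeta_10=2)
        dI, _ = rhs_il12(state(M1=1, I_10=2), p, drugs())
        assert dI == pytest.approx(4 * 1 / 2)

    def test_no_suppression_limit(self):
        dI, _ = rhs_il12(state(M1=3), base(v_12M=4), drugs())
        assert dI == pytest.approx(12.0)

    def test_hand_evaluation(self):
        dI, _ = rhs_il12(state(M1=1, I_10=3, I_12=1),
                         base(v_12M=4, zeta_10=1, delta_12=1), drugs())
        assert dI == pytest.approx(0.0)  # 4/(1+3) - 1

    @given(st.tuples(st.floats(0, 50), st.floats(0, 50)))
    def test_monotone_suppression_in_il10(self, pair):
        """dI_12/dt is non-increasing in IL-10, all else fixed."""
        lo, hi = sorted(pair)
        p = base(v_12M=4, zeta_10=1, delta_12=1)
        d_lo, _ = rhs_il12(state(M1=2, I_12=1, I_10=lo), p, drugs())
        d_hi, _ = rhs_il12(state(M1=2, I_12=1, I_10=hi), p, drugs())
        assert d_hi <= d_lo + 1e-12


class TestIl10Law:
    def test_decay_only(self):
        dI, _ = rhs_il10(state(I_10=5), base(delta_10=0.2), drugs())
        assert dI == pytest.approx(-1.0)

    def test_modulation_vanishes_without_ifn_gamma(self):
        p = base(v_10r=0.7, n_2r=5.0, zeta_2=1)
        dI, _ = rhs_il10(state(Treg=2, I_2=3), p, drugs())
        assert dI == pytest.approx(0.7 * 2)

    def test_drug_source_and_clearance(self):
        dI, dD = rhs_il10(state(D_10=2), base(),
                          drugs(v_D10=0.4, delta_D_10=0.5))
        assert dD == pytest.approx(-1.0)
        assert dI == pytest.approx(+0.8)

    def test_ifn_gamma_aids_il2_interferes(self):
        p = base(v_10r=1.0, n_2r=1.0, zeta_2=1.0)
        d_base, _ = rhs_il10(state(Treg=1), p, drugs())
        d_ifng, _ = rhs_il10(state(Treg=1, I_gamma=2), p, drugs())
        d_both, _ = rhs_il10(state(Treg=1, I_gamma=2, I_2=3), p, drugs())
        assert d_ifng > d_base          # IFN-gamma aids
        assert d_base < d_both < d_ifng  # IL-2 interferes with the aid


class TestZetaValidation:
    def test_zero_zeta_is_configuration_error(self):
        with pytest.raises(ValueError):
            base(zeta_10=0.0)
        with pytest.raises(ValueError):
            base(zeta_2=0.0)

    def test_config_rejects_zero_half_saturation(self):
        doc = healthy_config().model_dump()
        doc["params"]["zeta_10"] = {"value": 0.0}
        with pytest.raises(ConfigError):
            load_model_config(doc)


class TestTermRegistry:
    def test_toy_constant_decay_species(self):
        """Species appended via configuration obey dx/dt = a - b*x."""
        cfg = healthy_config()
        from ibdsim.config import ParamSpec
        params = dict(cfg.params)
        params["a_X"] = ParamSpec(value=0.3)
        params["b_X"] = ParamSpec(value=0.1)
        params["a_Y"] = ParamSpec(value=1.0)
        params["b_Y"] = ParamSpec(value=0.5)
        terms = cfg.terms + (
            TermSpec(target="X", kind="constant", rate="a_X"),
            TermSpec(target="X", kind="decay", rate="b_X"),
            TermSpec(target="Y", kind="constant", rate="a_Y"),
            TermSpec(target="Y", kind="decay", rate="b_Y"),
        )
        model = ImmuneModel(cfg.model_copy(update={
            "species": cfg.species + ("X", "Y"),
            "params": params, "terms": terms}))
        y = np.zeros(model.n)
        y[model.index["X"]] = 2.0
        y[model.index["Y"]] = 1.0
        d = model.rhs_full(0.0, y)
        assert d[model.index["X"]] == pytest.approx(0.3 - 0.1 * 2.0)
        assert d[model.index["Y"]] == pytest.approx(1.0 - 0.5 * 1.0)

    def test_unknown_species_in_term_rejected(self):
        doc = healthy_config().model_dump()
        doc["terms"] = list(doc["terms"]) + [
            {"target": "Th1", "kind": "linear", "rate": "g_1", "source": "nope"}]
        with pytest.raises(ConfigError):
            load_model_config(doc)

    def test_builtin_species_protected_from_accidental_terms(self):
        doc = healthy_config().model_dump()
        doc["terms"] = list(doc["terms"]) + [
            {"target": "I_12", "kind": "constant", "rate": "s_1"}]
        with pytest.raises(ConfigError):
            load_model_config(doc)

    def test_zero_state_zero_sources_is_fixed_point(self):
        model = modified_healthy(param_updates={
            "s_M1": 0, "s_M2": 0, "s_1": 0, "s_2": 0, "s_17": 0, "s_r": 0})
        d = model.rhs_full(0.0, np.zeros(model.n))
        assert np.all(d == 0.0)

    def test_drug_free_limit_matches_base_network(self, healthy):
        """With all drug compartments at zero and no infusion, the full rhs
        carries no drug contribution in any cytokine equation."""
        sigma_free = modified_healthy(
            drug_updates={"sigma_D_alpha": 0, "sigma_D_12": 0, "v_D10": 0})
        y = np.linspace(0.5, 2.0, healthy.n)
        y[healthy.n_species:] = 0.0
        for mode in TherapyMode:
            d1 = healthy.rhs_full(0.0, y, mode)
            d2 = sigma_free.rhs_full(0.0, y, mode)
            np.testing.assert_allclose(d1, d2, atol=1e-14)


class TestStateVectorContract:
    def test_fixed_documented_order(self, healthy):
        assert healthy.compartments[-3:] == ("D_alpha", "D_12", "D_10")
        assert healthy.compartments[:len(healthy.species)] == healthy.species

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            ImmuneState(("A", "A"), [1.0, 2.0])
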