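# Healthy baseline configuration.
#
# The network couples M1/M2 macrophages, helper and regulatory T cells and
# their cytokines.  All rate constants are per week, concentrations in
# nominal g/cm^3 units.  Every value is tagged "nominal": an
# order-of-magnitude-reasonable set chosen so that (a) the healthy steady
# state is 1.0 in every compartment, (b) the state is asymptotically stable
# with a relaxation time of a few weeks, and (c) the shipped patient cases
# reproduce the qualitative Th1/Th2 activity patterns.  Values transcribed
# from the published base-network source may replace nominals here
# (provenance: transcribed) without code changes.
#
# The rate laws of I_alpha, I_12 and I_10 (with drug coupling) are built
# into the model; only the remaining species carry registry terms.

name: healthy
species: [M1, M2, Th1, Th2, Th17, Treg, I_alpha, I_12, I_10, I_gamma, I_2, I_4]

params:
  # TNF-alpha law: production by M1 and Th1, first-order decay
  v_alpha_M: {value: 1.2, provenance: nominal}
  v_alpha_1: {value: 0.8, provenance: nominal}
  delta_alpha: {value: 2.0, provenance: nominal}
  # IL-12 law: production by M1 under saturating IL-10 suppression
  v_12M: {value: 4.0, provenance: nominal}
  zeta_10: {value: 1.0, provenance: nominal}
  delta_12: {value: 2.0, provenance: nominal}
  # IL-10 law: production by M2 and Treg (IFN-gamma aids, IL-2 interferes)
  v_10M: {value: 1.5, provenance: nominal}
  v_10r: {value: 0.4, provenance: nominal}
  n_2r: {value: 0.5, provenance: nominal}
  zeta_2: {value: 1.0, provenance: nominal}
  delta_10: {value: 2.0, provenance: nominal}
  # M1 macrophages: basal influx, activation by IFN-gamma and TNF-alpha
  s_M1: {value: 0.35, provenance: nominal}
  a_M1_gamma: {value: 0.1, provenance: nominal}
  a_M1_alpha: {value: 0.05, provenance: nominal}
  delta_M1: {value: 0.5, provenance: nominal}
  # M2 macrophages: basal influx, polarization by IL-4
  s_M2: {value: 0.3, provenance: nominal}
  a_M2_4: {value: 0.2, provenance: nominal}
  delta_M2: {value: 0.5, provenance: nominal}
  # Th1: basal differentiation plus saturating IL-12 drive
  s_1: {value: 0.1, provenance: nominal}
  a_1: {value: 0.2, provenance: nominal}
  zeta_t1: {value: 1.0, provenance: nominal}
  delta_T1: {value: 0.2, provenance: nominal}
  # Th2: basal differentiation plus saturating IL-4 drive
  s_2: {value: 0.1, provenance: nominal}
  a_2: {value: 0.2, provenance: nominal}
  zeta_t2: {value: 1.0, provenance: nominal}
  delta_T2: {value: 0.2, provenance: nominal}
  # Th17: basal differentiation plus IL-12-family drive suppressed by IL-10
  s_17: {value: 0.1, provenance: nominal}
  a_17: {value: 0.2, provenance: nominal}
  zeta_t17: {value: 1.0, provenance: nominal}
  delta_T17: {value: 0.2, provenance: nominal}
  # Treg: basal influx plus IL-10-driven expansion
  s_r: {value: 0.15, provenance: nominal}
  a_r: {value: 0.05, provenance: nominal}
  delta_Tr: {value: 0.2, provenance: nominal}
  # IFN-gamma: produced by Th1
  g_1: {value: 2.0, provenance: nominal}
  delta_gamma: {value: 2.0, provenance: nominal}
  # IL-2: produced by Th1
  c_2: {value: 2.0, provenance: nominal}
  delta_2: {value: 2.0, provenance: nominal}
  # IL-4: produced by Th2, antagonized by IFN-gamma
  c_4: {value: 4.0, provenance: nominal}
  zeta_g4: {value: 1.0, provenance: nominal}
  delta_4: {value: 2.0, provenance: nominal}

terms:
  - {target: M1, kind: constant, rate: s_M1}
  - {target: M1, kind: linear, rate: a_M1_gamma, source: I_gamma}
  - {target: M1, kind: linear, rate: a_M1_alpha, source: I_alpha}
  - {target: M1, kind: decay, rate: delta_M1}

  - {target: M2, kind: constant, rate: s_M2}
  - {target: M2, kind: linear, rate: a_M2_4, source: I_4}
  - {target: M2, kind: decay, rate: delta_M2}

  # saturating (Michaelis-Menten) cytokine drives keep the network globally
  # bounded, so no parameter draw can produce runaway T-cell expansion
  - {target: Th1, kind: constant, rate: s_1}
  - {target: Th1, kind: hill, rate: a_1, source: I_12, modulator: I_12, zeta: zeta_t1}
  - {target: Th1, kind: decay, rate: delta_T1}

  - {target: Th2, kind: constant, rate: s_2}
  - {target: Th2, kind: hill, rate: a_2, source: I_4, modulator: I_4, zeta: zeta_t2}
  - {target: Th2, kind: decay, rate: delta_T2}

  - {target: Th17, kind: constant, rate: s_17}
  - {target: Th17, kind: hill, rate: a_17, source: I_12, modulator: I_10, zeta: zeta_t17}
  - {target: Th17, kind: decay, rate: delta_T17}

  - {target: Treg, kind: constant, rate: s_r}
  - {target: Treg, kind: linear, rate: a_r, source: I_10}
  - {target: Treg, kind: decay, rate: delta_Tr}

  - {target: I_gamma, kind: linear, rate: g_1, source: Th1}
  - {target: I_gamma, kind: decay, rate: delta_gamma}

  - {target: I_2, kind: linear, rate: c_2, source: Th1}
  - {target: I_2, kind: decay, rate: delta_2}

  - {target: I_4, kind: hill, rate: c_4, source: Th2, modulator: I_gamma, zeta: zeta_g4}
  - {target: I_4, kind: decay, rate: delta_4}

drug_params:
  sigma_D_alpha: {value: 0.5, provenance: nominal}
  delta_D_alpha: {value: 0.35, provenance: nominal}
  sigma_D_12: {value: 0.5, provenance: nominal}
  delta_D_12: {value: 0.35, provenance: nominal}
  v_D10: {value: 0.5, provenance: nominal}
  delta_D_10: {value: 0.7, provenance: nominal}
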