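# Case 1: Th1 activity high, Th2 activity low.
#
# Classic Th1-driven disease: the IL-12 -> Th1 -> IFN-gamma axis is
# up-regulated (a_1, s_1, v_12M, g_1) together with TNF-alpha production
# (v_alpha_1, v_alpha_M), while the Th2/IL-4 axis (a_2, s_2, c_4) and
# macrophage IL-10 output (v_10M) are down-regulated.  Exactly ten
# parameters are overridden, all multiplicative on the healthy baseline.
name: case1
base: healthy
provenance: nominal
note: >
  Th1-dominant pattern: IFN-gamma and Th1 above healthy, Th2 and IL-4
  below, anti-inflammatory output reduced.  TNF-alpha production rates
  carry their lowest values among the four cases.
overrides:
  a_1: 2.2
  s_1: 1.4
  v_12M: 1.3
  g_1: 1.2
  v_alpha_1: 1.4
  v_alpha_M: 1.2
  a_2: 0.6
  s_2: 0.7
  c_4: 0.8
  v_10M: 0.7
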