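# Case 2: Th1 activity low, Th2 activity high.
#
# The Th1 pathway's cytokine output is impaired (g_1 strongly reduced:
# IFN-gamma below healthy) even though Th1 cells themselves accumulate
# (a_1, s_1 raised - the hallmark elevation of effector T cells and
# TNF-alpha present in every case).  The Th2/IL-4 axis (a_2, s_2, c_4)
# is up-regulated; IL-10 output constants are mildly reduced.
name: case2
base: healthy
provenance: nominal
note: >
  Th2-dominant pattern with impaired IFN-gamma output: IFN-gamma below
  healthy, Th2 and IL-4 above, while Th1 cells and TNF-alpha remain
  elevated.
overrides:
  g_1: 0.35
  a_1: 1.8
  s_1: 1.6
  a_2: 1.8
  s_2: 1.5
  c_4: 1.4
  v_alpha_1: 1.7
  v_alpha_M: 1.2
  v_10M: 0.8
  v_10r: 0.8
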