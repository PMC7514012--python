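# Case 4: both Th1 and Th2 activity low.
#
# Globally hypoactive helper pathways: IFN-gamma output impaired (g_1)
# and the Th2/IL-4 axis reduced (a_2, s_2, c_4), with reduced IL-10
# output.  Th1 cells and TNF-alpha nevertheless remain above healthy
# (a_1, s_1, v_alpha_1, v_alpha_M raised); the TNF-alpha production
# constants carry their highest values among the four cases.
name: case4
base: healthy
provenance: nominal
note: >
  Hypoactive pattern: IFN-gamma, Th2 and IL-4 below healthy while Th1
  cells and TNF-alpha stay elevated.
overrides:
  g_1: 0.4
  a_1: 1.6
  s_1: 1.7
  a_2: 0.6
  s_2: 0.6
  c_4: 0.8
  v_alpha_1: 1.7
  v_alpha_M: 1.3
  v_10M: 0.7
  v_10r: 0.8
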