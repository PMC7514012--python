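# Case 3: both Th1 and Th2 activity high.
#
# Mixed activation: both the IL-12 -> Th1 -> IFN-gamma axis (a_1, s_1,
# v_12M, g_1) and the Th2/IL-4 axis (a_2, s_2, c_4) are up-regulated,
# and - uniquely among the cases - IL-10 production (v_10M, v_10r) is
# raised, so the anti-inflammatory factors IL-4 and IL-10 sit above the
# healthy level.  The IFN-gamma production coefficient is raised, the
# smallest of the Th1-axis increases in this set.
name: case3
base: healthy
provenance: nominal
note: >
  Mixed pattern: Th1, Th2, IFN-gamma, IL-4 and IL-10 all above healthy;
  the only case with elevated anti-inflammatory factors.
overrides:
  a_1: 1.8
  s_1: 1.4
  v_12M: 1.3
  g_1: 1.1
  a_2: 1.8
  s_2: 1.5
  c_4: 1.5
  v_alpha_1: 1.4
  v_10M: 1.4
  v_10r: 1.4
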