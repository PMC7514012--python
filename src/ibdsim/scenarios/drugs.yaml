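# Nominal per-infusion dose magnitude.
#
# The dosing regimen (induction at weeks 0, 2, 4, 8; maintenance every
# 8 weeks) fixes *when* drug enters, but no published concentration scale
# fixes *how much*; the shipped magnitude is nominal, calibrated so that
# under the standard schedule the targeted cytokine dips below its
# patient steady state.  rate (conc/week) x duration (weeks) = total
# dose per infusion; duration approximates a one-day intravenous
# infusion.
dose:
  rate: 105.0
  duration: 0.14285714285714285   # 1/7 week = 1 day
  provenance: nominal
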