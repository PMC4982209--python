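# UK time-trade-off (TTO) value set for the EQ-5D-3L descriptive system.
# Decrements are subtracted from 1.0 (full health). Replaceable by any
# tariff with the same structure.
constant_decrement: 0.081
level2_decrements:
  mobility: 0.069
  self_care: 0.104
  usual_activities: 0.036
  pain_discomfort: 0.123
  anxiety_depression: 0.071
level3_decrements:
  mobility: 0.314
  self_care: 0.214
  usual_activities: 0.094
  pain_discomfort: 0.386
  anxiety_depression: 0.236
n3_decrement: 0.269
unconscious_utility: -0.4
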