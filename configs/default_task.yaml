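# Shipped task configuration: the full incentive design.
# An empty config file reproduces exactly the same values; this file spells
# them out for reference and editing.
try_spec:
  low_value: 1.0
  high_value: 14.0
  p_high: 0.1
  n_keys: 12
giveup_spec:
  low_value: 1.0
  high_value: 2.0
  p_high: 0.5
  n_keys: 12
trials_per_round: 12
rounds_per_block: 15
block_schemes: [baseline, baseline, baseline]
analysis_window: 9
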