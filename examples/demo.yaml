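# Demo: small simulated competitive-propagation run, end to end.
seed: 17
outdir: demo_run
timepoints: [0, 150, 270]
simulate:
  n_clones: 200
  depth: 20000
  error_rate: 0.001
  # per-minute growth-rate means; ~27 min doubling, PhD7 fastest
  rate_means: {PhD7: 0.026, PhD12: 0.024, PhDC7C: 0.022}
  wt_fraction_0: 0.125
  r_wt: 0.024
analysis:
  denominator: cleaned
  diversity_mode: unique
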