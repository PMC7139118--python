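# Demo configuration: one small end-to-end run with planted ground truth.
seed: 1
out_dir: cneduo_demo
simulate:
  cne_length: 32
  tree: "((human:1,mouse:1):1,(gar:1,shark:1):1);"
  substitution_rate: 0.02
  n_compensatory_events: 2
  retention_fraction: 0.4
  read_depth: 5000
  cage_spacing: 180
  signal_noise: 0.1
  n_samples: 150
  zero_fraction: 0.3
discover:
  min_identity: 0.75
  seed_len: 8
state:
  states: [closed, poised, active]
correlate:
  method: pearson-log
  threshold: 1.0
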