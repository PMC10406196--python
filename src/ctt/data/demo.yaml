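seed: 11
n_subjects: 8
output_dir: ctt_demo_out
simulate:
  n_units: 60
  n_conditions: 2
  n_localizer_trials_per_condition: 8
  n_main_trials_per_condition: 8
  n_runs_localizer: 2
  n_chunks_main: 4
  noise_sd: 0.8
  activation_weights:
    cond0: [1.0, 0.0]
    cond1: [0.0, 1.0]
extraction:
  supertrial_k: 1
tracking:
  metric: pearson
  target: cond0
  baseline: cond1
inference:
  scheme: group_sign_flip
  n_perm: 1000
  alternative: greater
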