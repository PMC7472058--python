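# Full study-style sweep: 3 placements x 2 feature sets x 4 window sizes
# = 24 models, each evaluated by leave-one-subject-out cross-validation.
# Run with:  actichild sweep -c examples/sweep.yaml
out_dir: results/sweep
seed: 1

# Omit data_dir to simulate a cohort; point it at a directory of
# <subject>_hip.csv / <subject>_wrist.csv / <subject>_events.csv to use
# recorded data instead.
# data_dir: path/to/csvs

sim:
  n_subjects: 15
  session_s: 1200      # 20 min free-play session
  rate_hz: 100

window_s: [1, 5, 10, 15]
placements: [wrist, hip, hip_wrist]
feature_sets: [base, lag_lead]
n_trees: 500
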