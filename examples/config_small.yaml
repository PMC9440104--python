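# Small Study-2 pipeline configuration for quick runs.
# All fields mirror prosocial_effort.PipelineConfig; omitted fields keep
# their defaults (e.g. the full 12-model family when `models` is absent).
study_id: 2
n_participants: 10
seed: 5
n_starts: 3
k_folds: 5
include_decision_time: true
with_covariate: true
exclusion_hi: 0.85
exclusion_lo: 0.15
models:
  - linear_kTarget_betaTarget
  - linear_kShared_betaShared
  - parabolic_kTarget_betaTarget
  - hyperbolic_kTarget_betaTarget
output_dir: scratch/cli_run
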