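n_subjects: 4
n_pooled_per_subject: 8
n_independent_per_subject: 8
n_probes: 20000
chamber_gain:
  1:
    green: 0.8
    red: 0.8
chamber_cv_inflation:
  8:
    red: 1.5
subject_effect_sd: 0.01
prep_noise_sd: 0.005
bead_count_mean: 14.0
background_mean: 200.0
background_sd: 30.0
n_pooled_slides: 4
type_i_fraction: 0.15
brightness_meanlog: 8.0
brightness_sdlog: 0.5
cv_base: 0.1
mixture_weights:
- 0.45
- 0.45
- 0.1
mixture_params:
- - 0.5
  - 8.0
- - 8.0
  - 0.5
- - 2.0
  - 2.0
outlier_plan: []
seed: 0
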