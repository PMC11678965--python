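# Named simulation profiles. These are artifact defaults chosen so that the
# qualitative structure holds: slower and more variable movement with
# increasing severity, the largest between-subject spread in the severe
# group, and a strong trial-2 learning effect (multiplier well below 1)
# there as well.
groups:
  control:
    step_frequency_hz: 1.05
    step_frequency_cv: 0.02
    walk_speed_scale: 1.0
    turn_duration_s: 1.6
    transition_duration_s: 1.3
    noise_sd_g: 0.02
    between_subject_sd: 0.06
    trial2_multiplier: 0.98
    asymmetry_ratio: 0.95
  mild:
    step_frequency_hz: 1.0
    step_frequency_cv: 0.04
    walk_speed_scale: 1.15
    turn_duration_s: 1.9
    transition_duration_s: 1.5
    noise_sd_g: 0.02
    between_subject_sd: 0.10
    trial2_multiplier: 0.96
    asymmetry_ratio: 0.90
  moderate:
    step_frequency_hz: 0.95
    step_frequency_cv: 0.06
    walk_speed_scale: 1.35
    turn_duration_s: 2.3
    transition_duration_s: 1.8
    noise_sd_g: 0.02
    between_subject_sd: 0.16
    trial2_multiplier: 0.93
    asymmetry_ratio: 0.85
  severe:
    step_frequency_hz: 0.9
    step_frequency_cv: 0.09
    walk_speed_scale: 1.6
    turn_duration_s: 2.8
    transition_duration_s: 2.2
    noise_sd_g: 0.02
    between_subject_sd: 0.35
    trial2_multiplier: 0.85
    asymmetry_ratio: 0.80
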