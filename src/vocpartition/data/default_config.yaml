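# Default generator configuration for the synthetic pig-vocalization dataset.
#
# The design mirrors the study layout: 40 animals, four growth phases, up to
# six distress conditions per phase (heat stress only in growing/finishing;
# thirst absent in farrowing), one 60 s recording per animal x phase x
# condition cell, split into three 20 s samples.
#
# Trait effects are calibrated *qualitatively* to the descriptive pattern of
# the study (pain: loud, high F2; cold: long calls; heat: high pitch, short
# calls), not fitted to any data.  Skewed traits (duration, energy, pitch)
# are generated log-normally: intercepts/effects are on the log scale.

n_animals: 40
sex_split: 0.5
recordings_per_cell: 1
samples_per_recording: 3
dropout_rate: 0.0
seed: 17

availability:
  farrowing: [normal, pain, hunger, cold]
  nursery: [normal, pain, hunger, thirst, cold]
  growing: [normal, pain, hunger, thirst, heat]
  finishing: [normal, pain, hunger, thirst, heat]

traits:
  intensity:                      # dB
    intercept: 72.5
    sex: {male: 0.5}
    phase: {nursery: 0.8, growing: 1.2, finishing: 1.5}
    condition: {pain: 10.2, hunger: 0.3, thirst: 1.0, cold: 1.6, heat: 4.0}
    sigma2_animal: 3.0
    sigma2_recording: 4.0
    sigma2_resid: 24.0
  duration:                       # s, log scale
    intercept: -0.71
    sex: {}
    phase: {nursery: -0.05, growing: -0.15, finishing: -0.30}
    condition: {pain: 0.65, hunger: 0.27, thirst: 0.06, cold: 0.84, heat: -0.37}
    sigma2_animal: 0.02
    sigma2_recording: 0.04
    sigma2_resid: 0.22
    log_scale: true
  pitch:                          # Hz, log scale
    intercept: 5.14
    sex: {male: -0.04}
    phase: {nursery: 0.15, growing: 0.22, finishing: -0.05}
    condition: {pain: 0.45, hunger: 0.26, thirst: -0.10, cold: -0.12, heat: 0.57}
    sigma2_animal: 0.010
    sigma2_recording: 0.020
    sigma2_resid: 0.35
    log_scale: true
  energy:                         # Pa^2 s, log scale
    intercept: -4.6
    sex: {male: 0.05}
    phase: {nursery: 0.1, growing: 0.15, finishing: 0.2}
    condition: {pain: 0.9, hunger: 0.2, thirst: 0.05, cold: 0.3, heat: 0.4}
    sigma2_animal: 0.04
    sigma2_recording: 0.07
    sigma2_resid: 0.45
    log_scale: true
  amp_max:                        # normalized amplitude
    intercept: 0.45
    sex: {}
    phase: {nursery: 0.01, growing: 0.02, finishing: 0.02}
    condition: {pain: 0.20, hunger: 0.02, thirst: 0.01, cold: 0.04, heat: 0.08}
    sigma2_animal: 0.002
    sigma2_recording: 0.003
    sigma2_resid: 0.018
  amp_min:
    intercept: -0.45
    sex: {}
    phase: {nursery: -0.01, growing: -0.02, finishing: -0.02}
    condition: {pain: -0.20, hunger: -0.02, thirst: -0.01, cold: -0.04, heat: -0.08}
    sigma2_animal: 0.002
    sigma2_recording: 0.003
    sigma2_resid: 0.018
  f1:                             # Hz
    intercept: 700.0
    sex: {male: -10.0}
    phase: {nursery: 10.0, growing: 30.0, finishing: 50.0}
    condition: {pain: 80.0, hunger: 10.0, thirst: -5.0, cold: -15.0, heat: 40.0}
    sigma2_animal: 300.0
    sigma2_recording: 500.0
    sigma2_resid: 8000.0
  f2:                             # Hz
    intercept: 1900.0
    sex: {male: -20.0}
    phase: {nursery: -80.0, growing: 60.0, finishing: 80.0}
    condition: {pain: 374.0, hunger: -52.0, thirst: 26.0, cold: -133.0, heat: 88.0}
    sigma2_animal: 3000.0
    sigma2_recording: 5000.0
    sigma2_resid: 55000.0
  f3:                             # Hz
    intercept: 2900.0
    sex: {male: -25.0}
    phase: {nursery: 20.0, growing: 50.0, finishing: 70.0}
    condition: {pain: 90.0, hunger: -20.0, thirst: 10.0, cold: -40.0, heat: 30.0}
    sigma2_animal: 4000.0
    sigma2_recording: 7000.0
    sigma2_resid: 60000.0
  f4:                             # Hz
    intercept: 3900.0
    sex: {male: -30.0}
    phase: {nursery: 20.0, growing: 60.0, finishing: 80.0}
    condition: {pain: 60.0, hunger: -10.0, thirst: 10.0, cold: -30.0, heat: 20.0}
    sigma2_animal: 5000.0
    sigma2_recording: 8000.0
    sigma2_resid: 80000.0

# Logistic model for pitch missingness (MNAR in the design factors):
# P(missing) = logistic(intercept + phase coef + condition coef).
# Calibrated so missingness is near zero in farrowing, rises sharply by
# finishing, and is highest under heat stress and hunger, lowest under
# thirst and cold.
missingness:
  intercept: -4.5
  phase: {nursery: 1.0, growing: 2.0, finishing: 3.3}
  condition: {pain: 0.55, hunger: 1.0, thirst: -1.1, cold: -1.2, heat: 1.4}
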