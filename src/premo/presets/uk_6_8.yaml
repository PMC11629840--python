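# UK-like population cohort, ages 6-8. Only inter-ocular mean SER/AL are
# recorded (eye_policy: mean). The onset intercept is calibrated so the
# expected incidence of myopia by age 15+ is ~58%; baseline biometry
# parameters are stated assumptions, not estimates of the real cohort.
n: 57
band: age_6_8
parental_probs: [0.40, 0.40, 0.20]
ser_mean: 1.10
ser_sd: 0.80
al_mean: 22.90
al_sd: 0.65
ser_al_corr: -0.45
onset_intercept: -3.54
onset_slope: 1.2
outcome_ser_noise_sd: 0.50
age_mean: 7.1
age_sd: 0.35
eye_policy: mean
p_outcome_ser_missing: 0.0
seed: 20060101
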