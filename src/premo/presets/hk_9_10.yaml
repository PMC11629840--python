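# Hong-Kong-like clinic cohort, ages 9-10 (scored with the 0-6 table).
# The onset intercept is calibrated so the expected incidence of myopia by
# age 15+ is ~76% (57 of 75 in the published cohort). Baseline biometry
# parameters are stated assumptions, not estimates of the real cohort.
n: 75
band: age_9_10
parental_probs: [0.25, 0.45, 0.30]
ser_mean: 0.70
ser_sd: 0.60
al_mean: 23.40
al_sd: 0.60
ser_al_corr: -0.45
onset_intercept: -0.9305
onset_slope: 0.9
outcome_ser_noise_sd: 0.50
age_mean: 9.7
age_sd: 0.50
eye_policy: least_hyperopic
p_outcome_ser_missing: 0.90
seed: 20100102
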