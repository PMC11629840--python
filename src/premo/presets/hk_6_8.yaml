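# Hong-Kong-like clinic cohort, ages 6-8. Per-eye measurements are
# recorded and the least hyperopic eye is scored. The onset intercept is
# calibrated so the expected incidence of myopia by age 15+ is ~94%; the
# flatter onset slope reflects the weaker score-outcome separation seen in
# high-incidence settings. Most myopes leave the clinic after onset, so
# their follow-up SER is missing (carried-forward label). Baseline biometry
# parameters are stated assumptions, not estimates of the real cohort.
n: 234
band: age_6_8
parental_probs: [0.25, 0.45, 0.30]
ser_mean: 0.90
ser_sd: 0.70
al_mean: 23.10
al_sd: 0.65
ser_al_corr: -0.45
onset_intercept: 1.12
onset_slope: 0.45
outcome_ser_noise_sd: 0.50
age_mean: 7.1
age_sd: 0.76
eye_policy: least_hyperopic
p_outcome_ser_missing: 0.95
seed: 20100101
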