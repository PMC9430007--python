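# Paper-like preset: study conditions for a 150-study reproduction portfolio
# (118 comparative + 32 descriptive).  True log effects are centred at the
# null with between-study sd tau 0.35 (effect sizes mostly between 1/2 and 2);
# arm event counts 50-500 give sampling SEs around 0.06-0.2 on the log scale;
# half of the sampling variance is shared between original and reproduction
# (same source patients).  The implementation-discrepancy mixture combines
# frequent small deviations (sd 0.15) with rare large ones (sd 0.55,
# probability 0.07).  Cohort-size ratios are log-normal (sd 0.5); the
# data-version shift probability (0.05) is an assumption — no quantitative
# prevalence for such events is established (see docs/methods.md).
n_comparative: 118
n_descriptive: 32
mu_theta: 0.0
tau: 0.35
event_count_range: [50, 500]
shared_error_fraction: 0.5
discrepancy_mix:
  pi_big: 0.07
  omega_small: 0.15
  omega_big: 0.55
size_ratio_logsd: 0.5
dataversion_shift_prob: 0.05
rate_shift_band: [13.0, 16.0]
covariate_shift:
  sd_small: 2.2
  prob_large: 0.17
  magnitude_large: 18.0
n_covariates: 8
mean_followup_years: 1.5
p_report_prob: 0.7
assume_prob_comparative: 0.65
assume_prob_descriptive: 0.6
seed: 0
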