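# Two-group survival cohort: exponential baseline hazard, configured
# hazard ratio for low vs high expression, uniform censoring window.
fixture = survival_cohort
seed = 1910
n_per_arm = 200
baseline_hazard = 0.01
hazard_ratio = 3.0
censor_max = 120.0
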