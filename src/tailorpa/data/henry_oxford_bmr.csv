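# Henry (2005) Oxford basal-metabolic-rate equations, weight-only form.
# BMR[MJ/d] = slope_mj_per_kg * weight[kg] + intercept_mj for the matching
# sex and age band; age_max is exclusive, blank means open-ended.
# Converted to kcal/d at load time (239.005 kcal/MJ).
sex,age_min,age_max,slope_mj_per_kg,intercept_mj
male,18,30,0.0669,2.28
male,30,60,0.0592,2.48
male,60,,0.0563,2.15
female,18,30,0.0546,2.33
female,30,60,0.0407,2.90
female,60,,0.0424,2.38
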