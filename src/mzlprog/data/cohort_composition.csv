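category,count,denominator,printed_pct,count_printed
male,83,146,56.85,1
age_ge_60,48,146,32.88,1
gastric_involvement,41,146,28.08,1
malt,119,146,81.51,1
smzl,19,146,13.01,1
nmzl,7,146,4.79,1
transformation,21,146,14.38,1
chemotherapy,127,146,86.99,1
chop,102,127,80.32,1
br,16,127,12.60,1
cr_pr,109,146,74.66,1
radiotherapy,22,146,15.07,0
surgery,44,146,30.14,0
rituximab,118,146,80.82,0
b_symptoms,36,146,24.66,0
hypertension,26,146,17.81,0
diabetes,12,146,8.22,0
hbv_infection,30,146,20.55,0
hp_infection,27,146,18.49,0
ecog_ge_2,38,146,26.02,0
stage_3_4,83,146,56.84,0
mzl_ipi_gt_2,50,146,34.25,0
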