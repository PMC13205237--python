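"""Maximally selected cut-point, log-rank test and stratified Cox model.

Plants a protective hazard step at CD21 = 50% (hazard ratio exp(-0.9) above)
in a mature-follow-up cohort, recovers the threshold with the exhaustive
standardized log-rank scan, and fits a treatment-stratified Cox model on the
dichotomised marker.
"""

from mzlprog import CohortSpec, cutpoint_search, fit_cox, generate_cohort, logrank_test

cohort, _ = generate_cohort(CohortSpec(
    n_patients=400, seed=12, baseline_hazard=0.007, censor_rate=0.006,
    admin_horizon=150.0, threshold_effects_os={"CD21": (50.0, -0.9)},
))
print(f"OS events: {int(cohort['os_event'].sum())}/400")

cut = cutpoint_search(cohort["CD21"], cohort["os_months"], cohort["os_event"], minprop=0.1)
print(f"selected cut-point: CD21 = {cut.cutoff:.2f}% (truth 50.00%), "
      f"standardized log-rank = {cut.standardized_statistic:.2f}, "
      f"high group adverse: {cut.direction_high_is_adverse}")

high = (cohort["CD21"] > cut.cutoff).astype(int)
chi2, p = logrank_test(cohort["os_months"], cohort["os_event"], high)
print(f"log-rank between groups: chi2 = {chi2:.1f}, p = {p:.2g}")

report = fit_cox(
    cohort.assign(CD21_high=high), "os_months", "os_event",
    ["CD21_high", "age_ge_60", "b_symptoms"],
    strata=["chemo", "rituximab", "radiotherapy", "surgery"],
)
row = report.table.loc["CD21_high"]
print(f"stratified Cox: HR = {row['hazard_ratio']:.2f} "
      f"(95% CI {row['ci95_low']:.2f}-{row['ci95_high']:.2f}), "
      f"C-index = {report.c_index:.3f}")
# the HR for the high group should sit near exp(-0.9) ~ 0.41: high CD21
# (an intact follicular dendritic cell network) is protective
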