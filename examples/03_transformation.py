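"""Histologic-transformation analysis: ROC, Youden cut-off, logistic model.

The synthetic cohort plants a transformation model in which LOW CD3 drives
transformation risk (log-odds -2.8 for high CD3 dichotomised at 25.6%). The
ROC uses direction="low" because low scores indicate the positive class; the
Youden-optimal cut-off then dichotomises the marker for the multivariable
logistic fit.
"""

from mzlprog import CohortSpec, fit_transformation_model, generate_cohort, roc_curve

cohort, ledger = generate_cohort(CohortSpec(n_patients=146, seed=4))
truth = ledger["true_transform"]

roc = roc_curve(cohort["CD3"], cohort["transformed"], direction="low")
print(f"CD3 vs transformation: AUC = {roc.auc:.2f}")
print(f"Youden cut-off = {roc.youden_cutoff:.2f}% (J = {roc.youden_j:.2f}); "
      f"generator cut-off {truth['cutoff_pct']}%")

work = cohort.assign(CD3_high=(cohort["CD3"] > roc.youden_cutoff).astype(int))
report = fit_transformation_model(work, ["CD3_high", "b_symptoms", "gastric_site"])
row = report.table.loc["CD3_high"]
print(f"high CD3: OR = {row['odds_ratio']:.2f} "
      f"(95% CI {row['ci95_low']:.2f}-{row['ci95_high']:.2f}, p = {row['p_value']:.3f})")
# an OR well below 1 reproduces the planted protective effect of T-cell
# infiltration against transformation (true OR = exp(-2.8) ~ 0.06)
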