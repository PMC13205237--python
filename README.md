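# mzlprog

Quantitative immunohistochemistry (IHC) scoring and biomarker-revised
prognostic modelling for **marginal zone lymphoma (MZL)**.

MZL is an indolent B-cell non-Hodgkin lymphoma whose clinical risk score, the
MZL-IPI, leaves transformation risk and fine-grained stratification poorly
resolved. Digitised IHC slides carry additional, quantifiable information —
the fraction of cells positive for markers such as CD3 (T-cell infiltration)
or CD21 (follicular dendritic cell networks). This package implements, as a
tested Python library, the full analysis chain from stained-tile
quantification to a marker-revised clinical index, together with a synthetic
data generator so that every stage is exercisable and verifiable without
patient data.

## The quantities at the core

**Per-cell positivity score.** For segmented cell *i* with pixel area
`A_cell,i` of which `A_positive,i` carries chromogen,

```
qi = A_positive,i / A_cell,i            (positive when qi >= alpha)
```

**Per-ROI positivity rate.**

```
Pr = 100 * N_positive,r / N_total,r     (percent)
```

**Revised index.** A prognosis-bearing marker is dichotomised at a cut-off
(strict `>`; protective: high = 0 points, adverse: high = 1 point) and

```
revised MZL-IPI = MZL-IPI + IHC score.
```

The cut-off is selected by repeated random resampling: each of many splits
assigns ~2/3 of patients to training (event-stratified) and 1/3 to
validation; the training-best candidate cut-off is applied unchanged to the
validation third, where Harrell's C of the revised index is paired with that
of the raw MZL-IPI; split-level pairs are averaged into 100 bins and compared
with a Wilcoxon signed-rank test. Supporting machinery includes Beer–Lambert
colour deconvolution, translation registration, watershed segmentation, exact
Otsu thresholding of the qi distribution, maximally selected log-rank
cut-points, Kaplan–Meier/log-rank/stratified Cox analysis (via lifelines),
ROC + Youden cut-offs, multivariable logistic models, and BH multiple-testing
control. See `docs/methods.md` for models, defaults and caveats — in
particular why the binned Wilcoxon p-value measures within-cohort
reproducibility, not population-level significance.

## Worked example

```python
import numpy as np
from mzlprog import (CohortSpec, RevisionConfig, TileSpec,
                     generate_cohort, generate_tile_pair,
                     quantify_tile_pair, run_revision)

# 1. quantify a stained tile pair with known ground truth
pair = generate_tile_pair(TileSpec(n_cells=120, positive_fraction=0.40,
                                   shift=(5, -3), seed=7))
roi, cells = quantify_tile_pair(pair, roi_id="demo")
print(roi.positivity_rate_pct, roi.alpha)      # 40.0  0.5

# 2. revise the MZL-IPI on a cohort with a planted protective CD21 step
cohort, _ = generate_cohort(CohortSpec(
    n_patients=400, seed=3, baseline_hazard=0.007, censor_rate=0.006,
    admin_horizon=150.0, threshold_effects_os={"CD21": (50.0, -0.9)}))
run = run_revision(cohort, RevisionConfig(
    marker="CD21", endpoint="os", direction="protective",
    candidate_cutoffs=np.arange(30.0, 71.0, 5.0),
    n_splits=1000, n_bins=100, seed=0))
print(run.selected_cutoff, round(run.mean_delta, 4), run.p_value)
# 50.0  0.0325  3.9e-18
```

The tile is quantified back to exactly the planted 40% positive fraction
after recovering the (5, −3) mis-registration, and the revision framework
selects the planted 50% threshold: adding the CD21 point raises the mean
validation C-index by 0.0325 over the raw index. Each example under
`examples/` runs one capability end to end and prints what the numbers mean:

```bash
python examples/01_quantify_tile.py    # registration, deconvolution, qi, Pr
python examples/04_survival_cutpoint.py
python examples/05_revise_index.py
```

A thin CLI mirrors the main operations
(`mzlprog simulate | quantify | cutpoint | revise | report | composition`).

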