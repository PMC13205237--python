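"""Histologic-transformation analysis: marker ROC, Youden cut-off, logistic fit.

Transformation (progression of indolent MZL to aggressive large-cell
lymphoma) is treated as a binary endpoint. A continuous marker's
discrimination is summarised by an ROC curve with trapezoidal AUC; the
operating threshold is the maximiser of the Youden index
``J = sensitivity + specificity - 1``. Adjusted association is estimated by
maximum-likelihood multivariable logistic regression with Wald CIs on the
odds-ratio scale; covariates redundant with the clinical index are expected
to be excluded by the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RocResult",
    "LogisticReport",
    "roc_curve",
    "youden_cutoff",
    "fit_transformation_model",
]


@dataclass
class RocResult:
    """ROC curve on the threshold grid of score midpoints plus +/-inf sentinels.

    ``direction`` records whether high (``"high"``) or low (``"low"``) scores
    indicate the positive class; thresholds are on the original score scale
    and classification is ``score >= threshold`` (direction ``"high"``) or
    ``score <= threshold`` (direction ``"low"``).
    """

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    direction: str
    youden_cutoff: float = field(default=np.nan)
    youden_j: float = field(default=np.nan)


def roc_curve(scores, labels, direction: str = "high") -> RocResult:
    """ROC analysis of a continuous score against a binary label.

    Thresholds are the midpoints between consecutive sorted unique scores,
    bracketed by -inf/+inf sentinels; AUC is the trapezoid rule over the
    resulting (1-specificity, sensitivity) polyline.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("both classes must be present")
    if direction not in ("high", "low"):
        raise ValueError("direction must be 'high' or 'low'")

    work = s if direction == "high" else -s
    uniq = np.unique(work)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = work >= t
        sens[i] = (pred & (y == 1)).sum() / n_pos
        spec[i] = (~pred & (y == 0)).sum() / n_neg
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))  # ROC path: fpr ascending, sens within
    auc = float(np.trapezoid(sens[order], fpr[order]))
    out_thresholds = thresholds if direction == "high" else -thresholds
    res = RocResult(
        thresholds=out_thresholds,
        sensitivities=sens,
        specificities=spec,
        auc=auc,
        direction=direction,
    )
    cut, j = youden_cutoff(res)
    res.youden_cutoff = cut
    res.youden_j = j
    return res


def youden_cutoff(roc: RocResult) -> tuple[float, float]:
    """Maximise ``J = sensitivity + specificity - 1`` over the ROC thresholds.

    Ties are broken toward the threshold with the larger sensitivity.
    """
    j = roc.sensitivities + roc.specificities - 1.0
    best = np.max(j)
    tied = np.flatnonzero(j >= best - 1e-12)
    winner = tied[np.argmax(roc.sensitivities[tied])]
    return float(roc.thresholds[winner]), float(j[winner])


@dataclass
class LogisticReport:
    """Per-covariate odds ratios with Wald 95% CIs from a multivariable fit."""

    table: pd.DataFrame  # index: covariate; columns: odds_ratio, ci95_low, ci95_high, p_value
    n: int
    converged: bool
    separation_flagged: bool = False


def fit_transformation_model(
    cohort: pd.DataFrame,
    covariates: list[str],
    outcome: str = "transformed",
) -> LogisticReport:
    """Multivariable logistic regression of a binary outcome on covariates.

    The marker of interest is expected to be dichotomised upstream (at the
    transformation-specific cut-off) and passed as one of ``covariates``.
    Perfect separation is flagged and no Wald CIs are reported for it.
    """
    y = pd.to_numeric(cohort[outcome], errors="coerce")
    X = cohort[covariates].apply(pd.to_numeric, errors="coerce")
    keep = y.notna() & X.notna().all(axis=1)
    y, X = y[keep].astype(int), X[keep].astype(float)
    if y.nunique() < 2:
        raise ValueError("outcome takes a single value; logistic model is undefined")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("covariate matrix is rank-deficient")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", False))
        except Exception:
            separation = True
            fit = sm.Logit(y, design).fit(method="bfgs", disp=0, maxiter=500)
            converged = False
    if not separation and np.abs(fit.params.to_numpy()).max() > 15:
        # Wald inference is meaningless under (quasi-)separation
        separation = True
    params = fit.params.drop("const")
    if separation:
        table = pd.DataFrame(
            {
                "odds_ratio": np.exp(params),
                "ci95_low": np.nan,
                "ci95_high": np.nan,
                "p_value": np.nan,
            }
        )
    else:
        ci = fit.conf_int().drop(index="const")
        table = pd.DataFrame(
            {
                "odds_ratio": np.exp(params),
                "ci95_low": np.exp(ci[0]),
                "ci95_high": np.exp(ci[1]),
                "p_value": fit.pvalues.drop("const"),
            }
        )
    return LogisticReport(table=table, n=int(y.size), converged=converged,
                          separation_flagged=separation)
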