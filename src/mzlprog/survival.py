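"""Survival layer: Kaplan-Meier, log-rank, maximally selected cut-points,
stratified Cox regression, and Harrell's concordance index.

Kaplan-Meier estimation, the two-group log-rank test and Cox partial
likelihood (Efron tie handling, treatment variables as strata with their own
baseline hazards) are delegated to lifelines. Two pieces are authored here
because their exact conventions carry the downstream analyses:

* :func:`cutpoint_search` — an exhaustive, vectorised scan of every observed
  marker value as a dichotomising threshold, maximising the standardized
  log-rank statistic under a minimum-group-proportion constraint (the
  ``surv_cutpoint`` convention).
* :func:`concordance_index` — Harrell's C over usable pairs: the pair (i, j)
  is comparable when the shorter observed time belongs to a subject with an
  event; concordant pairs score 1, risk ties 0.5, and pairs with tied event
  times are skipped. Higher risk must predict shorter survival.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "KmCurve",
    "CutpointResult",
    "CoxReport",
    "km_estimate",
    "logrank_test",
    "cutpoint_search",
    "fit_cox",
    "concordance_index",
]


@dataclass
class KmCurve:
    """Product-limit survival curve as right-continuous step data."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


@dataclass
class CutpointResult:
    cutoff: float
    standardized_statistic: float
    n_low: int
    n_high: int
    minprop: float
    n_candidates: int
    direction_high_is_adverse: bool


@dataclass
class CoxReport:
    table: pd.DataFrame  # index covariate; hazard_ratio, ci95_low, ci95_high, p_value
    strata: list[str]
    c_index: float
    n: int
    events: int
    converged: bool


def _check_time_event(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("time and event must be 1-D arrays of equal length")
    if (t < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event indicators must be 0/1")
    return t, e


def km_estimate(time, event) -> KmCurve:
    """Kaplan-Meier product-limit estimate with at-risk counts at event times."""
    t, e = _check_time_event(time, event)
    if t.size == 0:
        raise ValueError("empty sample")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        return KmCurve(times=np.array([]), survival=np.array([]), at_risk=np.array([]))
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = np.array([(t >= u).sum() for u in event_times])
    return KmCurve(times=event_times, survival=surv, at_risk=at_risk)


def logrank_test(time, event, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    t, e = _check_time_event(time, event)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError("log-rank test requires exactly two groups")
    m = g == labels[0]
    res = _ll_logrank(t[m], t[~m], event_observed_A=e[m], event_observed_B=e[~m])
    return float(res.test_statistic), float(res.p_value)


def _standardized_logrank_scan(
    marker: np.ndarray, time: np.ndarray, event: np.ndarray, candidates: np.ndarray
) -> np.ndarray:
    """|O - E| / sqrt(V) of the log-rank statistic for every candidate threshold
    (group = marker > threshold), vectorised over thresholds. Inadmissible or
    zero-variance splits come back as NaN."""
    order = np.argsort(time, kind="stable")
    t_s, e_s = time[order], event[order]
    n = t_s.size
    G = marker[None, :] > candidates[:, None]  # (T, n) high-group membership
    Gs = G[:, order].astype(float)

    # at-risk counts of the high group at each sorted index
    r1 = np.cumsum(Gs[:, ::-1], axis=1)[:, ::-1]
    uniq, start = np.unique(t_s, return_index=True)
    end = np.append(start[1:], n)
    n_at = (n - start).astype(float)
    n1_at = r1[:, start]

    ecum = np.concatenate([[0.0], np.cumsum(e_s)])
    d = ecum[end] - ecum[start]  # deaths at each unique time
    c1 = np.concatenate([np.zeros((candidates.size, 1)), np.cumsum(Gs * e_s, axis=1)], axis=1)
    d1 = c1[:, end] - c1[:, start]

    frac = n1_at / n_at
    o_minus_e = ((d1 - d * frac)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tie_adj = np.where(n_at > 1, (n_at - d) / (n_at - 1), 0.0)
        v = (d * frac * (1.0 - frac) * tie_adj).sum(axis=1)
        z = np.where(v > 0, np.abs(o_minus_e) / np.sqrt(v), np.nan)
    return z


def cutpoint_search(marker_values, time, event, minprop: float = 0.1) -> CutpointResult:
    """Exhaustive maximally-selected log-rank cut-point search.

    Every observed marker value is tried as a threshold (high group =
    ``marker > cutoff``); splits where either group does not hold strictly
    more than ``minprop`` of the sample are skipped; the threshold maximising the
    standardized log-rank statistic wins (ties -> smaller cutoff). The stored
    direction records whether the high group had the worse outcome (higher
    event odds by log-rank O-E sign), so downstream scoring is unambiguous.
    """
    t, e = _check_time_event(time, event)
    x = np.asarray(marker_values, dtype=float)
    if x.shape != t.shape:
        raise ValueError("marker and survival arrays must align")
    n = x.size
    uniq = np.unique(x)
    if uniq.size < 2:
        raise ValueError("need at least two distinct marker values")
    candidates = uniq[:-1]  # splitting above the max leaves an empty group
    n_high = (x[None, :] > candidates[:, None]).sum(axis=1)
    n_low = n - n_high
    admissible = (np.minimum(n_low, n_high) / n) > minprop
    if not admissible.any():
        raise ValueError(f"no admissible split at minprop={minprop}")
    z = _standardized_logrank_scan(x, t, e, candidates)
    z = np.where(admissible, z, np.nan)
    if np.all(np.isnan(z)):
        raise ValueError(f"no split with positive log-rank variance at minprop={minprop}")
    best = int(np.nanargmax(z))  # np.nanargmax returns the first (smallest cutoff) max
    cutoff = float(candidates[best])
    high = x > cutoff
    # direction: the group with the lower KM survival at the horizon is adverse
    km_high = km_estimate(t[high], e[high])
    km_low = km_estimate(t[~high], e[~high])
    horizon = float(np.max(t))
    adverse = km_high.survival_at(horizon) < km_low.survival_at(horizon)
    return CutpointResult(
        cutoff=cutoff,
        standardized_statistic=float(z[best]),
        n_low=int(n_low[best]),
        n_high=int(n_high[best]),
        minprop=minprop,
        n_candidates=int(admissible.sum()),
        direction_high_is_adverse=bool(adverse),
    )


def fit_cox(
    cohort: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
    strata: list[str] | None = None,
) -> CoxReport:
    """Multivariable Cox regression (Efron ties) with optional strata.

    Stratification variables get their own baseline hazards (used for
    treatment-modality adjustment). Harrell's C of the fitted linear
    predictor is reported; non-convergence is flagged with no CIs.
    """
    strata = list(strata or [])
    cols = [duration_col, event_col] + covariates + strata
    df = cohort[cols].dropna().copy()
    n = len(df)
    events = int(df[event_col].sum())
    if events < len(covariates):
        warnings.warn(
            f"only {events} events for {len(covariates)} covariates; estimates may be unstable",
            stacklevel=2,
        )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=duration_col, event_col=event_col,
                    strata=strata or None)
        converged = True
    except ConvergenceError:
        table = pd.DataFrame(
            {"hazard_ratio": np.nan, "ci95_low": np.nan, "ci95_high": np.nan,
             "p_value": np.nan},
            index=covariates,
        )
        return CoxReport(table=table, strata=strata, c_index=np.nan, n=n,
                         events=events, converged=False)
    summ = cph.summary
    table = pd.DataFrame(
        {
            "hazard_ratio": summ["exp(coef)"],
            "ci95_low": summ["exp(coef) lower 95%"],
            "ci95_high": summ["exp(coef) upper 95%"],
            "p_value": summ["p"],
        }
    )
    risk = cph.predict_partial_hazard(df).to_numpy()
    c = concordance_index(risk, df[duration_col].to_numpy(), df[event_col].to_numpy())
    return CoxReport(table=table, strata=strata, c_index=float(c), n=n,
                     events=events, converged=converged)


def concordance_index(risk_scores, time, event) -> float:
    """Harrell's C: fraction of usable pairs ordered correctly by risk.

    A pair is usable when the member with the shorter observed time had an
    event (pairs with exactly tied event times are skipped). Concordance
    means the shorter-lived member carries the strictly higher risk score;
    risk ties earn half credit.
    """
    t, e = _check_time_event(time, event)
    r = np.asarray(risk_scores, dtype=float).ravel()
    if r.shape != t.shape:
        raise ValueError("risk scores must align with the survival data")
    if t.size < 2:
        raise ValueError("need at least two subjects")
    earlier = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_usable = earlier.sum()
    if n_usable == 0:
        raise ValueError("no comparable pairs (no events before another subject's time)")
    conc = (earlier & (r[:, None] > r[None, :])).sum()
    ties = (earlier & (r[:, None] == r[None, :])).sum()
    return float((conc + 0.5 * ties) / n_usable)
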