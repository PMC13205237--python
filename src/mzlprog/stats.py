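"""Descriptive marker summaries, group comparisons and correlation analysis.

The comparison layer routes each variable to the conventional test:

* categorical — chi-square on the contingency table, falling back to
  Fisher's exact test for 2x2 tables with any expected count below 5;
* continuous, two groups — Shapiro-Wilk normality gate per group at 0.05:
  both normal -> independent-samples t test, otherwise Mann-Whitney U;
* continuous, three or more groups — same gate choosing one-way ANOVA vs
  Kruskal-Wallis.

Multiple testing uses Benjamini-Hochberg step-up FDR adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MarkerSummary",
    "ComparisonResult",
    "summarize_markers",
    "compare_groups",
    "correlation_matrix",
    "adjust_bh",
]


@dataclass
class MarkerSummary:
    marker: str
    n: int
    mean: float
    ci95_low: float
    ci95_high: float


@dataclass
class ComparisonResult:
    variable: str
    groups: tuple
    test_name: str
    statistic: float
    p_value: float
    p_adjusted: float | None = None


def summarize_markers(
    cohort: pd.DataFrame, markers: list[str] | None = None, min_n: int = 30
) -> list[MarkerSummary]:
    """Mean and t-based 95% CI per marker; markers with n < ``min_n`` dropped.

    ``n`` counts non-missing values. A constant marker has a zero-width CI.
    """
    if markers is None:
        markers = list(cohort.attrs.get("markers", []))
        if not markers:
            raise ValueError("no marker columns given and none recorded on the cohort")
    out: list[MarkerSummary] = []
    for m in markers:
        vals = pd.to_numeric(cohort[m], errors="coerce").dropna().to_numpy()
        n = vals.size
        if n < min_n:
            continue
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        half = float(sps.t.ppf(0.975, n - 1) * sem) if n > 1 else 0.0
        out.append(MarkerSummary(marker=m, n=n, mean=mean, ci95_low=mean - half,
                                 ci95_high=mean + half))
    return out


def _normality_gate(groups: list[np.ndarray]) -> bool:
    """True when every group passes Shapiro-Wilk at 0.05 (n < 3 counts as non-normal)."""
    for g in groups:
        if g.size < 3:
            return False
        if np.ptp(g) == 0:
            return False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if sps.shapiro(g).pvalue < 0.05:
                return False
    return True


def compare_groups(values, group_labels, variable_kind: str, variable: str = "") -> ComparisonResult:
    """Compare a variable across groups, routing to the conventional test.

    ``variable_kind`` is ``"categorical"`` or ``"continuous"``. The choice of
    test is recorded in ``test_name`` and is a pure function of the data.
    """
    values = pd.Series(values).reset_index(drop=True)
    labels = pd.Series(group_labels).reset_index(drop=True)
    keep = values.notna() & labels.notna()
    values, labels = values[keep], labels[keep]
    group_names = tuple(sorted(labels.unique(), key=str))
    if len(group_names) < 2:
        raise ValueError("need at least two non-empty groups")

    if variable_kind == "categorical":
        table = pd.crosstab(values, labels).to_numpy()
        chi2, p, _, expected = sps.chi2_contingency(table)
        if table.shape == (2, 2) and (expected < 5).any():
            odds, p = sps.fisher_exact(table, alternative="two-sided")
            return ComparisonResult(variable, group_names, "fisher_exact", float(odds), float(p))
        if (expected < 5).any():
            warnings.warn(
                "sparse contingency table larger than 2x2; chi-square used",
                stacklevel=2,
            )
        return ComparisonResult(variable, group_names, "chi2", float(chi2), float(p))

    if variable_kind != "continuous":
        raise ValueError("variable_kind must be 'categorical' or 'continuous'")

    groups = [values[labels == g].to_numpy(dtype=float) for g in group_names]
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs at least two observations for continuous tests")
    normal = _normality_gate(groups)
    if len(groups) == 2:
        if normal:
            stat, p = sps.ttest_ind(groups[0], groups[1])
            name = "t_test"
        else:
            stat, p = sps.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
            name = "mann_whitney_u"
    else:
        if normal:
            stat, p = sps.f_oneway(*groups)
            name = "anova"
        else:
            stat, p = sps.kruskal(*groups)
            name = "kruskal_wallis"
    return ComparisonResult(variable, group_names, name, float(stat), float(p))


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlation_matrix(numeric_table: pd.DataFrame, min_pairs: int = 3):
    """Pairwise-complete Pearson correlations with BH-adjusted p-values.

    Returns ``(r, p, p_adj)`` DataFrames. Cells with fewer than ``min_pairs``
    complete pairs or a zero-variance column are reported missing and excluded
    from the BH family, which spans the strict upper triangle.
    """
    cols = list(numeric_table.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    entries: list[tuple[int, int, float]] = []
    for i in range(k):
        for j in range(i + 1, k):
            x = pd.to_numeric(numeric_table[cols[i]], errors="coerce")
            y = pd.to_numeric(numeric_table[cols[j]], errors="coerce")
            keep = x.notna() & y.notna()
            xv, yv = x[keep].to_numpy(), y[keep].to_numpy()
            if xv.size < min_pairs or np.ptp(xv) == 0 or np.ptp(yv) == 0:
                r.iloc[i, j] = r.iloc[j, i] = np.nan
                continue
            res = sps.pearsonr(xv, yv)
            r.iloc[i, j] = r.iloc[j, i] = res.statistic
            p.iloc[i, j] = p.iloc[j, i] = res.pvalue
            entries.append((i, j, res.pvalue))
    p_adj = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    if entries:
        adj = adjust_bh([e[2] for e in entries])
        for (i, j, _), a in zip(entries, adj):
            p_adj.iloc[i, j] = p_adj.iloc[j, i] = a
    return r, p, p_adj
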