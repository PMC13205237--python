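"""Figure helpers: KM curves, forest plots, cut-off curves, paired-bin strips."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .survival import KmCurve

__all__ = ["plot_km", "plot_forest", "plot_cutoff_curve", "plot_paired_bins"]


def plot_km(curves: dict[str, KmCurve], path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        times = np.concatenate([[0.0], curve.times])
        surv = np.concatenate([[1.0], curve.survival])
        ax.step(times, surv, where="post", label=label)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_forest(table: pd.DataFrame, path, title: str = "", ratio_col: str = "hazard_ratio",
                lo_col: str = "ci95_low", hi_col: str = "ci95_high") -> None:
    """Log-scale forest plot of ratio estimates with 95% CIs."""
    fig, ax = plt.subplots(figsize=(5, 0.5 * len(table) + 1.5))
    y = np.arange(len(table))[::-1]
    ax.errorbar(
        table[ratio_col], y,
        xerr=[table[ratio_col] - table[lo_col], table[hi_col] - table[ratio_col]],
        fmt="s", color="k", ecolor="gray", capsize=3,
    )
    ax.axvline(1.0, color="r", linestyle="--", linewidth=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels(table.index)
    ax.set_xscale("log")
    ax.set_xlabel(ratio_col.replace("_", " "))
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_cutoff_curve(cutoff_summary: pd.DataFrame, selected: float, path,
                      title: str = "") -> None:
    """Mean validation C-improvement per candidate cut-off."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(cutoff_summary["cutoff"], cutoff_summary["mean_delta"], "o-", ms=3)
    ax.axvline(selected, color="r", linestyle="--", linewidth=0.8,
               label=f"selected {selected:g}%")
    ax.axhline(0.0, color="gray", linewidth=0.5)
    ax.set_xlabel("candidate cut-off (%)")
    ax.set_ylabel("mean validation ΔC-index")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_paired_bins(bin_means: pd.DataFrame, p_value: float, path,
                     title: str = "") -> None:
    """Paired strip plot of binned validation C-indices, original vs revised."""
    fig, ax = plt.subplots(figsize=(4, 4))
    x0 = np.random.default_rng(0).normal(0.0, 0.03, len(bin_means))
    ax.plot(
        np.vstack([x0, 1 + x0]),
        np.vstack([bin_means["c_original"], bin_means["c_revised"]]),
        color="lightgray", linewidth=0.5, zorder=1,
    )
    ax.scatter(x0, bin_means["c_original"], s=8, zorder=2, label="original")
    ax.scatter(1 + x0, bin_means["c_revised"], s=8, zorder=2, label="revised")
    for x, col in ((0, "c_original"), (1, "c_revised")):
        ax.hlines(bin_means[col].mean(), x - 0.15, x + 0.15, color="k", zorder=3)
    ax.set_xticks([0, 1])
    ax.set_xticklabels(["original", "revised"])
    ax.set_ylabel("validation C-index (bin mean)")
    ax.set_title(title or f"paired bins, p = {p_value:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
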