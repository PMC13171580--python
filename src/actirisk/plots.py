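"""Publication-style figures: forest plots, calibration, decision curves,
feature-importance bars.  All functions return the matplotlib Figure and
optionally save it; they never call show()."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def forest_plot(results_table: pd.DataFrame, model: str = "M2", path=None):
    """Forest plot of per-tertile HRs for every rhythm parameter."""
    sub = results_table[results_table["model"] == model]
    rows = []
    for _, r in sub.iterrows():
        for t in ("T1", "T2", "T3"):
            hr = r.get(f"HR_{t}", np.nan)
            if not np.isfinite(hr) or hr == 1.0 and t == r["reference"]:
                continue
            rows.append((f"{r['parameter']} {t}", hr,
                         r.get(f"CI_low_{t}", np.nan), r.get(f"CI_high_{t}", np.nan)))
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(rows) + 1.5))
    y = np.arange(len(rows))[::-1]
    for yi, (label, hr, lo, hi) in zip(y, rows):
        ax.plot([lo, hi], [yi, yi], color="0.4", lw=1.2)
        ax.plot(hr, yi, "s", color="tab:blue", ms=4)
    ax.axvline(1.0, color="0.7", ls="--", lw=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels([r[0] for r in rows], fontsize=7)
    ax.set_xlabel("Hazard ratio (95% CI)")
    ax.set_xscale("log")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig


def calibration_plot(calibration: pd.DataFrame, path=None):
    """Observed event rate vs mean predicted risk by decile."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(calibration["pred_mean"], calibration["obs_rate"], "o-",
            color="tab:blue", ms=4)
    lim = max(calibration["pred_mean"].max(), calibration["obs_rate"].max()) * 1.1
    ax.plot([0, lim], [0, lim], "--", color="0.6", lw=0.8)
    ax.set_xlabel("Mean predicted risk")
    ax.set_ylabel("Observed event fraction")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig


def decision_curve_plot(dca: pd.DataFrame, path=None):
    """Net benefit vs threshold, with treat-all / treat-none references."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(dca["threshold"], dca["net_benefit"], label="model", color="tab:blue")
    ax.plot(dca["threshold"], dca["treat_all"], label="treat all", color="0.6")
    ax.axhline(0.0, color="0.3", lw=0.8, label="treat none")
    ax.set_xlabel("Threshold probability")
    ax.set_ylabel("Net benefit")
    ax.set_ylim(bottom=min(-0.001, dca["net_benefit"].min()))
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig


def shap_importance_plot(mean_abs: pd.Series, top: int = 15, path=None):
    """Horizontal bar chart of mean |SHAP| for the top features."""
    vals = mean_abs.head(top)[::-1]
    fig, ax = plt.subplots(figsize=(5, 0.3 * len(vals) + 1))
    ax.barh(np.arange(len(vals)), vals.to_numpy(), color="tab:blue")
    ax.set_yticks(np.arange(len(vals)))
    ax.set_yticklabels(vals.index, fontsize=8)
    ax.set_xlabel("mean |SHAP| (log-hazard)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig
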