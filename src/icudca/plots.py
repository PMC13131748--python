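"""Standard figures: discrimination/calibration panel, decision curves, ops."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve, roc_curve

from .evaluation import reliability_bins


def evaluation_figure(pred_sets: dict[str, pd.DataFrame], path: str | Path) -> None:
    """ROC, PR, reliability and risk-distribution panels, one line per model."""
    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    ax_roc, ax_pr, ax_cal, ax_hist = axes.ravel()
    for family, preds in pred_sets.items():
        y, p = preds["y"].to_numpy(), preds["p"].to_numpy()
        fpr, tpr, _ = roc_curve(y, p)
        ax_roc.plot(fpr, tpr, label=family)
        prec, rec, _ = precision_recall_curve(y, p)
        ax_pr.plot(rec, prec, label=family)
        bins = reliability_bins(y, p).dropna()
        ax_cal.plot(bins["mean_pred"], bins["obs_rate"], marker="o", ms=3, label=family)
        ax_hist.hist(p[y == 1], bins=30, alpha=0.35, label=f"{family} exit")
    ax_roc.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax_roc.set(xlabel="false positive rate", ylabel="true positive rate", title="ROC")
    ax_pr.set(xlabel="recall", ylabel="precision", title="Precision-recall")
    ax_cal.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax_cal.set(xlabel="mean predicted", ylabel="observed rate", title="Reliability (20 bins)")
    ax_hist.set(xlabel="predicted probability", title="Risk distribution (exit days)")
    for ax in axes.ravel():
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def dca_figure(curve: pd.DataFrame, path: str | Path) -> None:
    """Net benefit plus the flagged-fraction and per-1,000 workload panels."""
    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    t = curve["threshold"]
    ax = axes[0, 0]
    ax.plot(t, curve["nb_model"], label="model")
    ax.plot(t, curve["nb_all"], label="review all")
    ax.plot(t, curve["nb_none"], label="review none")
    if curve["nb_heuristic"].notna().any():
        ax.plot(t, curve["nb_heuristic"], label="heuristic")
    ax.set(xlabel="threshold", ylabel="net benefit", title="Decision curve")
    ax.set_ylim(bottom=max(-0.25, float(curve["nb_model"].min()) - 0.05))
    ax.legend(fontsize=8)
    axes[0, 1].plot(t, curve["flagged_fraction"])
    axes[0, 1].set(xlabel="threshold", ylabel="fraction flagged", title="Review burden")
    axes[1, 0].plot(t, curve["tp_per_1000"])
    axes[1, 0].set(xlabel="threshold", ylabel="TP / 1,000 days", title="True positives")
    axes[1, 1].plot(t, curve["fp_per_1000"])
    axes[1, 1].set(xlabel="threshold", ylabel="FP / 1,000 days", title="False positives")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def ops_figure(ops: pd.DataFrame, budget: float, t_star: float | None, path: str | Path) -> None:
    """Daily workload and days-to-target against threshold, budget line drawn."""
    fig, ax1 = plt.subplots(figsize=(8, 5))
    t = ops["threshold"]
    ax1.plot(t, ops["total_minutes"], label="total minutes/day", color="tab:blue")
    ax1.plot(t, ops["review_minutes"], "--", label="review minutes", color="tab:cyan")
    ax1.plot(t, ops["consent_minutes"], ":", label="consent minutes", color="tab:green")
    ax1.axhline(budget, color="k", ls="--", lw=0.8, label="daily budget")
    ax1.set(xlabel="threshold", ylabel="minutes per day")
    ax2 = ax1.twinx()
    finite = ops["days_to_target"].replace(np.inf, np.nan)
    ax2.plot(t, finite, color="tab:red", label="days to target")
    ax2.set_ylabel("days to enrollment target")
    if t_star is not None:
        ax1.axvline(t_star, color="gray", lw=0.8)
    lines, labels = ax1.get_legend_handles_labels()
    l2, lab2 = ax2.get_legend_handles_labels()
    ax1.legend(lines + l2, labels + lab2, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
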