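"""Publication-style figures for the pipeline outputs.

All functions return a matplotlib Figure; callers decide whether to save
or show. Kept deliberately thin — the TSV outputs are the primary
artifacts.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def forest_plot(records_df: pd.DataFrame, log_scale: bool = True, top: int = 30):
    """Odds-ratio (or beta) forest plot: point estimate with 95% CI per variable."""
    df = records_df.dropna(subset=["estimate"]).sort_values("p").head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, max(2, 0.3 * len(df))))
    y = np.arange(len(df))
    ax.errorbar(
        df["estimate"], y,
        xerr=[df["estimate"] - df["ci_low"], df["ci_high"] - df["estimate"]],
        fmt="o", color="k", ecolor="gray", capsize=2, markersize=4,
    )
    ref = 1.0 if (df["estimate"] > 0).all() and log_scale else 0.0
    ax.axvline(ref, ls="--", color="r", lw=0.8)
    if log_scale and (df["estimate"] > 0).all():
        ax.set_xscale("log")
        ax.set_xlabel("odds ratio (95% CI)")
    else:
        ax.set_xlabel("estimate (95% CI)")
    ax.set_yticks(y)
    ax.set_yticklabels(df["variable"], fontsize=7)
    fig.tight_layout()
    return fig


def auc_curve_plot(curve_df: pd.DataFrame, title: str = "CV AUC vs number of variables"):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve_df["n_features"], curve_df["mean_auc"], color="C0")
    ax.fill_between(curve_df["n_features"], curve_df["ci_low"], curve_df["ci_high"],
                    alpha=0.25, color="C0")
    ax.set_xlabel("number of variables (N)")
    ax.set_ylabel("mean cross-validated AUC")
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    return fig


def roc_plot(roc_df: pd.DataFrame):
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(roc_df["fpr"], roc_df["tpr_mean"], color="C1")
    ax.fill_between(roc_df["fpr"], roc_df["tpr_ci_low"], roc_df["tpr_ci_high"],
                    alpha=0.25, color="C1")
    ax.plot([0, 1], [0, 1], ls="--", color="gray", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    fig.tight_layout()
    return fig


def pca_biplot(scores: pd.DataFrame, labels, arrows: pd.DataFrame | None = None):
    """PC1/PC2 scatter coloured by group, with optional marker arrows."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    labels = np.asarray(labels)
    for g, c in zip(np.unique(labels), ("C0", "C3")):
        m = labels == g
        ax.scatter(scores.loc[m, "PC1"], scores.loc[m, "PC2"], s=10, alpha=0.6,
                   color=c, label=str(g))
    if arrows is not None:
        scale = 0.8 * max(scores["PC1"].abs().max(), scores["PC2"].abs().max())
        for name, row in arrows.iterrows():
            ax.annotate("", xy=(row.iloc[0] * scale, row.iloc[1] * scale), xytext=(0, 0),
                        arrowprops=dict(arrowstyle="->", color="k"))
            ax.text(row.iloc[0] * scale, row.iloc[1] * scale, str(name), fontsize=6)
    ax.legend(fontsize=7)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    fig.tight_layout()
    return fig
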