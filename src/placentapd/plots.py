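"""Optional figures: trajectory panels and the FRI bar chart."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

GROUP_COLORS = {"control": "#4477aa", "disease": "#cc3311", "treated": "#228833"}


def plot_trajectories(measured: pd.DataFrame, markers: list[str] | None = None):
    """Group mean +/- SEM trajectories per marker (one panel each)."""
    markers = markers or sorted(measured["marker"].unique())
    ncols = min(3, len(markers))
    nrows = -(-len(markers) // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows), squeeze=False)
    for ax, marker in zip(axes.ravel(), markers):
        sub = measured[measured["marker"] == marker]
        for group, gsub in sub.groupby("group"):
            agg = gsub.groupby("gd")["value"].agg(["mean", "sem"])
            ax.errorbar(agg.index, agg["mean"], yerr=agg["sem"], marker="o",
                        capsize=3, label=group, color=GROUP_COLORS.get(group))
        ax.set_title(marker)
        ax.set_xlabel("gestational day")
    for ax in axes.ravel()[len(markers):]:
        ax.set_visible(False)
    axes[0, 0].legend(frameon=False)
    fig.tight_layout()
    return fig


def plot_fri(summary: pd.DataFrame, fri_col: str = "fri_mean", err_col: str = "fri_sem"):
    """Bar chart of per-marker Functional Recovery Indices."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    sub = summary.dropna(subset=[fri_col])
    err = sub[err_col] if err_col in sub.columns else None
    ax.bar(sub["marker"], sub[fri_col], yerr=err, capsize=4, color="#228833")
    ax.axhline(100, ls="--", c="gray", lw=1, label="full normalization")
    ax.axhline(0, ls=":", c="gray", lw=1, label="disease level")
    ax.set_ylabel("FRI at endpoint (%)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig
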