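"""Figure generation: scatterplot matrix and grade-coded scatterplots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from prolifmark.cohort_stats import MARKER_VARIABLES, RegressionFit, correlation_matrix

__all__ = ["scatter_matrix_plot", "grade_scatter_plot"]

_LABELS = {
    "mitoses_per_10hpf": "Mitoses / 10 HPF",
    "mib1_per_field": "MIB-1 / 10x field",
    "phh3_per_field": "PhH3 / 10x field",
    "iod": "Nuclear IOD",
}
_GRADE_GREYS = {1: "0.8", 2: "0.5", 3: "0.1"}


def scatter_matrix_plot(table: pd.DataFrame, path, variables=MARKER_VARIABLES) -> None:
    """Pairwise scatterplots (upper right), histograms (diagonal), r (lower left)."""
    corr = correlation_matrix(table, variables)
    k = len(variables)
    fig, axes = plt.subplots(k, k, figsize=(2.2 * k, 2.2 * k))
    for i, vi in enumerate(variables):
        for j, vj in enumerate(variables):
            ax = axes[i, j]
            if i == j:
                ax.hist(table[vi], bins=15, color="0.6")
            elif i < j:
                ax.scatter(table[vj], table[vi], s=8, color="0.3")
            else:
                ax.text(0.5, 0.5, f"r = {corr.loc[vi, vj]:.2f}",
                        ha="center", va="center", fontsize=11)
                ax.set_xticks([]); ax.set_yticks([])
            if i == k - 1:
                ax.set_xlabel(_LABELS[vj], fontsize=7)
            if j == 0:
                ax.set_ylabel(_LABELS[vi], fontsize=7)
            ax.tick_params(labelsize=6)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)


def grade_scatter_plot(table: pd.DataFrame, path,
                       x_col: str = "phh3_per_field",
                       y_col: str = "mib1_per_field",
                       fit: RegressionFit | None = None) -> None:
    """Scatterplot of two markers with tumors shaded by grade and optional fit line."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for grade, sub in table.groupby("grade"):
        ax.scatter(sub[x_col], sub[y_col], s=18,
                   color=_GRADE_GREYS.get(int(grade), "0.5"),
                   edgecolor="black", linewidth=0.3, label=f"grade {grade}")
    if fit is not None:
        xs = np.linspace(table[x_col].min(), table[x_col].max(), 50)
        ax.plot(xs, fit.predict(xs), color="black", linewidth=1)
        ax.set_title(
            f"{_LABELS.get(y_col, y_col)} = {fit.slope:.1f} x {_LABELS.get(x_col, x_col)}"
            f" + {fit.intercept:.0f}  (r = {fit.pearson_r:.2f})", fontsize=8)
    ax.set_xlabel(_LABELS.get(x_col, x_col))
    ax.set_ylabel(_LABELS.get(y_col, y_col))
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
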