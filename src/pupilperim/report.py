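"""Headless-safe plotting: per-parameter AUC panels and weight heat maps."""

from __future__ import annotations

import numpy as np

from .features import PARAMETER_NAMES
from .protocol import VisualFieldGrid


def plot_auc_panel(results, eye: str, conditions=("dim_red", "dim_blue"), path=None):
    """Mean +- SD AUC-ROC per parameter for one eye, dashed line at 0.7."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    colors = {"dim_red": "tab:red", "dim_blue": "tab:blue",
              "bright_red": "darkred", "bright_blue": "navy"}
    x = np.arange(len(PARAMETER_NAMES))
    for cond in conditions:
        means, sds = [], []
        for p in PARAMETER_NAMES:
            res = results.get(f"{p}|{cond}|{eye}")
            means.append(res.auc_mean if res else np.nan)
            sds.append(res.auc_sd if res else np.nan)
        ax.errorbar(x, means, yerr=sds, fmt="o", color=colors.get(cond, "k"),
                    label=cond, capsize=2)
    ax.axhline(0.7, ls="--", color="k", lw=1)
    ax.set_xticks(x, PARAMETER_NAMES, rotation=45)
    ax.set_ylabel("AUC-ROC")
    ax.set_title(f"{eye} eye")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig


def plot_weight_map(weight_map, grid: VisualFieldGrid, path=None):
    """Visual-field heat map of the averaged per-target model weights."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [loc.x_deg for loc in grid.locations]
    ys = [loc.y_deg for loc in grid.locations]
    fig, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(xs, ys, c=np.asarray(weight_map), s=200, cmap="Blues",
                    edgecolors="gray")
    fig.colorbar(sc, ax=ax, label="relative weight")
    ax.set_xlabel("x (deg, + = temporal field for right eye)")
    ax.set_ylabel("y (deg)")
    ax.set_title(f"{grid.eye.value} eye")
    ax.set_aspect("equal")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig
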