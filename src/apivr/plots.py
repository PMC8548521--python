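"""Figure rendering: learning curves and occupancy heat maps.

The heat map colour scale is clipped at 10% of the maximum bin count so the
shared start location does not swamp the rest of the arena; raw counts are
untouched.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .metrics import OccupancyGrid

__all__ = ["plot_learning_curves", "plot_heatmap"]

_CURVE_COLORS = {"cs_plus": "#c0392b", "cs_minus": "#2c3e50", "nc": "#95a5a6"}


def plot_learning_curves(curves: pd.DataFrame, path: Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for cat, grp in curves.groupby("category"):
        grp = grp.sort_values("trial")
        color = _CURVE_COLORS.get(cat, None)
        ax.plot(grp["trial"], 100 * grp["proportion"], label=cat, color=color)
        ax.fill_between(
            grp["trial"], 100 * grp["ci_low"], 100 * grp["ci_high"], alpha=0.2, color=color
        )
    ax.set_xlabel("trial")
    ax.set_ylabel("% of bees")
    ax.set_ylim(0, 100)
    ax.legend(frameon=False)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_heatmap(grid: OccupancyGrid, path: Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    vmax = grid.display_cap if grid.display_cap > 0 else None
    im = ax.imshow(
        grid.counts.T,
        origin="lower",
        extent=(grid.x_edges[0], grid.x_edges[-1], grid.y_edges[0], grid.y_edges[-1]),
        cmap="inferno",
        vmax=vmax,
        interpolation="nearest",
    )
    fig.colorbar(im, ax=ax, label="samples (capped)")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
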