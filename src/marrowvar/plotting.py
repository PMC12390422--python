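"""Figure helpers: axial trajectories, PDFF heatmaps, violin quartiles.

All functions accept an existing Axes and return it, so they compose
into panels; none call ``plt.show``.
"""

from __future__ import annotations

import numpy as np

from .heterogeneity import HeatmapSlice
from .segmentation import AxialTrajectory, RegionBoundaries


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_trajectory(traj: AxialTrajectory, ax=None, boundaries: RegionBoundaries | None = None):
    """Axial mean PDFF curve, optionally with region boundary lines."""
    ax = _get_ax(ax)
    ax.plot(traj.slice_index, traj.mean_pdff, marker="o", ms=3)
    if boundaries is not None:
        for x in (boundaries.p_end, boundaries.d_start):
            ax.axvline(x - 0.5, color="grey", lw=0.8)
    ax.set_xlabel("slice (proximal → distal)")
    ax.set_ylabel("mean PDFF (%)")
    ax.set_ylim(0, 100)
    return ax


def plot_heatmap(hm: HeatmapSlice, ax=None, cmap: str = "turbo"):
    """One axial slice on the fixed 0-100% pseudo-colour scale.

    Out-of-mask pixels are NaN and render transparent.
    """
    ax = _get_ax(ax)
    im = ax.imshow(hm.values, cmap=cmap, vmin=hm.vmin, vmax=hm.vmax, interpolation="nearest")
    ax.figure.colorbar(im, ax=ax, label="PDFF (%)")
    ax.set_title(f"slice {hm.slice_index}")
    ax.set_xticks([])
    ax.set_yticks([])
    return ax


def plot_violin_quartiles(quartiles, group: str, ax=None):
    """Q1/median/Q3 per scan day for one group (violin-style summary)."""
    ax = _get_ax(ax)
    sub = quartiles[quartiles["group"] == group].sort_values("day")
    days = sub["day"].to_numpy()
    med = sub["median"].to_numpy()
    ax.errorbar(
        days,
        med,
        yerr=np.vstack([med - sub["q1"], sub["q3"] - med]),
        fmt="o-",
        capsize=4,
    )
    ax.set_xlabel("study day")
    ax.set_ylabel("heterogeneity score (%²)")
    ax.set_title(group)
    return ax
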