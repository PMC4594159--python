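"""Matplotlib summaries: field overlays and NN-distance histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .colocalization import ColocSummary
from .containers import Focus, ImageStack, LabelMask


def plot_field(stack: ImageStack, foci: list[Focus] | None = None,
               mask: LabelMask | None = None, ax=None):
    """Max projection with optional mask outline and focus markers."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(stack.max_projection(), cmap="gray", interpolation="nearest")
    if mask is not None:
        ax.contour(mask.plane_labels() > 0, levels=[0.5], colors="cyan",
                   linewidths=0.5)
    if foci:
        xs = [f.x for f in foci]
        ys = [f.y for f in foci]
        ax.plot(xs, ys, "r+", markersize=6)
    ax.set_axis_off()
    return ax


def plot_distance_histograms(summary: ColocSummary, ax=None):
    """Reciprocal NN-distance histograms with the co-localization threshold."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    centers = 0.5 * (summary.hist_bins_um[:-1] + summary.hist_bins_um[1:])
    width = np.diff(summary.hist_bins_um).mean() * 0.4
    ax.bar(centers - width / 2, summary.hist_red_to_green, width=width,
           label="red → nearest green", color="tab:red", alpha=0.7)
    ax.bar(centers + width / 2, summary.hist_green_to_red, width=width,
           label="green → nearest red", color="tab:green", alpha=0.7)
    ax.axvline(summary.threshold_um, ls="--", color="k",
               label=f"threshold {summary.threshold_um} µm")
    ax.set_xlabel("nearest-neighbour distance (µm)")
    ax.set_ylabel("foci")
    ax.legend(frameon=False)
    return ax
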