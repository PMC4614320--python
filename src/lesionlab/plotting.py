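"""Convenience figures: per-trace disability curves and MAoD heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .results import DisabilityTrace, MAoDGrid

__all__ = ["plot_trace", "plot_grid"]


def plot_trace(trace: DisabilityTrace, ax=None, label=None):
    """Disability vs time, with removal events marked as vertical lines."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(trace.times, trace.disability, label=label)
    for t_ev, _ in trace.events:
        ax.axvline(t_ev, color="gray", lw=0.5, ls="--")
    ax.set_xlabel(trace.meta.get("time_column", "t"))
    ax.set_ylabel("disability")
    if label:
        ax.legend()
    return ax


def plot_grid(grid: MAoDGrid, ax=None):
    """Heatmap of per-cell mean MAoD (axis1 rows x IRT columns)."""
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(grid.means, aspect="auto", origin="lower", cmap="coolwarm")
    ax.set_xticks(range(len(grid.axis2)), [str(v) for v in grid.axis2])
    ax.set_yticks(range(len(grid.axis1)), [str(v) for v in grid.axis1])
    ax.set_xlabel(grid.axis2_name)
    ax.set_ylabel(grid.axis1_name)
    ax.figure.colorbar(im, ax=ax, label="mean MAoD")
    return ax
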