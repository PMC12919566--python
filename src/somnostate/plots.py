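"""Hypnogram and population-heatmap visualization.

State colors follow a fixed light-to-dark convention: state 0 (most
active) lightest through state k-1 (deepest sleep) darkest, so figures
are comparable across analyses.  All plot functions are read-only with
respect to data and return the written image path.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap

from .pipeline import ConsensusResult

__all__ = ["state_palette", "plot_hypnogram", "plot_population_heatmap"]


def state_palette(k: int) -> list:
    """Light (active) to dark (deep sleep) colors for k states."""
    cmap = matplotlib.colormaps["Blues"]
    return [cmap(0.25 + 0.7 * i / max(k - 1, 1)) for i in range(k)]


def plot_hypnogram(
    consensus_days: Sequence[ConsensusResult],
    out_path,
    palette: Optional[Sequence] = None,
) -> Path:
    """One stacked panel per day: per-minute state as vertical bars in
    state-specific colors, transitions as connecting lines, and a
    light/dark bar along the time axis (phase taken from the day when
    present, otherwise ZT0-720 is treated as light)."""
    days = list(consensus_days)
    if not days:
        raise ValueError("no consensus days to plot")
    k = days[0].k
    colors = list(palette) if palette is not None else state_palette(k)
    fig, axes = plt.subplots(
        len(days), 1, figsize=(10, 1.8 * len(days)), squeeze=False,
        sharex=True,
    )
    for ax, day in zip(axes[:, 0], days):
        states = day.consensus
        n = len(states)
        t = np.arange(n)
        # plotted upside-down so deeper sleep sits lower
        y = k - 1 - states
        ax.plot(t, y, color="0.6", lw=0.4, zorder=1)
        for s in range(k):
            m = states == s
            ax.vlines(t[m], -0.5, y[m], color=colors[s], lw=0.6, zorder=2)
        if day.phase is not None:
            is_day = np.asarray(day.phase) == "day"
        else:
            is_day = t < 720
        ax.imshow(
            (~is_day)[None, :], extent=(0, n, -0.95, -0.55), aspect="auto",
            cmap=ListedColormap(["white", "black"]), vmin=0, vmax=1,
        )
        ax.set_ylim(-1, k - 0.5)
        ax.set_yticks(range(k))
        ax.set_yticklabels([f"State{k - 1 - i}" for i in range(k)])
        ax.set_ylabel(f"day {day.day_index}")
    axes[-1, 0].set_xlabel("Zeitgeber time (min)")
    axes[0, 0].set_title(days[0].fly_id)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def plot_population_heatmap(
    consensus_by_fly: dict,
    out_path,
    palette: Optional[Sequence] = None,
) -> Path:
    """Flies x minutes raster colored by state, one row per fly-day,
    flies in sorted fly_id order.

    ``consensus_by_fly`` maps fly_id to its list of ConsensusResult days;
    all days must have equal length.
    """
    if not consensus_by_fly:
        raise ValueError("no flies to plot")
    rows = []
    labels = []
    length = None
    k = None
    for fly_id in sorted(consensus_by_fly):
        for day in consensus_by_fly[fly_id]:
            if length is None:
                length = len(day.consensus)
                k = day.k
            elif len(day.consensus) != length:
                raise ValueError("inconsistent day lengths across flies")
            rows.append(day.consensus)
            labels.append(f"{fly_id} d{day.day_index}")
    raster = np.vstack(rows)
    colors = list(palette) if palette is not None else state_palette(k)
    fig, ax = plt.subplots(
        figsize=(10, max(2.0, 0.18 * len(rows) + 1.0))
    )
    ax.imshow(
        raster, aspect="auto", interpolation="nearest",
        cmap=ListedColormap(colors), vmin=-0.5, vmax=k - 0.5,
    )
    ax.set_xlabel("Zeitgeber time (min)")
    ax.set_yticks(range(len(labels)))
    ax.set_yticklabels(labels, fontsize=6)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
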