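"""Decorative plotting helpers (no analysis logic, nothing asserts on these).

Each function returns a matplotlib Figure; callers decide whether to save.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["plot_hexagon_loci", "plot_fly_loci", "plot_marker_histogram", "plot_contrast_violin"]


def _hexagon_outline():
    angles = np.deg2rad(np.arange(30, 391, 60))
    return np.cos(angles), np.sin(angles)


def plot_hexagon_loci(contrasts: pd.DataFrame, ax=None):
    """Colour loci in the bee hexagon (rows with model == 'hexagon')."""
    import matplotlib.pyplot as plt

    fig = None
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 5))
    hx, hy = _hexagon_outline()
    ax.plot(hx, hy, color="0.4", lw=1)
    sub = contrasts[contrasts["model"] == "hexagon"]
    for grp, rows in sub.groupby("group", dropna=False):
        ax.scatter(rows["x"], rows["y"], s=18, label=str(grp), alpha=0.8)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_aspect("equal")
    ax.set_xlabel("x (EU)")
    ax.set_ylabel("y (EU)")
    ax.legend(fontsize=7)
    return fig or ax.figure


def plot_fly_loci(contrasts: pd.DataFrame, ax=None):
    """Colour loci in the categorical fly space (square [-1, 1]^2)."""
    import matplotlib.pyplot as plt

    fig = None
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 5))
    for v in (-1, 1):
        ax.axhline(v, color="0.4", lw=1)
        ax.axvline(v, color="0.4", lw=1)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    sub = contrasts[contrasts["model"] == "fly_categorical"]
    for grp, rows in sub.groupby("group", dropna=False):
        ax.scatter(rows["x"], rows["y"], s=18, label=str(grp), alpha=0.8)
    ax.set_aspect("equal")
    ax.set_xlabel("R7p - R8p signal")
    ax.set_ylabel("R7y - R8y signal")
    ax.legend(fontsize=7)
    return fig or ax.figure


def plot_marker_histogram(marker_bins: pd.DataFrame, ax=None):
    """Relative marker-point frequency per 10 nm bin, one panel per class."""
    import matplotlib.pyplot as plt

    groups = list(dict.fromkeys(marker_bins["group"])) if len(marker_bins) else []
    n = max(len(groups), 1)
    fig, axes = plt.subplots(n, 1, figsize=(6, 2.2 * n), squeeze=False)
    for axi, grp in zip(axes.ravel(), groups):
        rows = marker_bins[marker_bins["group"] == grp]
        width = (rows["bin_hi"] - rows["bin_lo"]).iloc[0] if len(rows) else 10
        axi.bar(rows["bin_lo"], rows["rel_freq"], width=width, align="edge")
        axi.set_title(str(grp), fontsize=9)
        axi.set_xlim(300, 700)
        axi.set_ylabel("rel. freq.")
    axes.ravel()[-1].set_xlabel("wavelength (nm)")
    fig.tight_layout()
    return fig


def plot_contrast_violin(contrasts: pd.DataFrame, model: str = "hexagon", ax=None):
    """Distribution of chromatic contrast per colour class for one model."""
    import matplotlib.pyplot as plt

    fig = None
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    sub = contrasts[(contrasts["model"] == model)].dropna(subset=["group"])
    groups = list(dict.fromkeys(sub["group"]))
    data = [sub.loc[sub["group"] == g, "chromatic_EU"].to_numpy() for g in groups]
    if data:
        ax.violinplot(data, showmeans=True)
        ax.set_xticks(range(1, len(groups) + 1), groups, rotation=30, fontsize=8)
    ax.set_ylabel("chromatic contrast (EU)")
    ax.set_title(model)
    return fig or ax.figure
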