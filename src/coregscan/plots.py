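"""Plain plotting helpers: KM step curves, -log10(q) panel heatmap, UpSet-style bars.

Content-faithful, not pixel-faithful: these render the quantities the
pipeline computes without attempting any published figure's aesthetics.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .survival import KmCurve

__all__ = ["plot_km", "plot_q_matrix", "plot_intersections"]


def plot_km(curves: dict[str, KmCurve], ax=None, title: str = ""):
    """Step plot of one KM curve per labeled group."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        x = np.concatenate([[0.0], curve.timeline])
        y = np.concatenate([[1.0], curve.survival])
        ax.step(x, y, where="post", label=label)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    if title:
        ax.set_title(title)
    return ax


def plot_q_matrix(q_matrix: pd.DataFrame, ax=None):
    """Heatmap of -log10(q) per class (rows) and cohort/direction (columns)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.6 * q_matrix.shape[1], 2 + 0.4 * q_matrix.shape[0]))
    im = ax.imshow(q_matrix.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(q_matrix.shape[1]), q_matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(q_matrix.shape[0]), q_matrix.index, fontsize=8)
    plt.colorbar(im, ax=ax, label="-log10(q)")
    return ax


def plot_intersections(combination_sizes: dict[tuple[str, ...], int], ax=None):
    """Bar chart of exclusive combination sizes (UpSet-style, no matrix dots)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    items = sorted(combination_sizes.items(), key=lambda kv: -kv[1])
    labels = ["&".join(c) for c, _ in items]
    ax.bar(range(len(items)), [n for _, n in items])
    ax.set_xticks(range(len(items)), labels, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("genes")
    return ax
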