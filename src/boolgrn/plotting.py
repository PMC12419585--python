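"""Diagnostic plots: mean-SD trend, volcano, attractor heatmaps.

All functions take an output path and write a PNG; matplotlib is imported
lazily with the Agg backend so headless runs work.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dynamics import AttractorSet


def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_mean_sd(trend: pd.DataFrame, path) -> None:
    """Scatter of per-gene (mean, SD) with the running-median trend line."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(trend["mean"], trend["sd"], s=4, alpha=0.3, label="genes")
    ax.plot(trend["mean"], trend["trend"], color="red", lw=1.5, label="median trend")
    ax.set_xlabel("mean log2(normalized + 1)")
    ax.set_ylabel("SD")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_volcano(deg: pd.DataFrame, path, fc_cut: float = 1.5) -> None:
    """log2FC vs -log10 p, significant genes highlighted."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 4))
    sig = deg["class"] != "ns"
    ax.scatter(deg.loc[~sig, "log2FC"], -np.log10(deg.loc[~sig, "p"]),
               s=5, color="grey", alpha=0.5)
    ax.scatter(deg.loc[sig, "log2FC"], -np.log10(deg.loc[sig, "p"]),
               s=8, color="red")
    for x in (-fc_cut, fc_cut):
        ax.axvline(x, ls="--", lw=0.8, color="black")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_attractor(attractors: AttractorSet, index: int, path,
                   n_steps: int = 8) -> None:
    """Genes x steps heatmap of one attractor's cycle, repeated to n_steps."""
    plt = _pyplot()
    a = attractors.attractors[index]
    cycle = [
        [(s >> i) & 1 for i in range(len(attractors.genes))] for s in a.states
    ]
    steps = [cycle[t % len(cycle)] for t in range(n_steps)]
    mat = np.array(steps).T  # genes x steps
    fig, ax = plt.subplots(figsize=(4, 0.25 * len(attractors.genes) + 1))
    ax.imshow(mat, aspect="auto", cmap="Greys", vmin=0, vmax=1)
    ax.set_yticks(range(len(attractors.genes)), attractors.genes, fontsize=6)
    ax.set_xlabel("step")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
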