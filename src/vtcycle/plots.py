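"""Figures for the cohort analysis.

All functions take data already computed by :mod:`vtcycle.features` /
:mod:`vtcycle.episodes` and write a file; nothing is recomputed here.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from vtcycle.episodes import Cohort

GROUP_COLORS = {"terminating": "tab:blue", "sustained": "tab:red", "unknown": "tab:gray"}


def poincare_plot(cohort: Cohort, path, n: int = 10) -> None:
    """Lag-1 Poincaré scatter of the first ``n`` CLs of every episode.

    Each episode contributes n-1 (CL_i, CL_{i+1}) pairs, coloured by
    outcome; the identity line marks perfectly stable rhythm.
    """
    fig, ax = plt.subplots(figsize=(5.2, 5.2))
    seen = set()
    for e in cohort:
        x = e.cl_ms[: min(n, e.n_beats)]
        label = e.label if e.label not in seen else None
        seen.add(e.label)
        ax.scatter(x[:-1], x[1:], s=14, alpha=0.55,
                   color=GROUP_COLORS.get(e.label, "k"), label=label)
    lims = ax.get_xlim()
    lo, hi = min(lims[0], ax.get_ylim()[0]), max(lims[1], ax.get_ylim()[1])
    ax.plot([lo, hi], [lo, hi], color="gray", lw=1, zorder=0)
    ax.set_xlabel("CL$_i$ (ms)")
    ax.set_ylabel("CL$_{i+1}$ (ms)")
    ax.set_title(f"Poincaré plot, first {n} CLs per episode")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def feature_boxplots(
    features: pd.DataFrame,
    path,
    columns: tuple = ("sd_cl10", "tinn10", "ar_phi"),
) -> None:
    """Side-by-side group box plots (with jittered points) per feature."""
    fig, axes = plt.subplots(1, len(columns), figsize=(3.2 * len(columns), 3.8))
    axes = np.atleast_1d(axes)
    rng = np.random.default_rng(0)  # jitter only; cosmetic
    for ax, col in zip(axes, columns):
        groups, data = [], []
        for lbl in ("terminating", "sustained"):
            vals = features.loc[features["label"] == lbl, col].to_numpy()
            groups.append(lbl)
            data.append(vals)
        ax.boxplot(data, tick_labels=["term.", "sust."], showfliers=False)
        for i, vals in enumerate(data):
            xs = 1 + i + rng.normal(0, 0.05, len(vals))
            ax.scatter(xs, vals, s=10, alpha=0.6, color=GROUP_COLORS[groups[i]])
        ax.set_title(col)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def feature_scatter_3d(
    features: pd.DataFrame,
    path,
    columns: tuple = ("sd_cl10", "ar_phi", "tinn10"),
) -> None:
    """3-D scatter of three features, coloured by outcome."""
    fig = plt.figure(figsize=(5.8, 5.2))
    ax = fig.add_subplot(projection="3d")
    for lbl in ("terminating", "sustained"):
        g = features[features["label"] == lbl]
        ax.scatter(g[columns[0]], g[columns[1]], g[columns[2]],
                   s=18, alpha=0.7, color=GROUP_COLORS[lbl], label=lbl)
    ax.set_xlabel(columns[0])
    ax.set_ylabel(columns[1])
    ax.set_zlabel(columns[2])
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
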