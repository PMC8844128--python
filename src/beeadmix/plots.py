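"""Figure helpers: stacked ancestry barplots and PCA scatter plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

LINEAGE_COLORS = {"A": "#d95f02", "M": "#1b9e77", "C": "#7570b3", "O": "#e7298a"}


def admixture_barplot(q: np.ndarray, cluster_labels, groups, path) -> None:
    """Stacked per-individual ancestry bars, grouped by population/lineage."""
    groups = pd.Series(list(groups))
    order = np.argsort(groups.values, kind="stable")
    q_ord = q[order]
    fig, ax = plt.subplots(figsize=(max(6, q.shape[0] * 0.12), 3))
    bottom = np.zeros(q.shape[0])
    for k, lab in enumerate(cluster_labels):
        color = LINEAGE_COLORS.get(lab)
        ax.bar(np.arange(q.shape[0]), q_ord[:, k], bottom=bottom, width=1.0,
               color=color, label=lab)
        bottom += q_ord[:, k]
    # group separators and labels
    grp = groups.values[order]
    edges = np.flatnonzero(grp[1:] != grp[:-1]) + 1
    for e in edges:
        ax.axvline(e - 0.5, color="black", lw=0.8)
    ticks, labels = [], []
    start = 0
    for e in list(edges) + [len(grp)]:
        ticks.append((start + e - 1) / 2)
        labels.append(str(grp[start]))
        start = e
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=7)
    ax.set_ylim(0, 1)
    ax.set_ylabel("ancestry")
    ax.legend(fontsize=7, ncol=len(cluster_labels), loc="upper center",
              bbox_to_anchor=(0.5, 1.18))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def pca_scatter(coords: np.ndarray, groups, explained, path) -> None:
    """PC1 vs PC2 colored by group."""
    groups = pd.Series(list(groups))
    fig, ax = plt.subplots(figsize=(5, 4))
    for name in groups.unique():
        sel = groups.values == name
        ax.scatter(coords[sel, 0], coords[sel, 1], s=12, label=str(name),
                   color=LINEAGE_COLORS.get(str(name)))
    ax.set_xlabel(f"PC1 ({explained[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({explained[1] * 100:.1f}%)")
    ax.legend(fontsize=7, markerscale=1.2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
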