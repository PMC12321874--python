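"""Static figures: class-sorted fingerprint bars and dendrograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster.hierarchy import dendrogram

__all__ = ["plot_fingerprint", "plot_dendrogram"]


def plot_fingerprint(rows, path, title: str = "Pathway fingerprint"):
    """Horizontal bar chart of per-pathway Jaccard, grouped by KEGG class."""
    rows = list(rows)
    labels = [f"{r.kegg_class} | {r.pathway_id}" for r in rows]
    values = [r.jaccard for r in rows]
    colors = ["#d62728" if r.flagged else "#1f77b4" for r in rows]
    fig, ax = plt.subplots(figsize=(8, max(2, 0.3 * len(rows))))
    y = np.arange(len(rows))
    ax.barh(y, values, color=colors)
    ax.set_yticks(y, labels, fontsize=7)
    ax.invert_yaxis()
    ax.set_xlabel("Jaccard similarity with driving genes")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_dendrogram(cluster_labels, path, title: str = "Spectral dendrogram"):
    """Dendrogram of the agglomerative merge tree of a clustering result."""
    fig, ax = plt.subplots(figsize=(8, 4))
    dendrogram(
        np.asarray(cluster_labels.merge_tree),
        labels=cluster_labels.ids,
        leaf_rotation=90,
        leaf_font_size=7,
        ax=ax,
    )
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
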