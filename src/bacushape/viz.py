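"""Minimal plotting: a tree with tips colored by a trait (smoke-test grade)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .trees import Phylogeny  # noqa: E402

__all__ = ["plot_tree_trait"]


def plot_tree_trait(tree: Phylogeny, trait: pd.Series, path: str,
                    cmap: str = "viridis") -> None:
    """Rectangular cladogram with tip markers colored by the trait value."""
    n = tree.n_tips
    ypos = np.zeros(tree.n_nodes)
    order = [v for v in tree.postorder if v < n]
    for rank, tip in enumerate(order):
        ypos[tip] = rank
    for v in tree.postorder:
        if tree.children[v]:
            ypos[v] = np.mean([ypos[c] for c in tree.children[v]])
    fig, ax = plt.subplots(figsize=(6, 0.3 * n + 1))
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        x0, x1 = tree.node_height[p], tree.node_height[v]
        ax.plot([x0, x1], [ypos[v], ypos[v]], color="0.3", lw=1)
        ax.plot([x0, x0], [ypos[p], ypos[v]], color="0.3", lw=1)
    vals = trait.reindex(tree.tip_labels).to_numpy(dtype=float)
    sc = ax.scatter(tree.node_height[:n], ypos[:n], c=vals, cmap=cmap,
                    zorder=3, s=40)
    for i, lab in enumerate(tree.tip_labels):
        ax.text(tree.node_height[i] + 0.02, ypos[i], lab, va="center",
                fontsize=7)
    fig.colorbar(sc, ax=ax, label=trait.name or "trait")
    ax.set_yticks([])
    ax.set_xlabel("time")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
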