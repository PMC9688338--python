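"""Plain 2-D matrix and graph views of connectivity results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .nbs import WeightedNetwork

__all__ = ["plot_adjacency", "plot_network"]


def plot_adjacency(matrix: np.ndarray, node_labels: list[str] | None = None,
                   ax=None, title: str = ""):
    """Heatmap of an adjacency / connectivity / t matrix."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    m = np.asarray(matrix, dtype=float)
    im = ax.imshow(m, cmap="viridis")
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    if node_labels:
        ax.set_xticks(range(len(node_labels)), node_labels, rotation=90,
                      fontsize=6)
        ax.set_yticks(range(len(node_labels)), node_labels, fontsize=6)
    if title:
        ax.set_title(title)
    return ax


def plot_network(W: WeightedNetwork | np.ndarray, ax=None,
                 highlight: list[str] | None = None, seed: int = 0):
    """Spring-layout drawing with edge widths proportional to weight."""
    if isinstance(W, WeightedNetwork):
        weights, labels = W.weights, W.node_labels
    else:
        weights = np.asarray(W, dtype=float)
        labels = [f"n{i}" for i in range(weights.shape[0])]
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    G = nx.from_numpy_array(weights)
    pos = nx.spring_layout(G, seed=seed)
    wmax = max((d["weight"] for *_, d in G.edges(data=True)), default=1.0)
    widths = [2.5 * d["weight"] / wmax for *_, d in G.edges(data=True)]
    colors = ["tab:red" if labels[i] in (highlight or []) else "tab:blue"
              for i in G.nodes]
    nx.draw_networkx(G, pos=pos, ax=ax, width=widths, node_color=colors,
                     labels=dict(enumerate(labels)), font_size=7,
                     node_size=250)
    ax.set_axis_off()
    return ax
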