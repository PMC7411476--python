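"""Static figures for the two network tracks.

Correlation networks are drawn with class-coded node colours
(chemokine green, innate pink, adaptive blue, growth factor black),
edge colour by correlation sign (red positive, blue negative) and edge
width proportional to |r|.  CCC output comprises three heat maps
(target density, secretory density, cell_sd over cells) and a circular
communication diagram with edge width proportional to |Ecc|.  Layouts
are deterministic (seeded spring layout / roster-order circle).
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .cccnet import CCCNetwork
from .corrnet import CorrelationNetwork
from .panel import CYTOKINE_CLASSES

CLASS_COLORS = {
    "chemokine": "#2ca02c",
    "innate": "#e377c2",
    "adaptive": "#1f77b4",
    "growth_factor": "#222222",
}


def plot_correlation_network(net: CorrelationNetwork, path,
                             classes: dict[str, str] | None = None) -> None:
    classes = classes or CYTOKINE_CLASSES
    g = net.to_networkx()
    pos = nx.spring_layout(g, seed=0)
    node_colors = [CLASS_COLORS.get(classes.get(n, ""), "#7f7f7f") for n in g]
    fig, ax = plt.subplots(figsize=(8, 8))
    nx.draw_networkx_nodes(g, pos, node_color=node_colors, node_size=280, ax=ax)
    nx.draw_networkx_labels(g, pos, font_size=7, ax=ax)
    for (a, b), r in net.edges.items():
        nx.draw_networkx_edges(
            g, pos, edgelist=[(a, b)],
            edge_color="#d62728" if r > 0 else "#1f77b4",
            width=0.5 + 3.0 * abs(r), ax=ax,
        )
    title = "cytokine correlation network"
    if net.stratum:
        title += f" — {net.stratum[0]}, {net.stratum[1]}"
    ax.set_title(f"{title} (|r| ≥ {net.threshold})")
    ax.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_ccc_heatmaps(net: CCCNetwork, path) -> None:
    data = {
        "target cell density": net.target_density,
        "secretory cell density": net.secretory_density,
        "cell_sd": net.cell_sd,
    }
    fig, axes = plt.subplots(1, 3, figsize=(9, 8), sharey=True)
    for ax, (label, series) in zip(axes, data.items()):
        vals = series.to_numpy()[:, None]
        im = ax.imshow(vals, aspect="auto", cmap="viridis")
        ax.set_xticks([])
        ax.set_title(label, fontsize=8)
        fig.colorbar(im, ax=ax, shrink=0.6)
    axes[0].set_yticks(range(len(net.cells)))
    axes[0].set_yticklabels(net.cells, fontsize=7)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_ccc_diagram(net: CCCNetwork, path, top_edges: int = 60) -> None:
    """Circular communication diagram; only the ``top_edges`` strongest
    edges are drawn to keep dense networks readable."""
    n = len(net.cells)
    angles = 2 * np.pi * np.arange(n) / max(n, 1)
    pos = {c: (np.cos(a), np.sin(a)) for c, a in zip(net.cells, angles)}
    flat = net.E.stack()
    flat = flat[flat != 0]
    strongest = flat.abs().sort_values(ascending=False).head(top_edges).index
    scale = flat.abs().max() or 1.0
    fig, ax = plt.subplots(figsize=(9, 9))
    for s, t in strongest:
        w = net.E.at[s, t]
        x0, y0 = pos[s]
        x1, y1 = pos[t]
        ax.annotate(
            "", xy=(x1, y1), xytext=(x0, y0),
            arrowprops=dict(
                arrowstyle="-|>", lw=0.3 + 3.0 * abs(w) / scale,
                color="#d62728" if w > 0 else "#1f77b4", alpha=0.7,
                shrinkA=12, shrinkB=12,
            ),
        )
    for c, (x, y) in pos.items():
        ax.plot(x, y, "o", color="#444444", ms=6)
        ax.annotate(c, (1.08 * x, 1.08 * y), fontsize=6,
                    ha="center", va="center")
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.set_title(f"cell-cell communication (network_sd = {net.network_sd:.2f})")
    ax.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
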