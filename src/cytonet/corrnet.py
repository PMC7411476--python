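"""Thresholded Pearson correlation networks on cytokines.

A per-stratum network is built in three steps: (1) the full Pearson
correlation matrix over animals in the stratum; (2) a hard magnitude
filter keeping pairs with |r| in [threshold, 1] (threshold 0.8 by
default, boundary included); (3) node-importance metrics on the
retained graph.

Three node metrics rank cytokines:

* **degree** — number of retained edges at the node (descending);
* **strength** — sum of |r| over retained incident edges (descending);
* **clustering** — unweighted local clustering coefficient
  2T_v / (k_v (k_v - 1)) (ASCENDING: a node whose neighbours are
  sparsely interconnected is treated as a hub bridging otherwise
  unconnected cytokines, hence *low* clustering marks importance.
  This direction is deliberate and counter-intuitive; see the methods
  note).

Cytokines in the top three positions of at least two rankings are the
network-track key cytokines.  Ties at the rank-3 boundary extend the
top-3 set inclusively and are logged.

``network_str`` (the sum of |r| over retained edges, each unordered
pair once) summarises the overall correlation intensity of a stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .panel import PanelTable

__all__ = [
    "CorrelationNetwork",
    "KeyCytokineScreen",
    "build_network",
    "correlation_matrix",
    "network_str",
    "node_metrics",
    "screen_key_cytokines",
    "write_edge_list",
    "write_graphml",
]


class InsufficientDataError(ValueError):
    """Fewer than 3 animals in the stratum; correlation is undefined."""


@dataclass
class CorrelationNetwork:
    """Undirected signed weighted graph on cytokines after the |r| filter.

    ``edges`` maps unordered pairs (stored as sorted-by-node-order
    tuples) to the signed Pearson r.  Isolated cytokines stay in
    ``nodes`` with degree 0.
    """

    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], float]
    threshold: float
    stratum: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        order = {n: i for i, n in enumerate(self.nodes)}
        fixed: dict[tuple[str, str], float] = {}
        for (a, b), r in self.edges.items():
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if a not in order or b not in order:
                raise ValueError(f"edge ({a}, {b}) references unknown node")
            key = (a, b) if order[a] < order[b] else (b, a)
            if key in fixed and fixed[key] != r:
                raise ValueError(f"conflicting duplicate edge {key}")
            if not (self.threshold <= abs(r) <= 1.0):
                raise ValueError(
                    f"edge {key} has |r| = {abs(r):.4f} outside "
                    f"[{self.threshold}, 1]"
                )
            fixed[key] = float(r)
        self.edges = fixed

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), r in self.edges.items():
            g.add_edge(a, b, r=r, weight=abs(r))
        return g


def correlation_matrix(stratum_panel: PanelTable) -> pd.DataFrame:
    """Pearson correlation matrix over a stratum's animals.

    Symmetric with unit diagonal.  Pairs involving a zero-variance
    cytokine are NaN (undefined) — they are *excluded* downstream, not
    treated as zero correlation.
    """
    if stratum_panel.n_animals < 3:
        raise InsufficientDataError(
            f"stratum has {stratum_panel.n_animals} < 3 animals"
        )
    corr = stratum_panel.values.corr(method="pearson")
    sd = stratum_panel.values.std(ddof=1)
    constant = sd == 0
    corr.loc[constant, :] = np.nan
    corr.loc[:, constant] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    return corr


def build_network(
    matrix: pd.DataFrame,
    threshold: float = 0.8,
    stratum: tuple[str, str] | None = None,
) -> CorrelationNetwork:
    """Apply the closed-boundary magnitude filter |r| >= threshold."""
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    nodes = tuple(matrix.columns)
    vals = matrix.to_numpy()
    edges: dict[tuple[str, str], float] = {}
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            r = vals[i, j]
            if np.isfinite(r) and abs(r) >= threshold:
                edges[(nodes[i], nodes[j])] = float(np.clip(r, -1.0, 1.0))
    return CorrelationNetwork(nodes=nodes, edges=edges,
                              threshold=threshold, stratum=stratum)


def network_str(net: CorrelationNetwork) -> float:
    """Overall correlation intensity: sum of |r| over retained edges."""
    return float(sum(abs(r) for r in net.edges.values()))


def node_metrics(net: CorrelationNetwork) -> pd.DataFrame:
    """Degree, strength and local clustering per cytokine.

    Clustering is computed on the unweighted thresholded graph (edge
    presence only); nodes of degree < 2 have clustering 0.
    """
    g = net.to_networkx()
    degree = dict(g.degree())
    strength = {n: 0.0 for n in net.nodes}
    for (a, b), r in net.edges.items():
        strength[a] += abs(r)
        strength[b] += abs(r)
    clustering = nx.clustering(g)  # unweighted; degree<2 -> 0.0
    return pd.DataFrame(
        {
            "degree": pd.Series(degree, dtype=int),
            "strength": pd.Series(strength, dtype=float),
            "clustering": pd.Series(clustering, dtype=float),
        }
    ).loc[list(net.nodes)]


@dataclass
class KeyCytokineScreen:
    """Outcome of the top-3-by-two-or-more-rankings key rule."""

    rankings: dict[str, list[str]]
    top3: dict[str, set[str]] = field(default_factory=dict)
    key_set: set[str] = field(default_factory=set)
    tie_log: list[str] = field(default_factory=list)


_RANK_DIRECTIONS = {"degree": "desc", "strength": "desc", "clustering": "asc"}


def _top3_tie_extended(series: pd.Series, direction: str,
                       tie_log: list[str], method: str) -> tuple[list[str], set[str]]:
    asc = direction == "asc"
    ordered = series.sort_values(ascending=asc, kind="stable")
    ranking = list(ordered.index)
    if len(ordered) <= 3:
        return ranking, set(ranking)
    cutoff = ordered.iloc[2]
    if asc:
        chosen = set(ordered.index[ordered <= cutoff])
    else:
        chosen = set(ordered.index[ordered >= cutoff])
    if len(chosen) > 3:
        tie_log.append(
            f"{method}: {len(chosen)} nodes tie into the top-3 at value "
            f"{cutoff:g}: {sorted(chosen)}"
        )
    return ranking, chosen


def screen_key_cytokines(metrics: pd.DataFrame) -> KeyCytokineScreen:
    """Apply the three rankings and the >= 2-of-3 top-3 key rule.

    Degree-0 nodes carry no association evidence and are excluded from
    every ranking.  With fewer than 3 ranked nodes, all ranked nodes
    are returned as candidates and a warning is logged.
    """
    ranked = metrics[metrics["degree"] > 0]
    screen = KeyCytokineScreen(rankings={})
    if ranked.empty:
        screen.tie_log.append("no connected nodes; empty screen")
        return screen
    for method, direction in _RANK_DIRECTIONS.items():
        ranking, top = _top3_tie_extended(
            ranked[method], direction, screen.tie_log, method
        )
        screen.rankings[method] = ranking
        screen.top3[method] = top
    if len(ranked) < 3:
        screen.tie_log.append(
            f"only {len(ranked)} connected nodes; all reported as candidates"
        )
        screen.key_set = set(ranked.index)
        return screen
    counts: dict[str, int] = {}
    for top in screen.top3.values():
        for n in top:
            counts[n] = counts.get(n, 0) + 1
    screen.key_set = {n for n, c in counts.items() if c >= 2}
    return screen


# ---------------------------------------------------------------------------
# export

def write_edge_list(net: CorrelationNetwork, path) -> None:
    rows = [(a, b, r) for (a, b), r in net.edges.items()]
    pd.DataFrame(rows, columns=["cytokine_a", "cytokine_b", "r"]).to_csv(
        path, index=False
    )


def write_graphml(net: CorrelationNetwork, path) -> None:
    nx.write_graphml(net.to_networkx(), path)
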