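"""Correlation-network track: oracles, filter semantics, key rule."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytonet.panel import PanelTable
from cytonet.corrnet import (
    CorrelationNetwork,
    InsufficientDataError,
    build_network,
    correlation_matrix,
    network_str,
    node_metrics,
    screen_key_cytokines,
)
from conftest import brute_force_pearson


def panel_from_matrix(arr, names=None):
    arr = np.asarray(arr, float)
    names = names or [f"c{j}" for j in range(arr.shape[1])]
    idx = pd.Index([f"a{i}" for i in range(arr.shape[0])], name="animal_id")
    return PanelTable(
        values=pd.DataFrame(arr, index=idx, columns=names),
        groups=pd.Series(["g"] * len(idx), index=idx),
        timepoints=pd.Series(["t"] * len(idx), index=idx),
    )


def net_from_edges(nodes, edges, threshold=0.8):
    return CorrelationNetwork(nodes=tuple(nodes), edges=dict(edges),
                              threshold=threshold)


# ---------------------------------------------------------------------------
# correlation matrix

class TestCorrelationMatrix:
    def test_exact_linear_dependence(self, tiny_panel):
        m = correlation_matrix(tiny_panel)
        assert m.loc["A", "B"] == pytest.approx(1.0)
        assert m.loc["A", "C"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T)

    def test_matches_textbook_formula_on_random_tables(self):
        rng = np.random.default_rng(0)
        panel = panel_from_matrix(rng.lognormal(0, 0.5, size=(7, 24)))
        m = correlation_matrix(panel)
        vals = panel.values.to_numpy()
        for i in range(24):
            for j in range(i + 1, 24):
                expect = brute_force_pearson(vals[:, i], vals[:, j])
                assert m.iat[i, j] == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_cytokine_is_undefined_not_zero(self):
        panel = panel_from_matrix(
            [[1, 5.0], [2, 5.0], [3, 5.0], [4, 5.0]], names=["A", "K"]
        )
        m = correlation_matrix(panel)
        assert np.isnan(m.loc["A", "K"])
        assert m.loc["K", "K"] == 1.0
        net = build_network(m, threshold=0.8)
        assert not net.edges  # undefined pair is excluded, never an edge

    def test_fewer_than_three_animals_rejected(self):
        with pytest.raises(InsufficientDataError):
            correlation_matrix(panel_from_matrix([[1, 2], [3, 4]]))


# ---------------------------------------------------------------------------
# thresholding

class TestBuildNetwork:
    def make_matrix(self, r):
        return pd.DataFrame([[1.0, r], [r, 1.0]], index=["A", "B"],
                            columns=["A", "B"])

    def test_boundary_value_is_kept(self):
        net = build_network(self.make_matrix(0.80), threshold=0.8)
        assert net.edges == {("A", "B"): 0.80}

    def test_below_threshold_dropped(self):
        net = build_network(self.make_matrix(0.79), threshold=0.8)
        assert not net.edges
        assert net.nodes == ("A", "B")  # isolated nodes retained

    def test_negative_boundary_kept(self):
        net = build_network(self.make_matrix(-0.8), threshold=0.8)
        assert net.edges == {("A", "B"): -0.8}

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_threshold_domain(self, bad):
        with pytest.raises(ValueError):
            build_network(self.make_matrix(0.9), threshold=bad)

    def test_independent_large_n_stratum_is_nearly_empty(self):
        rng = np.random.default_rng(42)
        panel = panel_from_matrix(rng.lognormal(0, 0.3, size=(200, 24)))
        net = build_network(correlation_matrix(panel))
        assert len(net.edges) == 0

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(7)
        panel = panel_from_matrix(rng.lognormal(0, 0.3, size=(6, 12)))
        m = correlation_matrix(panel)
        prev_edges, prev_str = None, None
        for thr in (0.5, 0.6, 0.7, 0.8, 0.9, 0.99):
            net = build_network(m, threshold=thr)
            if prev_edges is not None:
                assert set(net.edges) <= prev_edges
                assert network_str(net) <= prev_str + 1e-12
            prev_edges, prev_str = set(net.edges), network_str(net)


# ---------------------------------------------------------------------------
# network_str and node metrics

def test_network_str_is_sum_of_absolute_weights():
    net = net_from_edges("ABC", {("A", "B"): 0.9, ("B", "C"): -0.85})
    assert network_str(net) == pytest.approx(1.75)
    empty = net_from_edges("ABC", {})
    assert network_str(empty) == 0.0


def test_triangle_metrics():
    net = net_from_edges("ABC", {("A", "B"): 0.9, ("B", "C"): 0.9,
                                 ("A", "C"): -0.9})
    m = node_metrics(net)
    assert (m["degree"] == 2).all()
    assert np.allclose(m["strength"], 1.8)
    assert np.allclose(m["clustering"], 1.0)


def test_star_has_no_clustering():
    net = net_from_edges("CXYZ", {("C", "X"): 0.9, ("C", "Y"): 0.9,
                                  ("C", "Z"): 0.9})
    m = node_metrics(net)
    assert m.loc["C", "degree"] == 3
    assert m.loc["C", "clustering"] == 0.0
    assert (m.loc[["X", "Y", "Z"], "degree"] == 1).all()
    assert (m.loc[["X", "Y", "Z"], "clustering"] == 0.0).all()


def adjacency_oracle(net):
    """Independent node metrics from the adjacency matrix: degree = row
    sums, strength = |R| row sums, triangles from diag(A^3)."""
    n = len(net.nodes)
    pos = {c: i for i, c in enumerate(net.nodes)}
    a = np.zeros((n, n))
    w = np.zeros((n, n))
    for (x, y), r in net.edges.items():
        i, j = pos[x], pos[y]
        a[i, j] = a[j, i] = 1.0
        w[i, j] = w[j, i] = abs(r)
    degree = a.sum(axis=1)
    strength = w.sum(axis=1)
    tri = np.diag(np.linalg.matrix_power(a, 3)) / 2.0
    clustering = np.zeros(n)
    for i in range(n):
        k = degree[i]
        if k >= 2:
            clustering[i] = 2.0 * tri[i] / (k * (k - 1))
    return degree, strength, clustering


def test_metrics_match_adjacency_oracle_on_random_graphs():
    rng = np.random.default_rng(5)
    names = [f"c{j}" for j in range(24)]
    for _ in range(25):
        edges = {}
        for i in range(24):
            for j in range(i + 1, 24):
                if rng.random() < 0.12:
                    sign = 1 if rng.random() < 0.5 else -1
                    edges[(names[i], names[j])] = sign * rng.uniform(0.8, 1.0)
        net = net_from_edges(names, edges)
        m = node_metrics(net)
        deg, stren, clus = adjacency_oracle(net)
        np.testing.assert_allclose(m["degree"].to_numpy(float), deg)
        np.testing.assert_allclose(m["strength"].to_numpy(), stren, atol=1e-12)
        np.testing.assert_allclose(m["clustering"].to_numpy(), clus, atol=1e-12)


def test_clustering_matches_oracle_on_all_small_graphs():
    """Every non-isomorphic graph on <= 7 nodes (networkx atlas)."""
    from networkx.generators.atlas import graph_atlas_g

    for g in graph_atlas_g()[1:]:
        names = [str(v) for v in g.nodes]
        edges = {(str(a), str(b)): 0.9 for a, b in g.edges}
        net = net_from_edges(names, edges)
        m = node_metrics(net)
        deg, _, clus = adjacency_oracle(net)
        np.testing.assert_allclose(m["degree"].to_numpy(float), deg)
        np.testing.assert_allclose(m["clustering"].to_numpy(), clus, atol=1e-12)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.data())
def test_strength_and_degree_conservation(data):
    """sum(strength) = 2 * network_str and sum(degree) = 2 |edges|."""
    n = data.draw(st.integers(2, 12))
    names = [f"c{j}" for j in range(n)]
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if data.draw(st.booleans()):
                r = data.draw(st.floats(0.8, 1.0)) * (
                    -1 if data.draw(st.booleans()) else 1
                )
                edges[(names[i], names[j])] = r
    net = net_from_edges(names, edges)
    m = node_metrics(net)
    assert m["strength"].sum() == pytest.approx(2 * network_str(net), abs=1e-9)
    assert m["degree"].sum() == 2 * len(net.edges)


# ---------------------------------------------------------------------------
# key rule

def metrics_frame(rows):
    return pd.DataFrame(rows, columns=["degree", "strength", "clustering"])


def test_two_method_rule_selects_and_excludes():
    m = pd.DataFrame(
        {
            "degree": [5, 4, 3, 2, 1, 1],
            "strength": [4.5, 3.9, 1.0, 2.2, 0.9, 0.8],
            "clustering": [0.9, 0.8, 0.1, 0.2, 0.0, 0.3],
        },
        index=list("XYZUVW"),
    )
    screen = screen_key_cytokines(m)
    # X: top-3 by degree and strength -> key
    assert "X" in screen.key_set
    # top-3 sets: degree {X,Y,Z}, strength {X,Y,U}, clustering-asc {V,Z,U}
    assert screen.key_set == {"X", "Y", "Z", "U"}
    # V: top-3 only by clustering (0.0) -> not key
    assert "V" not in screen.key_set
    assert screen.rankings["clustering"][0] == "V"  # ascending


def test_clustering_ranks_ascending():
    m = pd.DataFrame(
        {"degree": [2, 2, 2, 2], "strength": [1.8, 1.7, 1.6, 1.5],
         "clustering": [1.0, 0.5, 0.0, 0.2]},
        index=list("ABCD"),
    )
    screen = screen_key_cytokines(m)
    assert screen.rankings["clustering"] == ["C", "D", "B", "A"]


def test_rank3_ties_extend_inclusively_and_log():
    m = pd.DataFrame(
        {"degree": [4, 3, 2, 2, 2, 1], "strength": [4, 3, 2, 1.9, 1.8, 1],
         "clustering": [0, 0, 0, 0, 0, 0]},
        index=list("ABCDEF"),
    )
    screen = screen_key_cytokines(m)
    assert screen.top3["degree"] == {"A", "B", "C", "D", "E"}
    assert any("degree" in line for line in screen.tie_log)


def test_degree_zero_nodes_never_ranked():
    m = pd.DataFrame(
        {"degree": [3, 2, 2, 0], "strength": [2.7, 1.8, 1.7, 0.0],
         "clustering": [0.5, 0.0, 0.0, 0.0]},
        index=list("ABCD"),
    )
    screen = screen_key_cytokines(m)
    for ranking in screen.rankings.values():
        assert "D" not in ranking


def test_fewer_than_three_connected_nodes_all_candidates():
    m = pd.DataFrame(
        {"degree": [1, 1, 0], "strength": [0.9, 0.9, 0.0],
         "clustering": [0.0, 0.0, 0.0]},
        index=list("ABC"),
    )
    screen = screen_key_cytokines(m)
    assert screen.key_set == {"A", "B"}
    assert any("candidates" in line for line in screen.tie_log)


def test_planted_block_is_recovered_as_top_degree_nodes():
    from cytonet.simulate import SimConfig, simulate_panel

    block = ("MCP-1", "CXCL1", "IL-6")
    cfg = SimConfig(n_per_stratum=50, corr_blocks=((block, 0.9),),
                    groups=("control",), timepoints=("day1",), seed=13)
    stratum = simulate_panel(cfg).stratify("control", "day1")
    net = build_network(correlation_matrix(stratum))
    m = node_metrics(net)
    ranked = set(m[m["degree"] > 0].index)
    assert ranked == set(block)
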