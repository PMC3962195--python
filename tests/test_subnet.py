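from itertools import combinations

import numpy as np
import pytest

from netgba.graph_core import InteractionGraph, induced_subgraph
from netgba.subnet import (
    build_direct_network,
    build_sp_network,
    compact_sp_network,
    connect_components,
)

from oracles import sp_network_oracle


def graph_from_pairs(pairs, itype="regulation"):
    g = InteractionGraph()
    for a, b in pairs:
        g.add_edge(a, b, itype)
    return g


def random_interactome(rng, n_nodes=300, n_edges=900):
    g = InteractionGraph()
    syms = [f"N{i:03d}" for i in range(n_nodes)]
    for s in syms:
        g.add_node(s)
    while g.simple_view().number_of_edges() < n_edges:
        a, b = rng.choice(syms, size=2, replace=False)
        g.add_edge(a, b, "regulation")
    return g


def adjacency(graph):
    view = graph.simple_view()
    return {n: set(view.neighbors(n)) for n in view.nodes}


class TestDirectNetwork:
    def test_non_adjacent_seeds_give_empty_network(self):
        g = graph_from_pairs([("A", "X"), ("B", "Y")])
        res = build_direct_network(g, ["A", "B"])
        assert res.graph.n_nodes() == 0
        assert res.stats["n_connected_seeds"] == 0

    def test_triangle_average_degree(self):
        g = graph_from_pairs([("A", "B"), ("B", "C"), ("A", "C")])
        res = build_direct_network(g, ["A", "B", "C"])
        assert res.graph.n_nodes() == 3
        assert res.stats["average_degree"] == pytest.approx(2.0)

    def test_matches_induced_subgraph_oracle(self):
        rng = np.random.default_rng(8)
        g = random_interactome(rng, 100, 250)
        seeds = list(rng.choice(g.nodes(), size=40, replace=False))
        res = build_direct_network(g, seeds)
        oracle = induced_subgraph(g, seeds)
        keep = {n for n in oracle.nodes() if oracle.degree(n) > 0}
        oracle2 = induced_subgraph(oracle, keep)
        assert res.graph == oracle2

    def test_no_seed_in_interactome(self):
        g = graph_from_pairs([("A", "B")])
        with pytest.raises(ValueError, match="no seed"):
            build_direct_network(g, ["ZZZ"])


class TestSpNetwork:
    def test_mutually_adjacent_seeds_no_connectors(self):
        g = graph_from_pairs([("A", "B"), ("B", "C"), ("A", "C"), ("A", "X")])
        res = build_sp_network(g, ["A", "B", "C"], max_len=2)
        assert res.connector_nodes == frozenset()
        di = build_direct_network(g, ["A", "B", "C"])
        assert res.graph == di.graph

    def test_single_intermediate_connector(self):
        g = graph_from_pairs([("A", "X"), ("X", "B")])
        res = build_sp_network(g, ["A", "B"], max_len=2)
        assert res.connector_nodes == {"X"}
        assert res.graph.n_nodes() == 3 and res.graph.n_edges() == 2

    def test_pair_beyond_max_len_contributes_nothing(self):
        g = graph_from_pairs([("A", "X"), ("X", "Y"), ("Y", "B")])
        res = build_sp_network(g, ["A", "B"], max_len=2)
        assert res.graph.n_nodes() == 0

    def test_equals_bfs_all_geodesics_oracle(self):
        rng = np.random.default_rng(9)
        g = random_interactome(rng, 300, 900)
        seeds = sorted(rng.choice(g.nodes(), size=30, replace=False))
        res = build_sp_network(g, seeds, max_len=2)
        nodes, edges = sp_network_oracle(adjacency(g), seeds, 2)
        assert set(res.graph.nodes()) == nodes
        got_edges = {
            (min(e.source, e.target), max(e.source, e.target))
            for e in res.graph.edges()
        }
        assert got_edges == edges

    @pytest.mark.parametrize("max_len", [2, 3])
    def test_small_graphs_equal_brute_force(self, max_len):
        rng = np.random.default_rng(10)
        for _ in range(50):
            n = int(rng.integers(4, 9))
            g = InteractionGraph()
            syms = [f"N{i}" for i in range(n)]
            for s in syms:
                g.add_node(s)
            for a, b in combinations(syms, 2):
                if rng.random() < 0.35:
                    g.add_edge(a, b, "binding")
            seeds = [s for s in syms if rng.random() < 0.5][:4]
            if len(seeds) < 2:
                continue
            res = build_sp_network(g, seeds, max_len=max_len)
            nodes, edges = sp_network_oracle(adjacency(g), seeds, max_len)
            assert set(res.graph.nodes()) == nodes

    def test_supergraph_of_direct_network(self):
        rng = np.random.default_rng(11)
        g = random_interactome(rng, 150, 400)
        seeds = sorted(rng.choice(g.nodes(), size=25, replace=False))
        sp = build_sp_network(g, seeds, max_len=2)
        di = build_direct_network(g, seeds)
        di_edges = set(map(str, di.graph.edges()))
        sp_edges = set(map(str, sp.graph.edges()))
        assert di_edges <= sp_edges

    def test_connectors_lie_on_short_geodesics(self):
        rng = np.random.default_rng(12)
        g = random_interactome(rng, 200, 500)
        seeds = sorted(rng.choice(g.nodes(), size=20, replace=False))
        res = build_sp_network(g, seeds, max_len=2)
        adj = adjacency(g)
        nodes, _ = sp_network_oracle(adj, seeds, 2)
        assert res.connector_nodes <= nodes


class TestCompactSpNetwork:
    def test_zero_cutoff_equals_sp_network(self):
        rng = np.random.default_rng(13)
        g = random_interactome(rng, 100, 300)
        seeds = sorted(rng.choice(g.nodes(), size=15, replace=False))
        compact = compact_sp_network(g, seeds, min_global_degree=0, max_len=2)
        sp = build_sp_network(g, seeds, max_len=2)
        assert set(compact.graph.nodes()) >= set(sp.graph.nodes())
        assert compact.seed_nodes == sp.seed_nodes

    def test_low_degree_seed_filtered_out(self):
        pairs = [("HUB", f"X{i}") for i in range(10)]
        pairs += [("LOW", "HUB"), ("S2", "HUB"), ("S2", "X0"), ("S2", "X1"), ("S2", "X2")]
        g = graph_from_pairs(pairs)
        res = compact_sp_network(g, ["HUB", "S2", "LOW"], min_global_degree=3)
        assert "LOW" not in res.graph.nodes()
        assert "LOW" not in res.seed_nodes

    def test_retained_seeds_equal_degree_filter(self):
        rng = np.random.default_rng(14)
        g = random_interactome(rng, 300, 900)
        seeds = sorted(rng.choice(g.nodes(), size=40, replace=False))
        cutoff = 10
        res = compact_sp_network(g, seeds, min_global_degree=cutoff, max_len=2)
        expected = {s for s in seeds if g.degree(s) >= cutoff}
        assert res.stats["n_seeds_retained"] == len(expected)
        assert res.seed_nodes <= expected

    def test_raising_cutoff_never_adds_seeds(self):
        rng = np.random.default_rng(15)
        g = random_interactome(rng, 200, 700)
        seeds = sorted(rng.choice(g.nodes(), size=30, replace=False))
        prev = None
        for cutoff in (0, 5, 8):
            n = compact_sp_network(g, seeds, cutoff, max_len=2).stats["n_seeds_retained"]
            if prev is not None:
                assert n <= prev
            prev = n

    def test_too_strict_filter_errors(self):
        g = graph_from_pairs([("A", "B"), ("B", "C")])
        with pytest.raises(ValueError, match="seeds have"):
            compact_sp_network(g, ["A", "C"], min_global_degree=100)


class TestConnectComponents:
    def test_already_connected_unchanged(self):
        g = graph_from_pairs([("A", "B"), ("B", "C")])
        res = build_sp_network(g, ["A", "C"], max_len=2)
        out = connect_components(res, g)
        assert out.graph == res.graph
        assert out.generic_nodes == frozenset()

    def test_hub_adjacent_to_both_components_added(self):
        pairs = [("A1", "A2"), ("B1", "B2"), ("H", "A1"), ("H", "B1")]
        g = graph_from_pairs(pairs)
        sub = build_direct_network(g, ["A1", "A2", "B1", "B2"])
        out = connect_components(sub, g)
        assert out.generic_nodes == {"H"}
        import networkx as nx

        assert nx.is_connected(out.graph.simple_view())

    def test_four_components_greedy_matches_exhaustive_small_search(self):
        # 4 seed pairs; M1 joins components 1+2, M2 joins 3+4, SUPER joins all
        pairs = []
        for i in range(1, 5):
            pairs.append((f"A{i}", f"B{i}"))
        pairs += [("M1", "A1"), ("M1", "A2"), ("M2", "A3"), ("M2", "A4")]
        pairs += [(f"SUPER", f"B{i}") for i in range(1, 5)]
        g = graph_from_pairs(pairs)
        seeds = [f"A{i}" for i in range(1, 5)] + [f"B{i}" for i in range(1, 5)]
        sub = build_direct_network(g, seeds)
        out = connect_components(sub, g)
        # exhaustive search: a single node (SUPER) suffices
        assert out.generic_nodes == {"SUPER"}

    def test_unmergeable_components_left_alone(self):
        g = graph_from_pairs([("A1", "A2"), ("B1", "B2")])
        sub = build_direct_network(g, ["A1", "A2", "B1", "B2"])
        out = connect_components(sub, g)
        assert out.generic_nodes == frozenset()
        import networkx as nx

        assert nx.number_connected_components(out.graph.simple_view()) == 2
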