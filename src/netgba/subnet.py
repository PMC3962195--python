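"""Direct-interaction, shortest-path and compact shortest-path subnetworks.

Given a seed-gene list and an interactome, three nested constructions:

* **direct-interaction (DI) network** — the subgraph induced on the seeds
  (isolated seeds removed);
* **shortest-path (SP) network** — seeds plus every node and edge lying on
  *any* geodesic of length <= ``max_len`` between a seed pair ("connector"
  nodes);
* **compact SP network** — seeds are first filtered by their global
  neighbourhood size in the interactome (well-connected seeds have a better
  chance of reaching known disease genes), then the SP network is built and
  any remaining components are stitched together with a minimal greedy set
  of "generic" nodes.

All distances are computed on the undirected, type-filtered simple view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import networkx as nx

from netgba.graph_core import InteractionGraph, _check_types, induced_subgraph
from netgba.seedsel import SeedSet

logger = logging.getLogger(__name__)


@dataclass
class SubnetResult:
    """A constructed subnetwork with node roles and summary statistics.

    Node roles are disjoint and cover the graph: ``seed`` (from the input
    list), ``connector`` (added on seed-seed geodesics), ``generic`` (added
    to restore connectivity).
    """

    graph: InteractionGraph
    seed_nodes: frozenset[str]
    connector_nodes: frozenset[str] = frozenset()
    generic_nodes: frozenset[str] = frozenset()
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        nodes = set(self.graph.nodes())
        assert self.seed_nodes | self.connector_nodes | self.generic_nodes == nodes
        assert not (self.seed_nodes & self.connector_nodes)
        assert not (self.seed_nodes & self.generic_nodes)
        assert not (self.connector_nodes & self.generic_nodes)

    def role(self, symbol: str) -> str:
        if symbol in self.seed_nodes:
            return "seed"
        if symbol in self.connector_nodes:
            return "connector"
        return "generic"

    def roles(self) -> dict[str, str]:
        return {s: self.role(s) for s in self.graph.nodes()}


def _average_degree(graph: InteractionGraph) -> float:
    g = graph.simple_view()
    n = g.number_of_nodes()
    return 2.0 * g.number_of_edges() / n if n else 0.0


def _seed_symbols(seeds: SeedSet | Iterable[str]) -> frozenset[str]:
    if isinstance(seeds, SeedSet):
        return frozenset(seeds.symbols)
    return frozenset(s.strip().upper() for s in seeds)


def build_direct_network(
    interactome: InteractionGraph,
    seeds: SeedSet | Iterable[str],
    allowed_types: Iterable[str] | None = None,
) -> SubnetResult:
    """Subgraph induced on the seeds; isolated seeds are dropped."""
    seed_syms = _seed_symbols(seeds)
    if not seed_syms:
        raise ValueError("empty seed set")
    present = {s for s in seed_syms if interactome.has_node(s)}
    if not present:
        raise ValueError("no seed gene present in the interactome")
    sub = induced_subgraph(interactome, present, allowed_types)
    isolated = {s for s in sub.nodes() if sub.degree(s) == 0}
    if isolated:
        sub = induced_subgraph(sub, set(sub.nodes()) - isolated, allowed_types)
    n_connected = sum(1 for s in sub.nodes() if sub.degree(s) >= 1)
    result = SubnetResult(
        graph=sub,
        seed_nodes=frozenset(sub.nodes()),
        stats={
            "n_seeds_input": len(seed_syms),
            "n_seeds_in_interactome": len(present),
            "n_connected_seeds": n_connected,
            "average_degree": _average_degree(sub),
        },
    )
    logger.info(
        "DI network: %d/%d seeds connected, average degree %.2f",
        n_connected, len(seed_syms), result.stats["average_degree"],
    )
    return result


def _geodesic_union(
    view: nx.Graph, seed_list: list[str], max_len: int
) -> tuple[set[str], set[tuple[str, str]]]:
    """Nodes and (unordered) edges on all seed-seed geodesics of length <= max_len."""
    seeds_present = [s for s in seed_list if s in view]
    seed_set = set(seeds_present)
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for s in seeds_present:
        dist = nx.single_source_shortest_path_length(view, s, cutoff=max_len)
        pred = nx.predecessor(view, s, cutoff=max_len)
        for t in seeds_present:
            if t <= s or t not in dist:
                continue
            # walk the shortest-path DAG backwards from t to s
            stack = [t]
            seen = {t}
            nodes.add(t)
            while stack:
                u = stack.pop()
                for p in pred.get(u, []):
                    edges.add((min(p, u), max(p, u)))
                    nodes.add(p)
                    if p not in seen:
                        seen.add(p)
                        stack.append(p)
    return nodes, edges


def build_sp_network(
    interactome: InteractionGraph,
    seeds: SeedSet | Iterable[str],
    allowed_types: Iterable[str] | None = None,
    max_len: int = 2,
) -> SubnetResult:
    """Union of all shortest paths (length <= ``max_len``) between seed pairs.

    Non-seed nodes on the retained geodesics become connector nodes.  All
    geodesics per pair are included, so the result is deterministic and
    independent of seed ordering.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    _check_types(allowed_types)
    seed_syms = _seed_symbols(seeds)
    if not seed_syms:
        raise ValueError("empty seed set")
    view = interactome.simple_view(allowed_types)
    nodes, pair_edges = _geodesic_union(view, sorted(seed_syms), max_len)

    sub = induced_subgraph(interactome, nodes, allowed_types)
    # keep only edges on geodesics (induced subgraph may add chords)
    keep = InteractionGraph()
    for s in sorted(nodes):
        n = interactome.node(s)
        keep.add_node(n.symbol, n.node_kind, n.is_tf)
    for e in sub.edges():
        if (min(e.source, e.target), max(e.source, e.target)) in pair_edges:
            keep.add_edge(e.source, e.target, e.itype, e.sign, e.directed)
    connectors = frozenset(nodes - seed_syms)
    seeds_in = frozenset(nodes & seed_syms)
    n_seed = len(seeds_in)
    result = SubnetResult(
        graph=keep,
        seed_nodes=seeds_in,
        connector_nodes=connectors,
        stats={
            "n_seeds_input": len(seed_syms),
            "n_connected_seeds": n_seed,
            "n_connectors": len(connectors),
            "average_degree": _average_degree(keep),
            "connector_to_seed_ratio": len(connectors) / n_seed if n_seed else float("nan"),
            "max_len": max_len,
        },
    )
    logger.info(
        "SP network: %d seeds + %d connectors, average degree %.2f",
        n_seed, len(connectors), result.stats["average_degree"],
    )
    return result


def compact_sp_network(
    interactome: InteractionGraph,
    seeds: SeedSet | Iterable[str],
    min_global_degree: int = 25,
    allowed_types: Iterable[str] | None = None,
    max_len: int = 2,
) -> SubnetResult:
    """SP network restricted to globally well-connected seeds, then reconnected.

    Seeds whose distinct-neighbour count in the *full* interactome falls
    below ``min_global_degree`` are discarded before path construction;
    afterwards :func:`connect_components` adds minimal generic nodes.
    """
    if min_global_degree < 0:
        raise ValueError("min_global_degree must be >= 0")
    seed_syms = _seed_symbols(seeds)
    retained = {
        s for s in seed_syms
        if interactome.has_node(s) and interactome.degree(s) >= min_global_degree
    }
    if len(retained) < 2:
        raise ValueError(
            f"only {len(retained)} of {len(seed_syms)} seeds have >= "
            f"{min_global_degree} interactome neighbors; cannot build a network"
        )
    logger.info(
        "compact SP: %d/%d seeds pass the global-degree filter (>= %d)",
        len(retained), len(seed_syms), min_global_degree,
    )
    sp = build_sp_network(interactome, retained, allowed_types, max_len)
    out = connect_components(sp, interactome, allowed_types)
    out.stats.update(
        {
            "min_global_degree": min_global_degree,
            "n_seeds_input": len(seed_syms),
            "n_seeds_retained": len(retained),
        }
    )
    return out


def connect_components(
    sub: SubnetResult,
    interactome: InteractionGraph,
    allowed_types: Iterable[str] | None = None,
) -> SubnetResult:
    """Greedily merge components by adding single interactome nodes.

    At each step the candidate node adjacent (in the type-filtered
    interactome) to the largest number of current components is added with
    all its edges into the subnetwork; ties break toward higher interactome
    degree, then alphabetically.  Stops when connected or when no single
    node can merge two components (logged as unmergeable).
    """
    allowed = _check_types(allowed_types)
    graph = sub.graph.copy()
    generic = set(sub.generic_nodes)
    full_view = interactome.simple_view(allowed)

    while True:
        comps = list(nx.connected_components(graph.simple_view()))
        if len(comps) <= 1:
            break
        comp_of = {n: i for i, c in enumerate(comps) for n in c}
        best: tuple[int, int, str] | None = None  # (-n_joined, -degree, symbol)
        for cand in full_view.nodes:
            if graph.has_node(cand):
                continue
            joined = {comp_of[nb] for nb in full_view.neighbors(cand) if nb in comp_of}
            if len(joined) < 2:
                continue
            key = (-len(joined), -interactome.degree(cand), cand)
            if best is None or key < best:
                best = key
        if best is None:
            logger.warning(
                "connect_components: %d components cannot be merged by any single node",
                len(comps),
            )
            break
        cand = best[2]
        node = interactome.node(cand)
        graph.add_node(node.symbol, node.node_kind, node.is_tf)
        for e in interactome.edges():
            if e.itype not in allowed:
                continue
            if cand in (e.source, e.target):
                other = e.target if e.source == cand else e.source
                if graph.has_node(other):
                    graph.add_edge(e.source, e.target, e.itype, e.sign, e.directed)
        generic.add(cand)
        logger.info("connect_components: added generic node %s", cand)

    seeds = frozenset(sub.seed_nodes)
    connectors = frozenset(sub.connector_nodes)
    stats = dict(sub.stats)
    stats.update(
        {
            "n_generic": len(generic),
            "average_degree": _average_degree(graph),
            "n_components": nx.number_connected_components(graph.simple_view())
            if graph.n_nodes()
            else 0,
        }
    )
    n_seed = len(seeds)
    stats["connector_to_seed_ratio"] = len(connectors) / n_seed if n_seed else float("nan")
    return SubnetResult(
        graph=graph,
        seed_nodes=seeds,
        connector_nodes=connectors,
        generic_nodes=frozenset(generic),
        stats=stats,
    )


def write_subnet(result: SubnetResult, path) -> None:
    """Edge list with a node-role column pair (seed|connector|generic)."""
    with open(path, "w") as fh:
        fh.write("source\titype\ttarget\tsign\tdirected\tsource_role\ttarget_role\n")
        for e in result.graph.edges():
            fh.write(
                f"{e.source}\t{e.itype}\t{e.target}\t{e.sign}\t{int(e.directed)}"
                f"\t{result.role(e.source)}\t{result.role(e.target)}\n"
            )
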