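"""Typed molecular-interaction graph: data model, edge-list I/O, subgraphs.

The interactome is a network over gene and miRNA symbols with a closed
vocabulary of interaction types (regulation, promoter binding, protein
modification, miRNA regulation, ...).  Parallel edges of different type
between the same pair are kept as distinct typed edges, but a node's degree
and neighbourhood always count *distinct adjacent symbols*: the topology of
the network is its undirected simple view, while direction and sign ride
along as edge attributes for reporting.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

#: Closed vocabulary of interaction types.
INTERACTION_TYPES = frozenset(
    {
        "regulation",
        "direct_regulation",
        "promoter_binding",
        "protein_modification",
        "mirna_regulation",
        "binding",
        "expression",
        "molecular_transport",
    }
)

SIGNS = frozenset({"positive", "negative", "unknown"})

#: Symbols matching this pattern are treated as miRNAs unless declared otherwise.
MIRNA_PATTERN = re.compile(r"^(HSA-)?(MIR-|LET-7)", re.IGNORECASE)


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip whitespace; no alias resolution."""
    s = symbol.strip().upper()
    if not s:
        raise ValueError("empty gene symbol")
    return s


def is_mirna_symbol(symbol: str) -> bool:
    return MIRNA_PATTERN.match(symbol) is not None


@dataclass(frozen=True)
class GeneNode:
    """A node in the interactome: a gene or a miRNA."""

    symbol: str
    node_kind: str = "gene"  # "gene" | "mirna"
    is_tf: bool = False

    def __post_init__(self) -> None:
        if self.node_kind not in ("gene", "mirna"):
            raise ValueError(f"unknown node_kind {self.node_kind!r}")


@dataclass(frozen=True)
class Interaction:
    """A typed, optionally signed/directed edge between two symbols."""

    source: str
    target: str
    itype: str
    sign: str = "unknown"
    directed: bool = False

    def __post_init__(self) -> None:
        if self.itype not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {self.itype!r}")
        if self.sign not in SIGNS:
            raise ValueError(f"unknown sign {self.sign!r}")

    @property
    def pair(self) -> tuple[str, str]:
        """Unordered endpoint pair (sorted)."""
        return tuple(sorted((self.source, self.target)))  # type: ignore[return-value]


class InteractionGraph:
    """Typed interaction network over uppercase gene/miRNA symbols.

    Backed by a :class:`networkx.MultiGraph` keyed by interaction type, so at
    most one edge exists per (unordered pair, itype).  Self-loops are dropped
    on insertion.
    """

    def __init__(self) -> None:
        self._g = nx.MultiGraph()

    # -- construction -------------------------------------------------------

    def add_node(self, symbol: str, node_kind: str | None = None, is_tf: bool = False) -> str:
        sym = normalize_symbol(symbol)
        kind = node_kind or ("mirna" if is_mirna_symbol(sym) else "gene")
        if kind not in ("gene", "mirna"):
            raise ValueError(f"unknown node_kind {kind!r}")
        if sym in self._g:
            # do not silently demote an existing annotation
            if node_kind is not None:
                self._g.nodes[sym]["node_kind"] = kind
            if is_tf:
                self._g.nodes[sym]["is_tf"] = True
        else:
            self._g.add_node(sym, node_kind=kind, is_tf=is_tf)
        return sym

    def add_edge(
        self,
        source: str,
        target: str,
        itype: str,
        sign: str = "unknown",
        directed: bool = False,
    ) -> bool:
        """Add a typed edge; returns False for dropped self-loops."""
        if itype not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {itype!r}")
        if sign not in SIGNS:
            raise ValueError(f"unknown sign {sign!r}")
        u = self.add_node(source)
        v = self.add_node(target)
        if u == v:
            logger.debug("dropping self-loop on %s", u)
            return False
        # one edge per unordered pair and type: MultiGraph key = itype
        self._g.add_edge(u, v, key=itype, sign=sign, directed=directed, source=u if directed else min(u, v))
        if directed:
            # remember orientation explicitly (MultiGraph is undirected)
            self._g.edges[u, v, itype]["source"] = u
            self._g.edges[u, v, itype]["target"] = v
        return True

    # -- inspection ---------------------------------------------------------

    @property
    def nx_multigraph(self) -> nx.MultiGraph:
        return self._g

    def node(self, symbol: str) -> GeneNode:
        d = self._g.nodes[symbol]
        return GeneNode(symbol, d.get("node_kind", "gene"), d.get("is_tf", False))

    def nodes(self) -> list[str]:
        return sorted(self._g.nodes)

    def gene_nodes(self) -> list[GeneNode]:
        return [self.node(s) for s in self.nodes()]

    def edges(self) -> list[Interaction]:
        out = []
        for u, v, itype, d in self._g.edges(keys=True, data=True):
            if d.get("directed"):
                s, t = d["source"], d["target"]
            else:
                s, t = min(u, v), max(u, v)
            out.append(Interaction(s, t, itype, d.get("sign", "unknown"), d.get("directed", False)))
        return sorted(out, key=lambda e: (e.pair, e.itype))

    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    def n_edges(self) -> int:
        """Number of typed edges (parallel types counted separately)."""
        return self._g.number_of_edges()

    def has_node(self, symbol: str) -> bool:
        return symbol in self._g

    def neighbors(self, symbol: str) -> set[str]:
        """Distinct adjacent symbols, regardless of edge type or multiplicity."""
        return set(self._g.neighbors(symbol))

    def degree(self, symbol: str) -> int:
        return len(self.neighbors(symbol))

    def simple_view(self, allowed_types: Iterable[str] | None = None) -> nx.Graph:
        """Undirected simple graph over the same nodes; one edge per adjacent pair.

        ``allowed_types`` restricts which typed edges induce adjacency; the
        node set is preserved either way.
        """
        allowed = _check_types(allowed_types)
        g = nx.Graph()
        g.add_nodes_from(self._g.nodes(data=True))
        for u, v, itype in self._g.edges(keys=True):
            if itype in allowed:
                g.add_edge(u, v)
        return g

    def copy(self) -> "InteractionGraph":
        out = InteractionGraph()
        out._g = self._g.copy()
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionGraph):
            return NotImplemented
        return set(self.nodes()) == set(other.nodes()) and self.edges() == other.edges()

    def __repr__(self) -> str:
        return f"InteractionGraph(n_nodes={self.n_nodes()}, n_edges={self.n_edges()})"


def _check_types(allowed_types: Iterable[str] | None) -> frozenset[str]:
    if allowed_types is None:
        return INTERACTION_TYPES
    allowed = frozenset(allowed_types)
    if not allowed:
        raise ValueError("allowed_types must be nonempty")
    unknown = allowed - INTERACTION_TYPES
    if unknown:
        raise ValueError(f"unknown interaction types: {sorted(unknown)}")
    return allowed


# ---------------------------------------------------------------------------
# edge-list I/O


def _iter_rows(path: Path, dialect: str) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if dialect == "sif":
                fields = line.split()
            else:
                fields = line.split("\t")
            yield lineno, fields


def load_edge_list(
    path: str | Path,
    dialect: str = "tsv",
    on_unknown_itype: str = "reject",
) -> InteractionGraph:
    """Read an interactome edge list.

    SIF dialect: whitespace-separated ``source itype target``.  TSV dialect:
    tab-separated ``source  itype  target  [sign  directed]`` with a header
    row.  Unknown interaction-type strings are either rejected (default) or
    mapped to ``regulation`` (``on_unknown_itype="map"``).
    """
    path = Path(path)
    if dialect not in ("sif", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if on_unknown_itype not in ("reject", "map"):
        raise ValueError("on_unknown_itype must be 'reject' or 'map'")
    graph = InteractionGraph()
    n_rows = n_loops = 0
    first = True
    for lineno, fields in _iter_rows(path, dialect):
        if dialect == "tsv" and first:
            first = False
            if fields[0].lower() in ("source", "#source"):
                continue
        first = False
        nonempty = [f for f in fields if f.strip()]
        if len(nonempty) == 1:
            # bare node row (isolated node)
            graph.add_node(nonempty[0])
            continue
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
        source, itype, target = fields[0], fields[1], fields[2]
        sign = fields[3] if len(fields) > 3 and fields[3] else "unknown"
        directed = len(fields) > 4 and fields[4].strip().lower() in ("1", "true", "yes")
        if itype not in INTERACTION_TYPES:
            if on_unknown_itype == "reject":
                raise ValueError(f"{path}:{lineno}: unknown interaction type {itype!r}")
            logger.warning("%s:%d: mapping unknown itype %r to 'regulation'", path, lineno, itype)
            itype = "regulation"
        n_rows += 1
        if not graph.add_edge(source, target, itype, sign=sign, directed=directed):
            n_loops += 1
            logger.info("%s:%d: dropped self-loop", path, lineno)
    logger.info(
        "loaded %s: %d rows -> %d nodes, %d edges (%d self-loops dropped)",
        path, n_rows, graph.n_nodes(), graph.n_edges(), n_loops,
    )
    return graph


def write_edge_list(graph: InteractionGraph, path: str | Path, dialect: str = "tsv") -> Path:
    """Write a graph as an edge list; round-trips exactly through load_edge_list."""
    path = Path(path)
    if dialect not in ("sif", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    isolated = [s for s in graph.nodes() if graph.degree(s) == 0]
    with open(path, "w") as fh:
        if dialect == "tsv":
            fh.write("source\titype\ttarget\tsign\tdirected\n")
            for e in graph.edges():
                fh.write(f"{e.source}\t{e.itype}\t{e.target}\t{e.sign}\t{int(e.directed)}\n")
        else:
            for e in graph.edges():
                fh.write(f"{e.source} {e.itype} {e.target}\n")
        # isolated nodes serialize as bare-symbol rows
        for s in isolated:
            fh.write(s + "\n")
    return path


def induced_subgraph(
    graph: InteractionGraph,
    keep: Iterable[str],
    allowed_types: Iterable[str] | None = None,
) -> InteractionGraph:
    """Subgraph on ``keep`` with only edges whose type is allowed.

    Symbols absent from the graph are ignored (and logged); the result
    contains exactly the kept-and-present nodes and the allowed edges among
    them.
    """
    allowed = _check_types(allowed_types)
    keep_norm = {normalize_symbol(s) for s in keep}
    missing = keep_norm - set(graph.nx_multigraph.nodes)
    if missing:
        logger.info("induced_subgraph: %d symbols absent from graph", len(missing))
    present = keep_norm - missing
    out = InteractionGraph()
    for s in sorted(present):
        n = graph.node(s)
        out.add_node(n.symbol, n.node_kind, n.is_tf)
    for e in graph.edges():
        if e.itype in allowed and e.source in present and e.target in present:
            out.add_edge(e.source, e.target, e.itype, e.sign, e.directed)
    return out
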