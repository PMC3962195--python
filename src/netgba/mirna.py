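"""miRNA regulatory layer: bipartite miRNA-target map over the seed genes.

Restricts the interactome to miRNA-regulation edges incident to seed genes,
counts regulators per gene and targets per miRNA, and flags transcription
factors co-present in the network (integrated TF/miRNA regulation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from netgba.graph_core import InteractionGraph
from netgba.seedsel import SeedSet

logger = logging.getLogger(__name__)


@dataclass
class MiRNATargetMap:
    """Bipartite adjacency miRNA -> targets, with the reverse map."""

    forward: dict[str, frozenset[str]] = field(default_factory=dict)
    reverse: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # consistency of the two directions
        pairs_f = {(m, g) for m, gs in self.forward.items() for g in gs}
        pairs_r = {(m, g) for g, ms in self.reverse.items() for m in ms}
        assert pairs_f == pairs_r, "forward/reverse maps inconsistent"

    @property
    def n_edges(self) -> int:
        return sum(len(gs) for gs in self.forward.values())


def build_mirna_network(
    interactome: InteractionGraph,
    seeds: SeedSet | Iterable[str],
) -> tuple[InteractionGraph, MiRNATargetMap]:
    """miRNA-regulation edges incident to seed genes, plus their miRNAs.

    The miRNA side of each edge is identified by node kind; a
    miRNA-regulation edge between two gene-kind nodes is a validation error
    (genes never appear on the miRNA side).  With no miRNA edges at all, an
    empty graph/map is returned with a warning.
    """
    seed_syms = frozenset(seeds.symbols) if isinstance(seeds, SeedSet) else frozenset(
        s.strip().upper() for s in seeds
    )
    mirna_edges = [e for e in interactome.edges() if e.itype == "mirna_regulation"]
    if not mirna_edges:
        logger.warning("interactome contains no mirna_regulation edges")
        return InteractionGraph(), MiRNATargetMap()

    graph = InteractionGraph()
    fwd: dict[str, set[str]] = {}
    for e in mirna_edges:
        src_kind = interactome.node(e.source).node_kind
        tgt_kind = interactome.node(e.target).node_kind
        if src_kind == "mirna" and tgt_kind == "gene":
            mirna, gene = e.source, e.target
        elif tgt_kind == "mirna" and src_kind == "gene":
            mirna, gene = e.target, e.source
        else:
            raise ValueError(
                f"mirna_regulation edge {e.source}-{e.target} must join a miRNA "
                f"to a gene (got kinds {src_kind}/{tgt_kind})"
            )
        if gene not in seed_syms:
            continue
        graph.add_node(mirna, "mirna")
        graph.add_node(gene, "gene", is_tf=interactome.node(gene).is_tf)
        graph.add_edge(mirna, gene, "mirna_regulation", e.sign, directed=True)
        fwd.setdefault(mirna, set()).add(gene)

    rev: dict[str, set[str]] = {}
    for m, gs in fwd.items():
        for g in gs:
            rev.setdefault(g, set()).add(m)
    mapping = MiRNATargetMap(
        {m: frozenset(gs) for m, gs in fwd.items()},
        {g: frozenset(ms) for g, ms in rev.items()},
    )
    logger.info(
        "miRNA network: %d miRNAs regulating %d seed genes via %d edges",
        len(mapping.forward), len(mapping.reverse), mapping.n_edges,
    )
    return graph, mapping


def mirnas_per_gene(mapping: MiRNATargetMap) -> pd.DataFrame:
    """Distinct regulating miRNAs per gene, descending, ties alphabetical."""
    rows = sorted(
        ((g, len(ms)) for g, ms in mapping.reverse.items()),
        key=lambda r: (-r[1], r[0]),
    )
    return pd.DataFrame(rows, columns=["gene", "n_mirnas"]).set_index("gene")


def targets_per_mirna(mapping: MiRNATargetMap) -> pd.DataFrame:
    """Distinct target genes per miRNA, descending, ties alphabetical."""
    rows = sorted(
        ((m, len(gs)) for m, gs in mapping.forward.items()),
        key=lambda r: (-r[1], r[0]),
    )
    return pd.DataFrame(rows, columns=["mirna", "n_targets"]).set_index("mirna")


def flag_tf_coregulation(
    graph: InteractionGraph,
    tf_list: Iterable[str],
) -> pd.DataFrame:
    """Flag network genes that encode transcription factors.

    Gene nodes in the miRNA network that appear in ``tf_list`` are under
    integrated TF/miRNA regulation.  Returns a per-node table with columns
    ``node_kind, is_tf``; summary counts go to the log.
    """
    tfs = frozenset(s.strip().upper() for s in tf_list)
    rows = []
    for sym in graph.nodes():
        node = graph.node(sym)
        rows.append((sym, node.node_kind, node.node_kind == "gene" and sym in tfs))
    out = pd.DataFrame(rows, columns=["node", "node_kind", "is_tf"]).set_index("node")
    n_tf = int(out["is_tf"].sum())
    logger.info("TF co-regulation: %d TF genes among %d network genes",
                n_tf, int((out["node_kind"] == "gene").sum()))
    return out
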