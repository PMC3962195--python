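"""Guilt-by-association scoring and four-way candidate classification.

A gene adjacent to many known disease genes in the disease subnetwork is
itself a plausible disease gene.  Each node's score is its number of
distinct first neighbours that belong to the known-disease gene list; nodes
are then classified as known vs of-interest, split by whether they entered
the network as differentially expressed seeds or as connecting proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from netgba.graph_core import InteractionGraph, normalize_symbol
from netgba.seedsel import SeedSet
from netgba.subnet import SubnetResult
from netgba.topology import MEASURES, top_k as _top_k

logger = logging.getLogger(__name__)

CATEGORIES = ("known_sdeg", "known_connector", "interest_sdeg", "interest_connector", "other")


@dataclass(frozen=True)
class KnownGeneSet:
    """Curated list of genes already implicated in the disease."""

    symbols: frozenset[str]
    source: str = ""

    @classmethod
    def from_file(cls, path) -> "KnownGeneSet":
        with open(path) as fh:
            symbols = frozenset(
                normalize_symbol(line) for line in fh if line.strip()
            )
        if not symbols:
            raise ValueError(f"empty known-gene list: {path}")
        return cls(symbols, source=str(path))

    def __len__(self) -> int:
        return len(self.symbols)


def gba_scores(graph: InteractionGraph, known: KnownGeneSet | Iterable[str]) -> pd.DataFrame:
    """Per-node count and identity of known-gene first neighbours.

    A known gene's own membership does not contribute to its score; only
    adjacency counts.  Returns a DataFrame indexed by node with columns
    ``known_neighbor_count`` and ``known_neighbors`` (sorted, comma-joined).
    """
    if graph.n_nodes() == 0:
        raise ValueError("empty graph")
    known_syms = known.symbols if isinstance(known, KnownGeneSet) else frozenset(known)
    rows = []
    for node in graph.nodes():
        hits = sorted(graph.neighbors(node) & known_syms)
        rows.append((node, len(hits), ",".join(hits)))
    return pd.DataFrame(
        rows, columns=["node", "known_neighbor_count", "known_neighbors"]
    ).set_index("node")


def classify_categories(
    table: pd.DataFrame,
    seeds: SeedSet | Iterable[str],
    sub: SubnetResult,
    known: KnownGeneSet | Iterable[str],
    centr: pd.DataFrame | None = None,
    top_k: int = 10,
) -> pd.DataFrame:
    """Assign each subnetwork node to one of five categories.

    known_sdeg / known_connector: members of the known list, split by seed
    membership.  interest_sdeg / interest_connector: non-known nodes with at
    least one known neighbour or a top-k rank on any centrality measure.
    Everything else: other.
    """
    known_syms = known.symbols if isinstance(known, KnownGeneSet) else frozenset(known)
    seed_syms = frozenset(seeds.symbols) if isinstance(seeds, SeedSet) else frozenset(seeds)
    missing = set(sub.graph.nodes()) - set(table.index)
    if missing:
        raise ValueError(f"GBA table missing subnetwork nodes: {sorted(missing)[:5]}...")
    top_ranked: set[str] = set()
    if centr is not None:
        for m in MEASURES:
            top_ranked |= set(_top_k(centr, m, top_k).index)
    out = table.copy()
    cats = []
    for node in out.index:
        in_known = node in known_syms
        in_seeds = node in seed_syms
        if in_known:
            cats.append("known_sdeg" if in_seeds else "known_connector")
        elif out.at[node, "known_neighbor_count"] >= 1 or node in top_ranked:
            cats.append("interest_sdeg" if in_seeds else "interest_connector")
        else:
            cats.append("other")
    out["category"] = pd.Categorical(cats, categories=CATEGORIES)
    return out


def category_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Count of nodes per category (covers every subnetwork node)."""
    counts = table["category"].value_counts().reindex(CATEGORIES, fill_value=0)
    return counts.rename("n_genes").to_frame()


def rank_candidates(table: pd.DataFrame) -> pd.DataFrame:
    """Genes of interest ordered by known-neighbour count, grouped report.

    Returns one row per count level with the alphabetical gene list at that
    level (mirrors the "count -> gene list" presentation of candidate
    tables).
    """
    if "category" in table.columns:
        interest = table[table["category"].astype(str).str.startswith("interest")]
    else:
        interest = table
    interest = interest.sort_index()
    if interest.empty:
        return pd.DataFrame(columns=["known_neighbor_count", "genes"])
    grouped = (
        interest.groupby("known_neighbor_count", sort=False)
        .apply(lambda d: ", ".join(sorted(d.index)), include_groups=False)
        .rename("genes")
        .reset_index()
        .sort_values("known_neighbor_count", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    return grouped
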