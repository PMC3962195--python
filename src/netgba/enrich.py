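"""Hypergeometric gene-set enrichment, BH FDR, and mechanism-network assembly.

For a query of n genes drawn from a background of N, the overlap k with a
set of K members is scored by the hypergeometric upper tail
P[X >= k], fold enrichment (k/n)/(K/N), and Benjamini-Hochberg adjusted
q-values across all tested sets.  The genes of the significantly enriched
sets can then be pooled and wired into a "mechanism network" over the
interactome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from netgba.graph_core import InteractionGraph, induced_subgraph, normalize_symbol
from netgba.subnet import SubnetResult

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """GMT-style collection: term -> (description, member symbols) + background."""

    sets: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        for term, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"empty gene set {term!r}")
            if not members <= self.background:
                raise ValueError(f"set {term!r} has members outside the background")

    def members(self, term: str) -> frozenset[str]:
        return self.sets[term][1]

    def __len__(self) -> int:
        return len(self.sets)


def load_gmt(path, background: Iterable[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file (term<TAB>description<TAB>members...).

    The background defaults to the union of all members.
    """
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT row needs >=3 fields")
            term, desc = fields[0], fields[1]
            members = frozenset(normalize_symbol(s) for s in fields[2:] if s.strip())
            if not members:
                raise ValueError(f"{path}:{lineno}: set {term!r} has no members")
            if term in sets:
                raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
            sets[term] = (desc, members)
    if not sets:
        raise ValueError(f"empty GMT file: {path}")
    if background is None:
        bg = frozenset().union(*(m for _, m in sets.values()))
    else:
        bg = frozenset(normalize_symbol(s) for s in background)
    return GeneSetCollection(sets, bg)


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(coll.sets):
            desc, members = coll.sets[term]
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrichment(
    query: Iterable[str],
    coll: GeneSetCollection,
    min_set_size: int = 3,
    max_set_size: int = 500,
    include_empty_overlap: bool = False,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a query gene list against a collection.

    The query is restricted to the background (logged).  Sets outside
    [min_set_size, max_set_size] are skipped.  Returns rows sorted by q then
    p then term, with columns term, name, k, K, n, N, fold_enrichment, p, q.
    """
    q_raw = {normalize_symbol(s) for s in query}
    q_set = q_raw & coll.background
    if not q_set:
        raise ValueError("query shares no genes with the background")
    if len(q_set) < len(q_raw):
        logger.info(
            "enrichment query restricted to background: %d -> %d genes",
            len(q_raw), len(q_set),
        )
    N = len(coll.background)
    n = len(q_set)
    rows = []
    for term in sorted(coll.sets):
        desc, members = coll.sets[term]
        K = len(members)
        if not min_set_size <= K <= max_set_size:
            continue
        k = len(q_set & members)
        if k == 0 and not include_empty_overlap:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N)
        rows.append((term, desc, k, K, n, N, fold, p))
    if not rows:
        return pd.DataFrame(
            columns=["term", "name", "k", "K", "n", "N", "fold_enrichment", "p", "q"]
        )
    out = pd.DataFrame(
        rows, columns=["term", "name", "k", "K", "n", "N", "fold_enrichment", "p"]
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    out = out.sort_values(["q", "p", "term"], kind="mergesort").reset_index(drop=True)
    return out


def select_enriched_terms(enrichment: pd.DataFrame, fdr: float = 0.05) -> list[str]:
    """Terms with BH q <= fdr."""
    return list(enrichment.loc[enrichment["q"] <= fdr, "term"])


def mechanism_network(
    selected_terms: Sequence[str],
    coll: GeneSetCollection,
    interactome: InteractionGraph,
    allowed_types: Iterable[str] | None = None,
    roles: dict[str, str] | None = None,
) -> tuple[frozenset[str], SubnetResult]:
    """Pool the member genes of the selected sets and wire them up.

    The mechanism gene list is the UNION of members across the selected
    terms; the network is the induced subgraph of that union in the
    interactome.  Node roles from earlier stages can be carried over via
    ``roles`` (symbol -> seed|connector|generic).

    Returns (union gene set, subnetwork result).
    """
    missing = set(selected_terms) - set(coll.sets)
    if missing:
        raise ValueError(f"terms not in collection: {sorted(missing)}")
    union: set[str] = set()
    for term in selected_terms:
        union |= coll.members(term)
    if not union:
        raise ValueError("selected terms have no member genes")
    graph = induced_subgraph(interactome, union, allowed_types)
    present = set(graph.nodes())
    roles = roles or {}
    seeds = frozenset(s for s in present if roles.get(s) == "seed")
    generic = frozenset(s for s in present if roles.get(s) == "generic")
    connectors = frozenset(present - seeds - generic)
    result = SubnetResult(
        graph=graph,
        seed_nodes=seeds,
        connector_nodes=connectors,
        generic_nodes=generic,
        stats={
            "n_terms": len(selected_terms),
            "n_mechanism_genes": len(union),
            "n_in_interactome": len(present),
        },
    )
    logger.info(
        "mechanism network: %d genes pooled from %d sets, %d present in interactome",
        len(union), len(selected_terms), len(present),
    )
    return frozenset(union), result
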