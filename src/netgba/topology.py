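"""Node centralities (degree, closeness, betweenness) and hub reporting.

All measures are computed on the undirected simple view.  Closeness is
component-local: closeness(v) = (n_c - 1) / sum of distances from v within
its component of size n_c (0 for isolated nodes).  Betweenness uses
fractional credit over equal-length geodesics, excludes endpoints, and is
normalized by (n - 1)(n - 2) / 2 within each component.
"""

from __future__ import annotations

import logging
from typing import Iterable

import networkx as nx
import pandas as pd

from netgba.graph_core import InteractionGraph

logger = logging.getLogger(__name__)

MEASURES = ("degree", "closeness", "betweenness")


def centralities(graph: InteractionGraph | nx.Graph) -> pd.DataFrame:
    """Degree, closeness and betweenness per node, plus component id.

    Returns a DataFrame indexed by node symbol.  Component ids are assigned
    in order of each component's alphabetically smallest member.
    """
    g = graph.simple_view() if isinstance(graph, InteractionGraph) else nx.Graph(graph)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    closeness = nx.closeness_centrality(g, wf_improved=False)
    betweenness: dict = {}
    comp_id: dict = {}
    comps = sorted(nx.connected_components(g), key=lambda c: min(c))
    for i, comp in enumerate(comps):
        sub = g.subgraph(comp)
        betweenness.update(
            nx.betweenness_centrality(sub, normalized=True, endpoints=False)
        )
        for n in comp:
            comp_id[n] = i
    nodes = sorted(g.nodes)
    return pd.DataFrame(
        {
            "degree": [g.degree(n) for n in nodes],
            "closeness": [closeness[n] for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
            "component_id": [comp_id[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def top_k(table: pd.DataFrame, measure: str, k: int) -> pd.DataFrame:
    """Top-k nodes by a measure, descending, ties alphabetical.

    Nodes tied with the k-th score are all included and flagged
    ``tied_at_rank_k``.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = table.iloc[
        sorted(
            range(len(table)),
            key=lambda i: (-table[measure].iloc[i], table.index[i]),
        )
    ]
    if k >= len(ordered):
        out = ordered[[measure]].copy()
        out["tied_at_rank_k"] = False
        return out
    cutoff = ordered[measure].iloc[k - 1]
    keep = ordered[ordered[measure] >= cutoff]
    out = keep[[measure]].copy()
    n_above = int((keep[measure] > cutoff).sum())
    tie_group = keep[measure] == cutoff
    # the tie group is flagged when it overflows the remaining k - n_above slots
    out["tied_at_rank_k"] = tie_group & (int(tie_group.sum()) > k - n_above)
    return out


def hubs(table: pd.DataFrame, degree_threshold: int = 15) -> set[str]:
    """Nodes with degree strictly above the threshold."""
    if degree_threshold < 0:
        raise ValueError("degree_threshold must be >= 0")
    return set(table.index[table["degree"] > degree_threshold])


def write_centralities(table: pd.DataFrame, path, roles: dict[str, str] | None = None) -> None:
    out = table.copy()
    out.insert(0, "role", [roles.get(n, "") if roles else "" for n in out.index])
    with open(path, "w") as fh:
        fh.write("# closeness: component-local (n_c-1)/sum(d); "
                 "betweenness: endpoint-free, pair-normalized per component\n")
        out.to_csv(fh, sep="\t")
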