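"""Bundled worked-example fixtures for a Parkinson's-disease
compact shortest-path analysis.

Three small, curated inputs ship with the package:

* the sixteen KEGG pathways (with member genes) found enriched in the
  disease subnetwork — their union is the 46-gene "mechanism" list;
* the reported first-neighbourhoods of CTNNB1 and PAK1 among known
  Parkinson's-disease genes (the guilt-by-association worked example);
* the seven reported miRNA regulators of SEMA6D.
"""

from __future__ import annotations

from importlib import resources

from netgba.enrich import GeneSetCollection, load_gmt
from netgba.gba import KnownGeneSet
from netgba.graph_core import InteractionGraph, load_edge_list


def _data_path(name: str):
    return resources.files("netgba") / "data" / name


def load_enriched_pathways() -> GeneSetCollection:
    """The 16 enriched KEGG pathways with their reported member genes."""
    with resources.as_file(_data_path("pd_enriched_kegg.gmt")) as p:
        return load_gmt(p)


def load_gba_example() -> tuple[InteractionGraph, KnownGeneSet]:
    """CTNNB1/PAK1 neighbourhood fixture plus the known-gene list it uses."""
    with resources.as_file(_data_path("gba_example_edges.tsv")) as p:
        graph = load_edge_list(p, dialect="tsv")
    with resources.as_file(_data_path("gba_example_known.txt")) as p:
        known = KnownGeneSet.from_file(p)
    return graph, known


def load_mirna_example() -> InteractionGraph:
    """The reported miRNA -> SEMA6D regulation edges."""
    with resources.as_file(_data_path("mirna_example_edges.tsv")) as p:
        return load_edge_list(p, dialect="tsv")
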