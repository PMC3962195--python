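"""Seeded generator of complete pipeline fixtures with ground truth.

Emulates the study conditions end to end: a scale-free typed interactome
with a planted, connected disease module enriched for known disease genes;
multi-tissue case/control log2 expression with the differential-expression
effect planted on module genes in every tissue; a bipartite miRNA layer
biased toward the module; and a GMT collection containing one set enriched
for the module.  Everything is deterministic under a fixed ``rng_seed``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from netgba.diffexpr import ExpressionMatrix
from netgba.graph_core import INTERACTION_TYPES, InteractionGraph, write_edge_list

logger = logging.getLogger(__name__)

#: edge types assignable to gene-gene edges (miRNA edges come from the miRNA layer)
_GENE_EDGE_TYPES = sorted(INTERACTION_TYPES - {"mirna_regulation"})


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults define the benchmark conditions."""

    rng_seed: int = 0
    n_genes: int = 2000
    attachment_edges_per_node: int = 3  # preferential-attachment m
    module_size: int = 50
    known_in_module: int = 15
    known_outside_module: int = 10
    module_extra_edges: int = 50        # intra-module edges beyond the spanning tree
    known_links_per_module_gene: int = 2  # GBA signal wiring
    n_tissues: int = 3
    n_case: int = 8
    n_control: int = 8
    effect_size: float = 1.5            # log2 units, planted in all tissues
    noise_sd: float = 0.5
    n_mirna: int = 20
    targets_per_mirna: int = 8
    mirna_module_bias: float = 0.7
    n_tf_genes: int = 4
    n_genesets: int = 30
    geneset_size: int = 40
    planted_set_overlap_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.module_size > self.n_genes:
            raise ValueError("module_size cannot exceed n_genes")
        if self.known_in_module > self.module_size:
            raise ValueError("known_in_module cannot exceed module_size")
        if self.known_outside_module > self.n_genes - self.module_size:
            raise ValueError("known_outside_module exceeds the non-module pool")
        for name in ("n_genes", "n_tissues", "n_case", "n_control", "n_genesets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """What was planted, for recovery tests."""

    module_members: frozenset[str]
    known_genes: frozenset[str]
    tf_genes: frozenset[str] = frozenset()
    planted_geneset_term: str | None = None
    effect_sizes: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "module_members": sorted(self.module_members),
                "known_genes": sorted(self.known_genes),
                "tf_genes": sorted(self.tf_genes),
                "planted_geneset_term": self.planted_geneset_term,
                "effect_sizes": dict(sorted(self.effect_sizes.items())),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            frozenset(d["module_members"]),
            frozenset(d["known_genes"]),
            frozenset(d.get("tf_genes", [])),
            d.get("planted_geneset_term"),
            d.get("effect_sizes", {}),
        )


def _symbols(cfg: SyntheticConfig) -> list[str]:
    width = len(str(cfg.n_genes))
    return [f"G{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]


def _rng(cfg: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, cfg.rng_seed])


def generate_interactome(cfg: SyntheticConfig) -> tuple[InteractionGraph, GroundTruth]:
    """Scale-free gene interactome with a planted, connected disease module.

    The backbone is a preferential-attachment graph.  Module genes get a
    random spanning tree plus extra intra-module edges (mutual enrichment)
    and each non-known module gene is wired to a few known module genes
    (the guilt-by-association signal).  Known genes outside the module are
    sprinkled over the rest of the graph.
    """
    rng = _rng(cfg, 1)
    symbols = _symbols(cfg)
    m = min(cfg.attachment_edges_per_node, cfg.n_genes - 1)
    backbone = nx.barabasi_albert_graph(
        cfg.n_genes, m, seed=int(rng.integers(2**31 - 1))
    )
    # shuffle the node->symbol assignment so the module is not age-biased
    perm = rng.permutation(cfg.n_genes)
    relabel = {i: symbols[perm[i]] for i in range(cfg.n_genes)}

    pairs: set[tuple[str, str]] = set()
    for u, v in backbone.edges():
        a, b = relabel[u], relabel[v]
        pairs.add((min(a, b), max(a, b)))

    module: list[str] = []
    known: set[str] = set()
    tf_genes: set[str] = set()
    if cfg.module_size > 0:
        module = sorted(rng.choice(symbols, size=cfg.module_size, replace=False))
        known = set(rng.choice(module, size=cfg.known_in_module, replace=False))
        outside = sorted(set(symbols) - set(module))
        if cfg.known_outside_module:
            known |= set(rng.choice(outside, size=cfg.known_outside_module, replace=False))
        # spanning tree keeps the module connected
        order = list(rng.permutation(module))
        for i in range(1, len(order)):
            a = order[i]
            b = order[int(rng.integers(i))]
            pairs.add((min(a, b), max(a, b)))
        for _ in range(cfg.module_extra_edges):
            a, b = rng.choice(module, size=2, replace=False)
            pairs.add((min(a, b), max(a, b)))
        known_mod = sorted(known & set(module))
        if known_mod:
            for g in module:
                if g in known:
                    continue
                k = min(cfg.known_links_per_module_gene, len(known_mod))
                for h in rng.choice(known_mod, size=k, replace=False):
                    pairs.add((min(g, h), max(g, h)))
        n_tf = min(cfg.n_tf_genes, len(module))
        tf_genes = set(rng.choice(module, size=n_tf, replace=False))

    graph = InteractionGraph()
    for s in symbols:
        graph.add_node(s, "gene", is_tf=s in tf_genes)
    itypes = rng.choice(_GENE_EDGE_TYPES, size=len(pairs))
    for (a, b), itype in zip(sorted(pairs), itypes):
        graph.add_edge(a, b, str(itype))

    truth = GroundTruth(
        module_members=frozenset(module),
        known_genes=frozenset(known),
        tf_genes=frozenset(tf_genes),
    )
    logger.info(
        "synthetic interactome: %d nodes, %d edges, module %d, known %d",
        graph.n_nodes(), graph.n_edges(), len(module), len(known),
    )
    return graph, truth


def generate_expression(
    cfg: SyntheticConfig, truth: GroundTruth
) -> tuple[dict[str, ExpressionMatrix], pd.DataFrame]:
    """Per-tissue log2 expression with the module effect planted in all tissues.

    Baseline per gene ~ Normal(8, 1) (shared across tissues); case samples
    of module genes are shifted by ``effect_size``; measurement noise is
    Normal(0, noise_sd).  Returns (tissue -> matrix, combined metadata).
    """
    rng = _rng(cfg, 2)
    symbols = _symbols(cfg)
    baseline = rng.normal(8.0, 1.0, size=cfg.n_genes)
    module_mask = np.array([s in truth.module_members for s in symbols])
    matrices: dict[str, ExpressionMatrix] = {}
    meta_rows = []
    for t in range(cfg.n_tissues):
        tissue = f"T{t + 1}"
        cols, data = [], []
        for grp, n in (("case", cfg.n_case), ("control", cfg.n_control)):
            for i in range(n):
                sid = f"{tissue}_{grp}_{i + 1}"
                x = baseline + rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes)
                if grp == "case":
                    x = x + cfg.effect_size * module_mask
                cols.append(sid)
                data.append(x)
                meta_rows.append((sid, grp, tissue))
        matrices[tissue] = ExpressionMatrix(
            pd.DataFrame(np.column_stack(data), index=symbols, columns=cols)
        )
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "group", "tissue"])
    truth.effect_sizes.update(
        {s: (cfg.effect_size if s in truth.module_members else 0.0) for s in symbols}
    )
    return matrices, meta


def generate_mirna_layer(cfg: SyntheticConfig, truth: GroundTruth) -> list[tuple[str, str]]:
    """Directed miRNA -> target edges, biased toward module genes."""
    rng = _rng(cfg, 3)
    symbols = _symbols(cfg)
    module = sorted(truth.module_members)
    edges: list[tuple[str, str]] = []
    for i in range(cfg.n_mirna):
        mirna = f"HSA-MIR-{i + 1:03d}"
        targets: set[str] = set()
        while len(targets) < min(cfg.targets_per_mirna, cfg.n_genes):
            if module and rng.random() < cfg.mirna_module_bias:
                targets.add(str(rng.choice(module)))
            else:
                targets.add(str(rng.choice(symbols)))
        edges.extend((mirna, g) for g in sorted(targets))
    return edges


def generate_genesets(cfg: SyntheticConfig, truth: GroundTruth) -> dict[str, list[str]]:
    """GMT-ready sets; one planted set draws members from the module."""
    rng = _rng(cfg, 4)
    symbols = _symbols(cfg)
    module = sorted(truth.module_members)
    nonmodule = sorted(set(symbols) - set(module))
    sets: dict[str, list[str]] = {}
    size = min(cfg.geneset_size, cfg.n_genes)
    n_from_module = min(int(round(cfg.planted_set_overlap_fraction * size)), len(module))
    planted = sorted(rng.choice(module, size=n_from_module, replace=False)) + sorted(
        rng.choice(nonmodule, size=size - n_from_module, replace=False)
    )
    planted_term = "GS_PLANTED"
    sets[planted_term] = sorted(planted)
    for i in range(1, cfg.n_genesets):
        term = f"GS{i:03d}"
        sets[term] = sorted(rng.choice(symbols, size=size, replace=False))
    truth.planted_geneset_term = planted_term
    return sets


def write_fixture_bundle(cfg: SyntheticConfig, out_dir: str | Path) -> Path:
    """Emit every file the pipeline consumes, plus ground truth and manifest.

    Files: ``interactome.tsv`` (gene-gene + miRNA edges), one
    ``expression_<tissue>.tsv`` per tissue, ``metadata.tsv``,
    ``genesets.gmt``, ``known_genes.txt``, ``tf_list.txt``,
    ``ground_truth.json``, ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph, truth = generate_interactome(cfg)
    matrices, meta = generate_expression(cfg, truth)
    mirna_edges = generate_mirna_layer(cfg, truth)
    genesets = generate_genesets(cfg, truth)

    for mirna, gene in mirna_edges:
        graph.add_node(mirna, "mirna")
        graph.add_edge(mirna, gene, "mirna_regulation", directed=True)
    write_edge_list(graph, out / "interactome.tsv", dialect="tsv")

    for tissue, mat in matrices.items():
        mat.values.round(5).to_csv(out / f"expression_{tissue}.tsv", sep="\t",
                                   index_label="gene")
    meta.to_csv(out / "metadata.tsv", sep="\t", index=False)

    with open(out / "genesets.gmt", "w") as fh:
        for term in sorted(genesets):
            fh.write("\t".join([term, "synthetic gene set", *genesets[term]]) + "\n")
    with open(out / "known_genes.txt", "w") as fh:
        fh.writelines(s + "\n" for s in sorted(truth.known_genes))
    with open(out / "tf_list.txt", "w") as fh:
        fh.writelines(s + "\n" for s in sorted(truth.tf_genes))
    (out / "ground_truth.json").write_text(truth.to_json())
    manifest = {"config": dataclasses.asdict(cfg), "rng_seed": cfg.rng_seed}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("fixture bundle written to %s", out)
    return out
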