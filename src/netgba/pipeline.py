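"""End-to-end orchestration: seeds -> networks -> centrality -> GBA -> enrichment -> miRNA.

Driven by a single declarative YAML config; every stage writes its tables to
the output directory and appends a structured line to a JSON-lines run log.
Headline counts are collected in ``summary.json``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from netgba import __version__
from netgba.diffexpr import ExpressionMatrix, moderated_t, quantile_normalize, read_expression_tsv, read_metadata_tsv
from netgba.enrich import hypergeom_enrichment, load_gmt, mechanism_network, select_enriched_terms
from netgba.gba import KnownGeneSet, category_summary, classify_categories, gba_scores, rank_candidates
from netgba.graph_core import load_edge_list
from netgba.mirna import build_mirna_network, flag_tf_coregulation, mirnas_per_gene, targets_per_mirna
from netgba.seedsel import SeedSet, read_seeds, select_seed_genes, venn_overlap, write_seeds
from netgba.subnet import build_direct_network, build_sp_network, compact_sp_network, write_subnet
from netgba.topology import centralities, hubs, write_centralities

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative run configuration.

    Either ``datasets`` (expression matrices + metadata per dataset) or a
    precomputed ``seed_list`` must be given.  Defaults are the workflow's
    standard parameters: seed alphas 0.05/0.01, global-degree seed filter
    25, geodesics up to length 2, enrichment FDR 0.05, top-10 centrality
    ranks, hub degree > 15.
    """

    interactome: str
    known_genes: str | None = None
    tf_list: str | None = None
    gmt: str | None = None
    blocklist: str | None = None
    datasets: dict = field(default_factory=dict)  # name -> {"matrices": {tissue: path}, "metadata": path}
    seed_list: str | None = None
    out_dir: str = "netgba_out"
    alpha: float = 0.05
    tighten_alpha: float | None = 0.01
    min_global_degree: int = 25
    max_len: int = 2
    fdr: float = 0.05
    top_k: int = 10
    hub_degree: int = 15
    allowed_types: list | None = None
    quantile_normalize: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        base = Path(path).parent
        for attr in ("interactome", "known_genes", "tf_list", "gmt", "blocklist", "seed_list"):
            v = getattr(cfg, attr)
            if v is not None and not Path(v).is_absolute():
                setattr(cfg, attr, str(base / v))
        for ds in cfg.datasets.values():
            ds["matrices"] = {
                t: str(base / p) if not Path(p).is_absolute() else p
                for t, p in ds["matrices"].items()
            }
            if not Path(ds["metadata"]).is_absolute():
                ds["metadata"] = str(base / ds["metadata"])
        return cfg

    def validate(self) -> None:
        if not Path(self.interactome).exists():
            raise FileNotFoundError(f"interactome not found: {self.interactome}")
        if not self.datasets and not self.seed_list:
            raise ValueError("config needs either datasets or a seed_list")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


class _RunLog:
    def __init__(self, path: Path):
        self._fh = open(path, "a")

    def stage(self, name: str, **info) -> None:
        rec = {"stage": name, **info}
        self._fh.write(json.dumps(rec) + "\n")
        self._fh.flush()
        logger.info("stage %s: %s", name, info)

    def close(self) -> None:
        self._fh.close()


def _de_stage(cfg: RunConfig, out: Path, log: _RunLog) -> SeedSet:
    datasets_tables: dict[str, dict[str, pd.DataFrame]] = {}
    for name, ds in cfg.datasets.items():
        meta = read_metadata_tsv(ds["metadata"])
        mats = {t: read_expression_tsv(p) for t, p in ds["matrices"].items()}
        combined = ExpressionMatrix(pd.concat([m.values for m in mats.values()], axis=1))
        if cfg.quantile_normalize:
            combined = quantile_normalize(combined)
        contrasts: dict[str, pd.DataFrame] = {}
        for tissue in ds["matrices"]:
            contrasts[tissue] = moderated_t(combined, meta, tissue)
        contrasts["diagnosis"] = moderated_t(combined, meta, "diagnosis")
        for cname, de in contrasts.items():
            de.to_csv(out / f"de_{name}_{cname}.tsv", sep="\t")
        datasets_tables[name] = contrasts
        log.stage("diffexpr", dataset=name, n_genes=len(combined.genes),
                  contrasts=sorted(contrasts))
    seeds = select_seed_genes(datasets_tables, cfg.alpha, cfg.tighten_alpha)
    # per-dataset Venn regions at the working alpha
    with open(out / "venn_regions.tsv", "w") as fh:
        fh.write("dataset\tregion\tn_genes\n")
        for name, tabs in datasets_tables.items():
            from netgba.seedsel import select_sdegs

            contrast_names = sorted(tabs)
            sets = [select_sdegs(tabs[c], cfg.alpha) for c in contrast_names]
            if 2 <= len(sets) <= 4:
                _, regions = venn_overlap(sets)
                for region, n in sorted(regions.items()):
                    fh.write(f"{name}\t{region}\t{n}\n")
    return seeds


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages; returns the report directory."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run_log.jsonl")
    summary: dict = {"version": __version__}
    try:
        interactome = load_edge_list(cfg.interactome, dialect="tsv")
        log.stage("load_interactome", n_nodes=interactome.n_nodes(),
                  n_edges=interactome.n_edges())

        # --- seeds ---------------------------------------------------------
        if cfg.datasets:
            try:
                seeds = _de_stage(cfg, out, log)
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("diffexpr/seedsel", str(exc)) from exc
        else:
            seeds = read_seeds(cfg.seed_list)
            log.stage("seedsel", source="precomputed", n_seeds=len(seeds))
        write_seeds(seeds, out / "seeds.txt")
        summary["n_seeds"] = len(seeds)
        log.stage("seedsel", n_seeds=len(seeds), alpha=seeds.alpha)
        if not seeds.symbols:
            raise PipelineError("seedsel", "no seed genes selected")

        allowed = cfg.allowed_types

        # --- networks ------------------------------------------------------
        try:
            di = build_direct_network(interactome, seeds, allowed)
            write_subnet(di, out / "di_network.tsv")
            summary["n_di_connected"] = di.stats["n_connected_seeds"]
            summary["di_average_degree"] = di.stats["average_degree"]
            log.stage("di_network", **{k: v for k, v in di.stats.items()})

            sp = build_sp_network(interactome, seeds, allowed, cfg.max_len)
            write_subnet(sp, out / "sp_network.tsv")
            log.stage("sp_network", **{k: v for k, v in sp.stats.items()})

            compact = compact_sp_network(
                interactome, seeds, cfg.min_global_degree, allowed, cfg.max_len
            )
            write_subnet(compact, out / "compact_sp_network.tsv")
            summary["n_connectors"] = len(compact.connector_nodes)
            summary["n_generic"] = len(compact.generic_nodes)
            summary["compact_average_degree"] = compact.stats["average_degree"]
            log.stage("compact_sp_network", **{k: v for k, v in compact.stats.items()})
            pd.DataFrame(
                [{"network": "di", **di.stats},
                 {"network": "sp", **sp.stats},
                 {"network": "compact_sp", **compact.stats}]
            ).to_csv(out / "subnet_stats.tsv", sep="\t", index=False)
        except Exception as exc:
            if isinstance(exc, PipelineError):
                raise
            raise PipelineError("subnet", str(exc)) from exc

        # --- topology ------------------------------------------------------
        try:
            centr = centralities(compact.graph)
            write_centralities(centr, out / "centrality.tsv", compact.roles())
            hub_set = hubs(centr, cfg.hub_degree)
            summary["n_hubs"] = len(hub_set)
            log.stage("topology", n_nodes=len(centr), n_hubs=len(hub_set))
        except Exception as exc:
            raise PipelineError("topology", str(exc)) from exc

        # --- GBA -----------------------------------------------------------
        try:
            if not cfg.known_genes:
                raise FileNotFoundError("no known-gene list configured")
            known = KnownGeneSet.from_file(cfg.known_genes)
            table = gba_scores(compact.graph, known)
            table = classify_categories(table, seeds, compact, known, centr, cfg.top_k)
            table.to_csv(out / "gba_table.tsv", sep="\t")
            rank_candidates(table).to_csv(out / "candidates_ranked.tsv", sep="\t", index=False)
            category_summary(table).to_csv(out / "category_summary.tsv", sep="\t")
            log.stage("gba", n_known=len(known),
                      n_candidates=int(table["category"].astype(str).str.startswith("interest").sum()))
        except Exception as exc:
            raise PipelineError("gba", str(exc)) from exc

        # --- enrichment + mechanism network -------------------------------
        if cfg.gmt:
            try:
                coll = load_gmt(cfg.gmt)
                query = [
                    s for s in compact.graph.nodes()
                    if compact.graph.node(s).node_kind == "gene"
                ]
                enr = hypergeom_enrichment(query, coll)
                enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                blocked: set[str] = set()
                if cfg.blocklist:
                    with open(cfg.blocklist) as fh:
                        blocked = {line.strip() for line in fh if line.strip()}
                terms = [t for t in select_enriched_terms(enr, cfg.fdr) if t not in blocked]
                summary["n_enriched_terms"] = len(terms)
                if terms:
                    union, mech = mechanism_network(
                        terms, coll, interactome, allowed, compact.roles()
                    )
                    write_subnet(mech, out / "mechanism_network.tsv")
                    summary["n_mechanism_genes"] = len(union)
                else:
                    summary["n_mechanism_genes"] = 0
                log.stage("enrich", n_tested=len(enr), n_enriched=len(terms))
            except Exception as exc:
                raise PipelineError("enrich", str(exc)) from exc

        # --- miRNA layer ---------------------------------------------------
        try:
            mirna_graph, mapping = build_mirna_network(interactome, seeds)
            write_subnet_graph = mirna_graph.n_nodes() > 0
            if write_subnet_graph:
                from netgba.graph_core import write_edge_list

                write_edge_list(mirna_graph, out / "mirna_network.tsv")
            mirnas_per_gene(mapping).to_csv(out / "mirna_per_gene.tsv", sep="\t")
            targets_per_mirna(mapping).to_csv(out / "targets_per_mirna.tsv", sep="\t")
            if cfg.tf_list:
                with open(cfg.tf_list) as fh:
                    tfs = [line.strip() for line in fh if line.strip()]
                flag_tf_coregulation(mirna_graph, tfs).to_csv(out / "tf_flags.tsv", sep="\t")
            summary["n_mirnas"] = len(mapping.forward)
            log.stage("mirna", n_mirnas=len(mapping.forward),
                      n_targeted_genes=len(mapping.reverse))
        except Exception as exc:
            raise PipelineError("mirna", str(exc)) from exc

        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        log.stage("done", **{k: v for k, v in summary.items() if k != "version"})
        return out
    finally:
        log.close()
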