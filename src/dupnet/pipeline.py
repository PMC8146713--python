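"""End-to-end pipeline orchestration with a run directory and manifest.

Stages (in the workflow order: interactome construction, topology,
diffusion prioritization, module detection/enrichment, pathway enrichment,
disease network, tissue subnetwork):

    build     read + clean + filter the interactome, map regions to seed
              genes, expand to the eDSi
    topology  background centrality means on the interactome LCC, per-node
              profile and hub/bottleneck flags on the eDSi
    diffuse   heat diffusion from the disease-gene query list, max-rank
              selection, prioritized candidates
    modules   SKNN + Louvain modules on the eDSi and per-module
              over-representation (BH q)
    enrich    pathway-style over-representation of the prioritized genes
              (raw p threshold)
    disease   gene-disease association network over seeds + candidates
    tissue    tissue functional subnetwork around the prioritized genes

Each stage reads its prerequisites from the run directory, so stages are
independently re-runnable and every summary number is recomputable from the
emitted files. A rerun with the same inputs, config and seed is
byte-identical on all tables and the manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .associations import build_disease_network, tissue_subnetwork
from .diffusion import diffuse, prioritize_candidates, rank_and_select
from .enrichment import enrich_modules, fisher_enrichment, louvain_partition, sknn_graph
from .io import (
    read_bed_genes,
    read_gene_disease,
    read_gmt,
    read_graphml,
    read_scored_edge_list,
    write_graph,
)
from .network import clean, expand_seeds, filter_by_score, largest_connected_component
from .regions import map_regions, parse_region
from .topology import background_stats, centrality_profile, classify, summarize_flags

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "report_summary", "STAGES"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and a remediation hint."""


@dataclass
class RunConfig:
    """Resolved pipeline configuration. Defaults are the published analysis
    parameters: score > 0.4, incident expansion, hub threshold 100,
    diffusion time 0.1 with max rank 302, SKNN k=10, q/p thresholds 0.05,
    tissue confidence > 0.10 with at most 15 added genes."""

    # inputs
    edges_path: str = ""
    edges_dialect: str = "hippie"
    annotation_path: str = ""
    regions_path: str = ""
    id_genes_path: str = ""
    gmt_path: str = ""
    gene_disease_path: str = ""
    tissue_network_path: str = ""
    # parameters
    score_threshold: float = 0.4
    strict_threshold: bool = True
    expansion_mode: str = "incident"
    overlap_rule: str = "any_overlap"
    hub_threshold: int = 100
    diffusion_time: float = 0.1
    max_rank: int = 302
    include_query_in_rank: bool = True
    weighted_diffusion: bool = False
    sknn_k: int = 10
    louvain_resolution: float = 1.0
    q_threshold: float = 0.05
    p_threshold: float = 0.05
    tissue_min_confidence: float = 0.10
    tissue_max_added: int = 15
    seed: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)


def _read_regions_file(path) -> list:
    """Two-column TSV: region label, region string (``chrN:start-end``)."""
    regions = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                label, text = "", parts[0]
            else:
                label, text = parts[0], parts[1]
            regions.append(parse_region(text, label=label))
    return regions


def _manifest_path(run_dir) -> Path:
    return Path(run_dir) / "manifest.json"


def _load_manifest(run_dir) -> dict:
    p = _manifest_path(run_dir)
    if p.exists():
        with p.open() as fh:
            return json.load(fh)
    return {"stages": {}}


def _save_manifest(run_dir, manifest: dict) -> None:
    with _manifest_path(run_dir).open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _require(run_dir: Path, name: str, stage: str, hint: str) -> Path:
    p = run_dir / name
    if not p.exists():
        raise PipelineError(f"stage {stage!r}: missing {name} ({hint})")
    return p


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# stages


def _stage_build(config: RunConfig, run_dir: Path) -> dict:
    if not config.edges_path:
        raise PipelineError("stage 'build': no edges_path configured (set the interactome file)")
    edges = read_scored_edge_list(config.edges_path, dialect=config.edges_dialect)
    G = clean(edges)
    G = filter_by_score(G, config.score_threshold, strict=config.strict_threshold)
    lcc = largest_connected_component(G)
    write_graph(lcc, run_dir / "interactome.graphml")

    annotation = read_bed_genes(
        _pipeline_input(config.annotation_path, "build", "annotation_path (BED gene annotation)")
    )
    regions = _read_regions_file(
        _pipeline_input(config.regions_path, "build", "regions_path (region strings)")
    )
    seed_sets = map_regions(annotation, regions, rule=config.overlap_rule)
    seed_rows = [
        {"region": region, "gene": gene}
        for region, genes in seed_sets.items()
        for gene in sorted(genes)
    ]
    _write_tsv(pd.DataFrame(seed_rows, columns=["region", "gene"]), run_dir / "seeds.tsv")

    gene_region = {g: r for r, genes in seed_sets.items() for g in genes}
    edsi = expand_seeds(lcc, gene_region, mode=config.expansion_mode)
    if config.id_genes_path:
        query = _read_gene_list(config.id_genes_path)
        edsi.flag_query(query)
    write_graph(edsi.graph, run_dir / "edsi.graphml")
    return {
        "input_edges": len(edges),
        "skipped_rows": edges.skipped,
        "lcc_nodes": lcc.number_of_nodes(),
        "lcc_edges": lcc.number_of_edges(),
        "seed_genes_mapped": len(gene_region),
        "seed_genes_in_lcc": len(edsi.seed_genes),
        "seed_genes_missing": len(edsi.missing_seeds),
        "edsi_nodes": edsi.graph.number_of_nodes(),
        "edsi_edges": edsi.graph.number_of_edges(),
        "query_genes_in_edsi": len(edsi.query_genes),
    }


def _pipeline_input(path: str, stage: str, hint: str) -> str:
    if not path:
        raise PipelineError(f"stage {stage!r}: missing input ({hint})")
    if not Path(path).exists():
        raise PipelineError(f"stage {stage!r}: input file not found: {path} ({hint})")
    return path


def _read_gene_list(path) -> list:
    with Path(path).open() as fh:
        return [line.strip() for line in fh if line.strip()]


def _load_edsi(run_dir: Path, stage: str):
    p = _require(run_dir, "edsi.graphml", stage, "run the build stage first")
    return read_graphml(p)


def _seed_map(run_dir: Path, stage: str, graph: nx.Graph) -> dict:
    seeds = {}
    for n, d in graph.nodes(data=True):
        if d.get("is_seed"):
            seeds[n] = d.get("region", "")
    if not seeds:
        raise PipelineError(f"stage {stage!r}: eDSi carries no seed flags")
    return seeds


def _stage_topology(config: RunConfig, run_dir: Path) -> dict:
    lcc = read_graphml(
        _require(run_dir, "interactome.graphml", "topology", "run the build stage first")
    )
    edsi = _load_edsi(run_dir, "topology")
    background = background_stats(lcc)
    profile = centrality_profile(edsi)
    flags = classify(profile, background, hub_threshold=config.hub_threshold)
    table = profile.join(flags).reset_index()
    table.insert(1, "is_seed", [bool(edsi.nodes[n].get("is_seed")) for n in table["node"]])
    _write_tsv(table, run_dir / "topology.tsv")
    with (run_dir / "background.json").open("w") as fh:
        json.dump(background.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    seeds = _seed_map(run_dir, "topology", edsi)
    seed_pct = summarize_flags(flags, seeds)
    return {
        "background": background.as_dict(),
        "seed_flag_percent": seed_pct,
        "edsi_mean_degree": float(profile["degree"].mean()),
    }


def _stage_diffuse(config: RunConfig, run_dir: Path) -> dict:
    edsi = _load_edsi(run_dir, "diffuse")
    query = _read_gene_list(
        _pipeline_input(config.id_genes_path, "diffuse", "id_genes_path (disease-gene query list)")
    )
    heat = diffuse(
        edsi, query, t=config.diffusion_time, weighted=config.weighted_diffusion
    )
    result = rank_and_select(
        heat, max_rank=config.max_rank, include_query=config.include_query_in_rank
    )
    seeds = _seed_map(run_dir, "diffuse", edsi)
    table = result.table.copy()
    table["is_seed"] = table["gene"].map(lambda g: g in seeds)
    table["region"] = table["gene"].map(lambda g: seeds.get(g, ""))
    table["is_query"] = table["gene"].map(lambda g: g in heat.query_genes)
    _write_tsv(table, run_dir / "diffusion.tsv")
    prioritized = prioritize_candidates(result, seeds)
    _write_tsv(prioritized, run_dir / "prioritized.tsv")
    return {
        "query_genes_present": len(heat.query_genes),
        "total_heat": heat.total(),
        "selected_nodes": len(result.selected),
        "prioritized_genes": len(prioritized),
    }


def _stage_modules(config: RunConfig, run_dir: Path) -> dict:
    edsi = _load_edsi(run_dir, "modules")
    library = read_gmt(
        _pipeline_input(config.gmt_path, "modules", "gmt_path (gene-set library)")
    )
    k = min(config.sknn_k, max(1, edsi.number_of_nodes() - 1))
    sknn = sknn_graph(edsi, k=k)
    partition = louvain_partition(
        sknn, resolution=config.louvain_resolution, seed=config.seed
    )
    member_rows = [
        {"module": m.module_id, "gene": g}
        for m in partition.modules
        for g in sorted(m.genes)
    ]
    _write_tsv(pd.DataFrame(member_rows, columns=["module", "gene"]), run_dir / "modules.tsv")
    enr = enrich_modules(partition, library, background=set(edsi.nodes))
    _write_tsv(enr, run_dir / "module_enrichment.tsv")
    significant = enr[enr["q"] < config.q_threshold] if not enr.empty else enr
    return {
        "sknn_k": k,
        "n_modules": len(partition.modules),
        "modularity": partition.modularity,
        "module_term_tests": len(enr),
        "enriched_module_terms_q": int(len(significant)),
    }


def _stage_enrich(config: RunConfig, run_dir: Path) -> dict:
    lcc = read_graphml(
        _require(run_dir, "interactome.graphml", "enrich", "run the build stage first")
    )
    library = read_gmt(
        _pipeline_input(config.gmt_path, "enrich", "gmt_path (gene-set library)")
    )
    pri_path = _require(run_dir, "prioritized.tsv", "enrich", "run the diffuse stage first")
    pri = pd.read_csv(pri_path, sep="\t")
    genes = set(pri["gene"]) if not pri.empty else set()
    if not genes:
        _write_tsv(
            pd.DataFrame(columns=["term", "description", "k", "n", "K", "N", "p", "q"]),
            run_dir / "pathway_enrichment.tsv",
        )
        return {"query_genes": 0, "enriched_terms_p": 0}
    enr = fisher_enrichment(genes, library, background=set(lcc.nodes), restrict_query=True)
    _write_tsv(enr, run_dir / "pathway_enrichment.tsv")
    significant = enr[enr["p"] < config.p_threshold] if not enr.empty else enr
    return {"query_genes": len(genes), "enriched_terms_p": int(len(significant))}


def _stage_disease(config: RunConfig, run_dir: Path) -> dict:
    records = read_gene_disease(
        _pipeline_input(
            config.gene_disease_path, "disease", "gene_disease_path (association table)"
        )
    )
    seeds_path = _require(run_dir, "seeds.tsv", "disease", "run the build stage first")
    seeds_df = pd.read_csv(seeds_path, sep="\t")
    genes = set(seeds_df["gene"]) if not seeds_df.empty else set()
    net = build_disease_network(records, genes)
    edge_rows = [
        {"gene": u if net.graph.nodes[u]["kind"] == "gene" else v,
         "disease": v if net.graph.nodes[u]["kind"] == "gene" else u,
         "score": d["score"]}
        for u, v, d in net.graph.edges(data=True)
    ]
    edge_df = pd.DataFrame(edge_rows, columns=["gene", "disease", "score"])
    edge_df = edge_df.sort_values(["gene", "disease"], kind="mergesort").reset_index(drop=True)
    _write_tsv(edge_df, run_dir / "disease_network.tsv")
    counts = net.disease_degree.rename_axis("disease").reset_index()
    _write_tsv(counts, run_dir / "disease_counts.tsv")
    top = counts.iloc[0] if not counts.empty else None
    return {
        "associations": net.n_edges,
        "diseases": int(len(net.disease_degree)),
        "top_disease": None if top is None else str(top["disease"]),
        "top_disease_genes": None if top is None else int(top["n_genes"]),
    }


def _stage_tissue(config: RunConfig, run_dir: Path) -> dict:
    if not config.tissue_network_path:
        return {"skipped": True, "reason": "no tissue_network_path configured"}
    edges = read_scored_edge_list(
        _pipeline_input(config.tissue_network_path, "tissue", "tissue_network_path"),
        dialect="generic",
    )
    pri_path = _require(run_dir, "prioritized.tsv", "tissue", "run the diffuse stage first")
    pri = pd.read_csv(pri_path, sep="\t")
    query = set(pri["gene"]) if not pri.empty else set()
    if not query:
        return {"skipped": True, "reason": "empty prioritized gene set"}
    sub = tissue_subnetwork(
        edges,
        query,
        min_confidence=config.tissue_min_confidence,
        max_added=config.tissue_max_added,
    )
    write_graph(sub.graph, run_dir / "tissue_network.graphml")
    edge_df = pd.DataFrame(
        [
            {"gene_a": u, "gene_b": v, "score": d["score"]}
            for u, v, d in sorted(sub.graph.edges(data=True))
        ],
        columns=["gene_a", "gene_b", "score"],
    )
    _write_tsv(edge_df, run_dir / "tissue_edges.tsv")
    return {
        "query_genes_present": len(sub.query_genes),
        "added_genes": len(sub.added_genes),
        "tissue_nodes": sub.graph.number_of_nodes(),
        "tissue_edges": sub.graph.number_of_edges(),
    }


STAGES = {
    "build": _stage_build,
    "topology": _stage_topology,
    "diffuse": _stage_diffuse,
    "modules": _stage_modules,
    "enrich": _stage_enrich,
    "disease": _stage_disease,
    "tissue": _stage_tissue,
}
_STAGE_ORDER = ["build", "topology", "diffuse", "modules", "enrich", "disease", "tissue"]


def run_pipeline(config: RunConfig, run_dir, stages=None) -> dict:
    """Execute pipeline stages into ``run_dir``; returns the manifest.

    ``stages`` defaults to the full ordered stage list. A failing stage
    raises :class:`PipelineError` naming the stage; artifacts of earlier
    stages are preserved. The manifest records the resolved config, package
    version, seed and per-stage summaries, with no timestamps, so a rerun is
    byte-identical.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(run_dir / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("dupnet")
    root.addHandler(log_handler)
    try:
        manifest = _load_manifest(run_dir)
        manifest["version"] = __version__
        manifest["config"] = config.as_dict()
        manifest["seed"] = config.seed
        for name in stages or _STAGE_ORDER:
            if name not in STAGES:
                raise PipelineError(f"unknown stage {name!r}; choose from {_STAGE_ORDER}")
            logger.info("stage %s: starting", name)
            try:
                summary = STAGES[name](config, run_dir)
            except PipelineError:
                _save_manifest(run_dir, manifest)
                raise
            except Exception as exc:  # annotate with the stage name
                _save_manifest(run_dir, manifest)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = summary
            logger.info("stage %s: %s", name, summary)
        _save_manifest(run_dir, manifest)
        return manifest
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def report_summary(run_dir) -> str:
    """Human-readable run summary, derived only from the emitted files."""
    run_dir = Path(run_dir)
    manifest_file = _manifest_path(run_dir)
    if not manifest_file.exists():
        raise PipelineError(f"no manifest.json in {run_dir}; not a run directory?")
    manifest = _load_manifest(run_dir)
    lines = [f"dupnet run summary ({run_dir})", f"version: {manifest.get('version', '?')}"]
    for name in _STAGE_ORDER:
        summary = manifest.get("stages", {}).get(name)
        if summary is None:
            lines.append(f"  {name}: skipped")
            continue
        if summary.get("skipped"):
            lines.append(f"  {name}: skipped ({summary.get('reason', '')})")
            continue
        flat = {}
        for k, v in summary.items():
            if isinstance(v, dict):
                flat.update({f"{k}.{kk}": vv for kk, vv in v.items()})
            else:
                flat[k] = v
        parts = ", ".join(f"{k}={v}" for k, v in flat.items())
        lines.append(f"  {name}: {parts}")
    pri_path = run_dir / "prioritized.tsv"
    if pri_path.exists():
        pri = pd.read_csv(pri_path, sep="\t")
        if pri.empty:
            lines.append("  prioritized candidates: none")
        else:
            top = ", ".join(
                f"{r.gene}(rank {r.rank})" for r in pri.head(10).itertuples(index=False)
            )
            lines.append(f"  top prioritized candidates: {top}")
    enr_path = run_dir / "module_enrichment.tsv"
    if enr_path.exists():
        enr = pd.read_csv(enr_path, sep="\t")
        if not enr.empty:
            top_terms = ", ".join(
                f"{r.term}@{r.module}(q={r.q:.2e})"
                for r in enr.head(5).itertuples(index=False)
            )
            lines.append(f"  top enriched module terms: {top_terms}")
    return "\n".join(lines)
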