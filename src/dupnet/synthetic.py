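"""Synthetic pipeline inputs with known planted structure.

Every input the real analysis consumes can be generated here with ground
truth attached, so each stage is testable without downloads:

* a scale-free scored interactome (preferential attachment, i.i.d. edge
  confidences) standing in for a curated PPI database export;
* genomic duplication regions on an artificial chromosome ``chrS`` whose
  planted protein-coding genes are known interactome nodes, plus decoy genes
  just outside the boundaries and non-coding entries;
* a planted disease module — a connected gene set wired preferentially to a
  designated "causal" subset of the seed genes — whose members form the
  disease-gene (ID-gene) query list;
* a GMT library with one term oversampled from the disease module (the
  planted enriched term) among uniform null terms;
* a gene-disease association table in which a planted disease is associated
  with every causal seed.

The dataset is a pure function of (config, seed): the same pair always
reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .io import (
    EdgeList,
    EdgeRecord,
    GeneAnnotation,
    GeneDiseaseRecord,
    GeneSetLibrary,
    GeneSetTerm,
    write_bed_genes,
    write_gene_disease,
    write_gmt,
    write_scored_edge_list,
)
from .regions import GenomicRegion

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_interactome",
    "plant_regions_and_genes",
    "plant_disease_module",
    "plant_enriched_library",
    "plant_disease_table",
    "generate_dataset",
]

_GENE_WIDTH = 50_000
_GENE_GAP = 10_000
_REGION_SPACING = 10_000_000


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters. Defaults are the package's study conditions:
    a scaled-down analogue of a confidence-scored human interactome with
    three duplicated regions and a planted disease module.

    All sizes must be positive and probabilities in [0, 1]; the config is a
    frozen dataclass serializable to JSON, so any dataset is reproducible
    from (config, seed).
    """

    # interactome
    n_nodes: int = 2000
    attachment: int = 8
    score_low: float = 0.0
    score_high: float = 1.0
    # regions
    n_regions: int = 3
    genes_per_region: int = 15
    decoys_per_region: int = 2
    noncoding_per_region: int = 2
    # planted disease module
    disease_module_size: int = 25
    n_causal_seeds: int = 8
    wiring_prob: float = 0.6
    background_wiring_prob: float = 0.02
    # planted enriched library
    n_terms: int = 40
    term_size: int = 20
    enrichment_odds: float = 100.0
    # gene-disease table
    n_diseases: int = 12
    planted_disease_extra_prob: float = 0.35
    extra_association_rows: int = 150

    def __post_init__(self) -> None:
        if self.n_nodes < 10:
            raise ValueError("n_nodes must be >= 10")
        if not 1 <= self.attachment < self.n_nodes:
            raise ValueError("attachment must be in [1, n_nodes)")
        for name in ("wiring_prob", "background_wiring_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_regions * self.genes_per_region + self.disease_module_size > self.n_nodes:
            raise ValueError("regions + disease module exceed the node budget")
        if self.enrichment_odds < 1.0:
            raise ValueError("enrichment_odds must be >= 1")
        if self.term_size > self.n_nodes:
            raise ValueError("term_size exceeds the gene universe")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _symbols(n: int) -> list:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_interactome(config: SyntheticConfig, seed: int) -> EdgeList:
    """Preferential-attachment interactome with i.i.d. uniform edge scores.

    Edge count is exactly ``attachment * (n_nodes - attachment)``. The
    HIPPIE-style synthetic entrez id of gene ``G0007`` is ``7``.
    """
    rng = np.random.default_rng(seed)
    ba_seed = int(rng.integers(2**31))
    G = nx.barabasi_albert_graph(config.n_nodes, config.attachment, seed=ba_seed)
    names = _symbols(config.n_nodes)
    records = []
    for u, v in sorted(G.edges()):
        score = float(rng.uniform(config.score_low, config.score_high))
        records.append(
            EdgeRecord(
                names[u],
                names[v],
                score,
                {"entrez_a": str(u), "entrez_b": str(v)},
            )
        )
    return EdgeList(records)


def plant_regions_and_genes(
    config: SyntheticConfig, nodes: list, seed: int
) -> tuple:
    """Plant duplication regions and a gene annotation on chromosome ``chrS``.

    Region ``i`` receives ``genes_per_region`` protein-coding genes laid
    head-to-tail inside it; each region also gets decoy protein-coding genes
    placed entirely *outside* its boundaries (the nearest one ending exactly
    1 base before the region start) and non-coding entries *inside* it, both
    of which correct region mapping must exclude.

    Returns ``(annotations, regions, truth)`` where truth maps region label
    -> planted gene set.
    """
    rng = np.random.default_rng(seed)
    n_seed_genes = config.n_regions * config.genes_per_region
    chosen = rng.choice(len(nodes), size=n_seed_genes, replace=False)
    annotations: list[GeneAnnotation] = []
    regions: list[GenomicRegion] = []
    truth: dict[str, set] = {}
    decoy_i = 0
    nc_i = 0
    for r in range(config.n_regions):
        label = f"dupS{r + 1}"
        region_start = r * _REGION_SPACING + 1_000_000 + 1  # 1-based
        span = config.genes_per_region * (_GENE_WIDTH + _GENE_GAP) + _GENE_GAP
        region_end = region_start + span - 1
        regions.append(
            GenomicRegion("chrS", region_start, region_end, assembly="synthS", label=label)
        )
        genes = [
            nodes[chosen[r * config.genes_per_region + j]]
            for j in range(config.genes_per_region)
        ]
        truth[label] = set(genes)
        pos = region_start - 1 + _GENE_GAP  # 0-based BED start of first gene
        for g in genes:
            annotations.append(GeneAnnotation("chrS", pos, pos + _GENE_WIDTH, g))
            pos += _GENE_WIDTH + _GENE_GAP
        # decoy genes entirely outside the region: the first ends exactly at
        # the base before region_start (BED end = region_start - 1, 1-based
        # last base = region_start - 1)
        for d in range(config.decoys_per_region):
            end0 = (region_start - 1) - d * (_GENE_WIDTH + _GENE_GAP)
            annotations.append(
                GeneAnnotation("chrS", end0 - _GENE_WIDTH, end0, f"DECOY{decoy_i:03d}")
            )
            decoy_i += 1
        # non-coding entries inside the region (excluded by the biotype filter)
        for _ in range(config.noncoding_per_region):
            start0 = int(rng.integers(region_start - 1, region_end - _GENE_WIDTH))
            annotations.append(
                GeneAnnotation("chrS", start0, start0 + _GENE_WIDTH, f"LNC{nc_i:03d}", "lncRNA")
            )
            nc_i += 1
    return annotations, regions, truth


def plant_disease_module(
    config: SyntheticConfig, graph: nx.Graph, seeds: dict, seed: int
) -> tuple:
    """Plant a disease-gene module wired to a causal subset of the seeds.

    The module is a connected set of non-seed nodes (grown by BFS from a
    random start). Every seed gene is wired to each module gene with
    probability ``wiring_prob`` if the seed is causal, else
    ``background_wiring_prob``; new edges get fresh i.i.d. scores from the
    configured distribution. Setting both probabilities equal makes the
    causal flag carry no signal (the null configuration).

    Returns ``(extra_edges, id_genes, truth)``; truth records causal and
    non-causal seeds and, at wiring probability 1, guarantees every causal
    seed is adjacent to at least one disease gene.
    """
    rng = np.random.default_rng(seed)
    all_seeds = sorted({g for gs in seeds.values() for g in gs} if isinstance(next(iter(seeds.values()), None), (set, frozenset)) else seeds)
    seed_set = set(all_seeds)
    candidates = [n for n in sorted(graph.nodes) if n not in seed_set]
    if config.disease_module_size >= len(candidates):
        raise ValueError("disease module larger than the available non-seed nodes")
    # grow a connected module by BFS over non-seed nodes
    order = list(rng.permutation(len(candidates)))
    module: list[str] = []
    for start_idx in order:
        start = candidates[start_idx]
        module = []
        frontier = [start]
        visited = {start}
        while frontier and len(module) < config.disease_module_size:
            node = frontier.pop(0)
            module.append(node)
            for nbr in sorted(graph.neighbors(node)):
                if nbr not in visited and nbr not in seed_set:
                    visited.add(nbr)
                    frontier.append(nbr)
        if len(module) == config.disease_module_size:
            break
    if len(module) < config.disease_module_size:
        raise ValueError("could not grow a connected disease module of the requested size")
    n_causal = min(config.n_causal_seeds, len(all_seeds))
    causal = sorted(rng.choice(all_seeds, size=n_causal, replace=False).tolist())
    causal_set = set(causal)
    extra_edges: list[EdgeRecord] = []
    for s in all_seeds:
        p = config.wiring_prob if s in causal_set else config.background_wiring_prob
        if p <= 0.0:
            continue
        wired = rng.random(len(module)) < p
        if s in causal_set and config.wiring_prob >= 1.0 and not wired.any():
            wired[0] = True
        for m, w in zip(module, wired):
            if w and not graph.has_edge(s, m):
                score = float(rng.uniform(config.score_low, config.score_high))
                extra_edges.append(EdgeRecord(s, m, score))
    truth = {
        "module_genes": sorted(module),
        "causal_seeds": causal,
        "noncausal_seeds": sorted(seed_set - causal_set),
    }
    return extra_edges, sorted(module), truth


def plant_enriched_library(
    config: SyntheticConfig, module_genes: list, universe: list, seed: int
) -> tuple:
    """GMT library with one term oversampled from ``module_genes``.

    The planted term draws its genes without replacement with sampling weight
    ``enrichment_odds`` for module genes and 1 elsewhere (``inf`` means the
    term is drawn from the module alone; odds 1 gives a null library). The
    remaining terms are uniform draws from the universe.
    """
    rng = np.random.default_rng(seed)
    universe = sorted(universe)
    module_set = set(module_genes)
    if not module_set <= set(universe):
        raise ValueError("module genes must lie inside the gene universe")
    terms: dict[str, GeneSetTerm] = {}
    if np.isinf(config.enrichment_odds):
        if config.term_size > len(module_genes):
            raise ValueError("term_size exceeds the module with infinite odds")
        picked = rng.choice(sorted(module_set), size=config.term_size, replace=False)
    else:
        weights = np.array(
            [config.enrichment_odds if g in module_set else 1.0 for g in universe]
        )
        weights /= weights.sum()
        picked = rng.choice(universe, size=config.term_size, replace=False, p=weights)
    planted_id = "T_PLANTED"
    terms[planted_id] = GeneSetTerm("planted enriched term", frozenset(picked.tolist()))
    for i in range(config.n_terms - 1):
        genes = rng.choice(universe, size=config.term_size, replace=False)
        terms[f"T{i + 1:03d}"] = GeneSetTerm(f"null term {i + 1}", frozenset(genes.tolist()))
    library = GeneSetLibrary("synthetic_library", terms)
    return library, {"planted_term": planted_id}


def plant_disease_table(
    config: SyntheticConfig, seeds: set, causal: list, universe: list, seed: int
) -> tuple:
    """Gene-disease association table with a planted most-associated disease.

    The planted disease ``D_PLANTED`` is associated with every causal seed
    and with each remaining seed with probability
    ``planted_disease_extra_prob`` (a shared phenotype touches genes across
    all regions, like the dominant disease of a duplication-syndrome
    association network); each seed additionally draws a small Poisson number
    of other diseases, and random filler rows cover non-seed genes. Scores
    are Uniform(0, 1).
    """
    rng = np.random.default_rng(seed)
    diseases = [f"D{i + 1:03d}" for i in range(config.n_diseases)]
    planted = "D_PLANTED"
    records: list[GeneDiseaseRecord] = []
    planted_genes = set(causal)
    for g in sorted(set(seeds) - set(causal)):
        if rng.random() < config.planted_disease_extra_prob:
            planted_genes.add(g)
    for g in sorted(planted_genes):
        records.append(GeneDiseaseRecord(g, planted, float(rng.uniform())))
    for g in sorted(seeds):
        for _ in range(int(rng.poisson(1.2))):
            d = diseases[int(rng.integers(len(diseases)))]
            records.append(GeneDiseaseRecord(g, d, float(rng.uniform())))
    universe = sorted(universe)
    for _ in range(config.extra_association_rows):
        g = universe[int(rng.integers(len(universe)))]
        d = diseases[int(rng.integers(len(diseases)))]
        records.append(GeneDiseaseRecord(g, d, float(rng.uniform())))
    # collapse duplicates keeping max score, as the reader would
    best: dict[tuple, float] = {}
    for r in records:
        key = (r.gene, r.disease)
        if key not in best or r.score > best[key]:
            best[key] = r.score
    deduped = [
        GeneDiseaseRecord(g, d, s) for (g, d), s in sorted(best.items())
    ]
    truth = {"planted_disease": planted, "planted_disease_n_genes": len(planted_genes)}
    return deduped, truth


@dataclass
class SyntheticDataset:
    """All six pipeline inputs plus the ground-truth manifest."""

    config: SyntheticConfig
    seed: int
    edges: EdgeList
    annotations: list
    regions: list
    id_genes: list
    library: GeneSetLibrary
    gene_disease: list
    truth: dict

    def write(self, directory) -> dict:
        """Emit every input in its on-disk format; returns the path map."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        paths = {
            "edges": d / "interactome.tsv",
            "annotation": d / "genes.bed",
            "regions": d / "regions.txt",
            "id_genes": d / "id_genes.txt",
            "gmt": d / "library.gmt",
            "gene_disease": d / "gene_disease.tsv",
            "truth": d / "truth.json",
        }
        write_scored_edge_list(self.edges, paths["edges"], dialect="hippie")
        write_bed_genes(self.annotations, paths["annotation"])
        with paths["regions"].open("w") as fh:
            for r in self.regions:
                fh.write(f"{r.label}\t{r.chrom}:{r.start:,}-{r.end:,}\n")
            # region strings use thousands separators, as printed in CMA reports
        with paths["id_genes"].open("w") as fh:
            for g in self.id_genes:
                fh.write(g + "\n")
        write_gmt(self.library, paths["gmt"])
        write_gene_disease(self.gene_disease, paths["gene_disease"])
        with paths["truth"].open("w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return {k: str(v) for k, v in paths.items()}


def generate_dataset(config: SyntheticConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Generate the full synthetic dataset (a pure function of config + seed)."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(2**31, size=5)]
    edges = generate_interactome(config, sub[0])
    names = _symbols(config.n_nodes)
    annotations, regions, region_truth = plant_regions_and_genes(config, names, sub[1])
    G = nx.Graph()
    G.add_nodes_from(names)
    for r in edges:
        G.add_edge(r.gene_a, r.gene_b)
    extra_edges, id_genes, module_truth = plant_disease_module(
        config, G, region_truth, sub[2]
    )
    all_edges = EdgeList(list(edges) + extra_edges)
    library, term_truth = plant_enriched_library(
        config, module_truth["module_genes"], names, sub[3]
    )
    all_seeds = set().union(*region_truth.values())
    gene_disease, disease_truth = plant_disease_table(
        config, all_seeds, module_truth["causal_seeds"], names, sub[4]
    )
    truth = {
        "config": config.as_dict(),
        "seed": seed,
        "regions": {k: sorted(v) for k, v in region_truth.items()},
        **module_truth,
        **term_truth,
        **disease_truth,
    }
    dataset = SyntheticDataset(
        config=config,
        seed=seed,
        edges=all_edges,
        annotations=annotations,
        regions=regions,
        id_genes=id_genes,
        library=library,
        gene_disease=gene_disease,
        truth=truth,
    )
    _check_manifest(dataset)
    return dataset


def _check_manifest(ds: SyntheticDataset) -> None:
    """Internal consistency: the manifest must describe the emitted data."""
    planted = set()
    for genes in ds.truth["regions"].values():
        planted |= set(genes)
    annotated = {a.symbol for a in ds.annotations if a.biotype == "protein_coding"}
    if not planted <= annotated:
        raise AssertionError("planted region genes missing from the annotation")
    if set(ds.truth["module_genes"]) != set(ds.id_genes):
        raise AssertionError("disease-gene list does not match the planted module")
    if ds.truth["planted_term"] not in ds.library.terms:
        raise AssertionError("planted term missing from the library")
    table_pairs = {(r.gene, r.disease) for r in ds.gene_disease}
    for g in ds.truth["causal_seeds"]:
        if (g, ds.truth["planted_disease"]) not in table_pairs:
            raise AssertionError("planted disease association missing from the table")
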