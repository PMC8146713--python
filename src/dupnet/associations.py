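"""Gene-disease bipartite networks and tissue-specific subnetwork extraction.

The gene-disease network restricts a scored association table (DisGeNET-style)
to a gene set of interest and exposes per-disease gene counts and per-gene
disease counts — the quantities reported for the duplication-syndrome
candidates (e.g. which disease has most associated genes, which gene touches
most diseases).

The tissue subnetwork mirrors the query semantics of tissue functional-network
servers: keep the query genes, greedily add up to ``max_added`` of the most
strongly connected extra genes, then retain edges with confidence strictly
above ``min_confidence`` (published parameters: > 0.10 and 15).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .io import EdgeRecord, GeneDiseaseRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GeneDiseaseNetwork",
    "build_disease_network",
    "TissueSubnetwork",
    "tissue_subnetwork",
]


@dataclass
class GeneDiseaseNetwork:
    """Bipartite gene-disease graph with degree summaries.

    ``graph`` nodes carry a ``kind`` attribute (``"gene"`` or ``"disease"``);
    edges carry the association ``score``. ``disease_degree`` counts genes per
    disease, ``gene_degree`` diseases per gene; both are sorted descending.
    """

    graph: nx.Graph
    gene_degree: pd.Series
    disease_degree: pd.Series

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_disease_network(
    table: Iterable[GeneDiseaseRecord], genes: Iterable[str]
) -> GeneDiseaseNetwork:
    """Restrict an association table to ``genes`` and build the bipartite graph.

    Duplicate (gene, disease) pairs keep the maximum score. An empty
    restriction yields an empty network with a warning.
    """
    genes = set(genes)
    G = nx.Graph()
    for r in table:
        if r.gene not in genes:
            continue
        if G.has_edge(r.gene, r.disease):
            if r.score > G.edges[r.gene, r.disease]["score"]:
                G.edges[r.gene, r.disease]["score"] = r.score
            continue
        G.add_node(r.gene, kind="gene")
        G.add_node(r.disease, kind="disease")
        G.add_edge(r.gene, r.disease, score=r.score)
    if G.number_of_edges() == 0:
        logger.warning("build_disease_network: no association involves the given genes")
    gene_nodes = sorted(n for n, d in G.nodes(data=True) if d["kind"] == "gene")
    disease_nodes = sorted(n for n, d in G.nodes(data=True) if d["kind"] == "disease")
    gene_degree = pd.Series(
        {n: G.degree(n) for n in gene_nodes}, dtype=int, name="n_diseases"
    ).sort_values(ascending=False, kind="mergesort")
    disease_degree = pd.Series(
        {n: G.degree(n) for n in disease_nodes}, dtype=int, name="n_genes"
    ).sort_values(ascending=False, kind="mergesort")
    return GeneDiseaseNetwork(
        graph=G, gene_degree=gene_degree, disease_degree=disease_degree
    )


@dataclass
class TissueSubnetwork:
    """A tissue functional subnetwork around a query gene set.

    ``added_genes`` preserves the greedy addition order; every retained edge
    has confidence strictly above ``min_confidence``.
    """

    graph: nx.Graph
    query_genes: frozenset
    added_genes: list
    tissue: str
    min_confidence: float
    max_added: int


def _as_weighted_graph(edges) -> nx.Graph:
    if isinstance(edges, nx.Graph):
        return edges
    G = nx.Graph()
    for e in edges:
        if isinstance(e, EdgeRecord):
            a, b, w = e.gene_a, e.gene_b, e.score
        else:
            a, b, w = e[0], e[1], float(e[2])
        if a == b:
            continue
        if not G.has_edge(a, b) or w > G.edges[a, b]["score"]:
            G.add_edge(a, b, score=w)
    return G


def tissue_subnetwork(
    functional_net,
    query: Iterable[str],
    min_confidence: float = 0.10,
    max_added: int = 15,
    tissue: str = "",
) -> TissueSubnetwork:
    """Extract a tissue subnetwork around ``query`` genes.

    ``functional_net`` is a weighted edge list (triples or
    :class:`EdgeRecord`) or a graph with ``score`` edge weights in [0, 1].
    Non-query genes are added greedily, one at a time, in descending order of
    their strongest connection to the current node set (ties by lexicographic
    symbol), up to ``max_added``; finally only edges with confidence strictly
    greater than ``min_confidence`` among the kept nodes are retained.
    """
    if max_added < 0:
        raise ValueError("max_added must be >= 0")
    G = _as_weighted_graph(functional_net)
    query = set(query)
    present = sorted(q for q in query if q in G)
    if not present:
        raise ValueError("no query gene is present in the functional network")
    kept = set(present)
    added: list[str] = []
    for _ in range(max_added):
        best_gene = None
        best_score = 0.0
        for cand in G.nodes:
            if cand in kept:
                continue
            strength = max(
                (G.edges[cand, u]["score"] for u in G.neighbors(cand) if u in kept),
                default=0.0,
            )
            if strength > best_score or (
                strength == best_score and strength > 0.0
                and (best_gene is None or cand < best_gene)
            ):
                best_gene, best_score = cand, strength
        if best_gene is None:
            break
        kept.add(best_gene)
        added.append(best_gene)
    H = nx.Graph()
    for n in sorted(kept):
        H.add_node(n, is_query=(n in query), tissue=tissue)
    for u, v, d in G.subgraph(kept).edges(data=True):
        if d["score"] > min_confidence:
            H.add_edge(u, v, **d)
    return TissueSubnetwork(
        graph=H,
        query_genes=frozenset(present),
        added_genes=added,
        tissue=tissue,
        min_confidence=min_confidence,
        max_added=max_added,
    )
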