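"""Functional module detection (shared-k-nearest-neighbor graph + Louvain)
and gene-set over-representation (one-sided Fisher + Benjamini-Hochberg).

Module detection follows the SKNN scheme: each node's k strongest-weighted
neighbors form its neighbor list; two nodes are linked in the SKNN graph when
their lists share a member or when they appear in each other's lists, with
the shared-member count as edge weight. Louvain community detection on that
graph yields the functional modules.

Over-representation uses the hypergeometric upper tail
P(X >= k | N, K, n) — the one-sided Fisher exact test — with step-up
Benjamini-Hochberg correction across one family of tests. The BH family for
a module run is every (module, term) pair of that run; the background
universe is explicit in the result metadata because it materially changes p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneSetLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "sknn_graph",
    "FunctionalModule",
    "ModulePartition",
    "louvain_partition",
    "fisher_enrichment",
    "enrich_modules",
]


def _edge_weight(net: nx.Graph, u, v) -> float:
    d = net.edges[u, v]
    return float(d.get("weight", d.get("score", 1.0)))


def sknn_graph(net: nx.Graph, k: int = 10) -> nx.Graph:
    """Shared-k-nearest-neighbor graph of a weighted network.

    Each node's neighbor list holds its ``k`` highest-weight neighbors (ties
    by lexicographic symbol; nodes with fewer than k neighbors list them
    all). Output nodes are the input nodes; an edge u-v exists iff the two
    lists share at least one member or u, v appear in each other's lists.
    Edge weight is the shared-member count (minimum 1 for containment-only
    links). Deterministic and independent of edge iteration order.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k >= net.number_of_nodes():
        raise ValueError(f"k={k} must be smaller than the node count {net.number_of_nodes()}")
    knn: dict = {}
    for n in net.nodes:
        nbrs = sorted(net.neighbors(n), key=lambda m: (-_edge_weight(net, n, m), m))
        knn[n] = nbrs[:k]
    H = nx.Graph()
    H.add_nodes_from(sorted(net.nodes))
    shared: dict[tuple, int] = {}
    owners: dict = {}
    for n, lst in knn.items():
        for m in lst:
            owners.setdefault(m, []).append(n)
    for member, own in owners.items():
        own = sorted(own)
        for i in range(len(own)):
            for j in range(i + 1, len(own)):
                pair = (own[i], own[j])
                shared[pair] = shared.get(pair, 0) + 1
    for (u, v), w in shared.items():
        H.add_edge(u, v, weight=float(w))
    for n, lst in knn.items():
        for m in lst:
            if m != n and not H.has_edge(n, m):
                H.add_edge(n, m, weight=1.0)
    return H


@dataclass(frozen=True)
class FunctionalModule:
    module_id: str
    genes: frozenset


@dataclass
class ModulePartition:
    """A full Louvain partition with its modularity and detection parameters."""

    modules: list
    modularity: float
    resolution: float
    seed: int

    def as_mapping(self) -> dict:
        return {m.module_id: set(m.genes) for m in self.modules}


def louvain_partition(
    graph: nx.Graph, resolution: float = 1.0, seed: int = 0
) -> ModulePartition:
    """Louvain community detection (two-phase modularity maximization).

    Node visit order is drawn from the seeded RNG, so the same seed yields
    the same partition. Modules are relabeled M1, M2, ... in order of
    decreasing size (ties by smallest member symbol).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty graph")
    communities = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=seed
    )
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    modularity = float(
        nx.community.modularity(
            graph, communities, weight="weight", resolution=resolution
        )
    ) if graph.number_of_edges() > 0 else 0.0
    modules = [
        FunctionalModule(module_id=f"M{i + 1}", genes=frozenset(c))
        for i, c in enumerate(communities)
    ]
    return ModulePartition(
        modules=modules, modularity=modularity, resolution=resolution, seed=seed
    )


def fisher_enrichment(
    query: Iterable[str],
    library: GeneSetLibrary,
    background: Iterable[str],
    restrict_query: bool = False,
) -> pd.DataFrame:
    """One-sided Fisher over-representation of ``query`` in each library term.

    For each term: k = |query ∩ term|, n = |query|, K = |term ∩ background|,
    N = |background|; p = P(X >= k) under the hypergeometric null;
    q = Benjamini-Hochberg across all terms of the library. Terms are first
    intersected with the background; terms that vanish are dropped. The
    query must be contained in the background (set ``restrict_query`` to
    clip it instead of raising).

    Returns a DataFrame with columns term, description, k, n, K, N, p, q,
    sorted by (q, p, term).
    """
    background = set(background)
    if not background:
        raise ValueError("empty background universe")
    query = set(query)
    stray = query - background
    if stray:
        if restrict_query:
            query &= background
        else:
            raise ValueError(
                f"{len(stray)} query genes outside the background "
                "(pass restrict_query=True to clip)"
            )
    n = len(query)
    N = len(background)
    rows = []
    for term_id in sorted(library.terms):
        term = library.terms[term_id]
        term_genes = term.genes & background
        if not term_genes:
            continue
        K = len(term_genes)
        k = len(query & term_genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, term.description, k, n, K, N, min(p, 1.0)))
    df = pd.DataFrame(
        rows, columns=["term", "description", "k", "n", "K", "N", "p"]
    )
    if df.empty:
        df["q"] = pd.Series(dtype=float)
        return df
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df.sort_values(["q", "p", "term"], kind="mergesort").reset_index(drop=True)


def enrich_modules(
    modules: ModulePartition | Sequence[FunctionalModule],
    library: GeneSetLibrary,
    background: Iterable[str],
) -> pd.DataFrame:
    """Per-module over-representation with one BH family across the run.

    Every (module, term) pair of the run forms a single correction family.
    Returns a DataFrame with columns module, term, description, k, n, K, N,
    p, q sorted by (q, p, module, term). Size-1 modules are tested like any
    other.
    """
    module_list = modules.modules if isinstance(modules, ModulePartition) else list(modules)
    background = set(background)
    frames = []
    for m in module_list:
        sub = fisher_enrichment(m.genes, library, background, restrict_query=True)
        sub.insert(0, "module", m.module_id)
        frames.append(sub.drop(columns=["q"]))
    if not frames:
        return pd.DataFrame(
            columns=["module", "term", "description", "k", "n", "K", "N", "p", "q"]
        )
    df = pd.concat(frames, ignore_index=True)
    if df.empty:
        df["q"] = pd.Series(dtype=float)
        return df
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df.sort_values(["q", "p", "module", "term"], kind="mergesort").reset_index(
        drop=True
    )
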