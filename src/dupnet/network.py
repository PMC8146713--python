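"""Interactome model: cleaning, confidence filtering, largest connected
component, and seed-neighborhood expansion.

The interactome is an undirected :class:`networkx.Graph` keyed by gene
symbol, with a ``score`` attribute in [0, 1] on every edge and a
``provenance`` list on ``G.graph`` recording each transformation applied.

The expanded duplication-syndrome interactome (eDSi) is the subnetwork
containing the duplicated-region genes (seeds) plus all their direct
interaction partners. Two expansion modes exist: *incident* (default) keeps
only edges touching a seed, *induced* keeps every edge among the retained
nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .io import EdgeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "clean",
    "filter_by_score",
    "largest_connected_component",
    "ExpandedSubnetwork",
    "expand_seeds",
]


def _log_provenance(G: nx.Graph, entry: str) -> None:
    G.graph.setdefault("provenance", []).append(entry)


def clean(edges: Iterable[EdgeRecord]) -> nx.Graph:
    """Build an interactome from raw edge records.

    Self-loops are removed and duplicate unordered pairs collapsed keeping
    the maximum score (best evidence wins). Idempotent; an empty input gives
    an empty graph.
    """
    G = nx.Graph()
    self_loops = 0
    duplicates = 0
    for r in edges:
        a, b = r.gene_a, r.gene_b
        G.add_node(a)
        G.add_node(b)
        if a == b:
            self_loops += 1
            continue
        if G.has_edge(a, b):
            duplicates += 1
            if r.score > G.edges[a, b]["score"]:
                G.edges[a, b]["score"] = r.score
        else:
            G.add_edge(a, b, score=r.score)
    _log_provenance(
        G, f"clean: removed {self_loops} self-loops, collapsed {duplicates} duplicates"
    )
    if self_loops or duplicates:
        logger.info(
            "clean: removed %d self-loops, collapsed %d duplicate pairs",
            self_loops,
            duplicates,
        )
    return G


def filter_by_score(G: nx.Graph, min_score: float = 0.4, strict: bool = True) -> nx.Graph:
    """Keep edges with confidence above ``min_score``.

    ``strict=True`` (default) keeps ``score > min_score``, the published
    filtering rule; ``strict=False`` keeps ``score >= min_score``. Nodes left
    isolated *by the edge removal* are dropped; nodes isolated beforehand are
    kept.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ValueError(f"min_score {min_score} outside [0, 1]")
    keep = (
        (lambda s: s > min_score) if strict else (lambda s: s >= min_score)
    )
    H = nx.Graph(**G.graph)
    H.graph["provenance"] = list(G.graph.get("provenance", []))
    previously_isolated = {n for n in G.nodes if G.degree(n) == 0}
    for n in G.nodes:
        H.add_node(n, **G.nodes[n])
    for u, v, d in G.edges(data=True):
        if keep(d["score"]):
            H.add_edge(u, v, **d)
    dropped = [
        n for n in list(H.nodes) if H.degree(n) == 0 and n not in previously_isolated
    ]
    H.remove_nodes_from(dropped)
    op = ">" if strict else ">="
    _log_provenance(
        H,
        f"filter_by_score: kept score {op} {min_score}, "
        f"dropped {len(dropped)} newly isolated nodes",
    )
    return H


def largest_connected_component(G: nx.Graph) -> nx.Graph:
    """The component with the most nodes.

    Ties broken by most edges, then by the lexicographically smallest sorted
    node list, so the result is deterministic. An empty graph returns an
    empty graph (logged).
    """
    if G.number_of_nodes() == 0:
        logger.warning("largest_connected_component: empty graph")
        H = nx.Graph(**G.graph)
        _log_provenance(H, "largest_connected_component: empty input")
        return H
    components = [
        (comp, G.subgraph(comp).number_of_edges())
        for comp in nx.connected_components(G)
    ]
    components.sort(key=lambda item: (-len(item[0]), -item[1], sorted(item[0])))
    best = components[0][0]
    H = G.subgraph(best).copy()
    H.graph = dict(G.graph)
    H.graph["provenance"] = list(G.graph.get("provenance", []))
    _log_provenance(
        H,
        f"largest_connected_component: {H.number_of_nodes()} nodes, "
        f"{H.number_of_edges()} edges of {G.number_of_nodes()}-node input",
    )
    return H


@dataclass
class ExpandedSubnetwork:
    """Seed genes plus first neighbors, with provenance flags.

    ``seed_genes`` maps each seed present in the graph to its region label
    (empty string when seeds were given as a plain set). ``missing_seeds``
    lists requested seeds absent from the source network. Node attributes
    ``is_seed`` (bool) and ``region`` (str) are set on the graph.
    """

    graph: nx.Graph
    seed_genes: dict
    expansion_mode: str
    missing_seeds: frozenset = frozenset()
    query_genes: frozenset = frozenset()

    def flag_query(self, query: Iterable[str]) -> None:
        """Record which query genes (e.g. disease genes) are in the subnetwork."""
        present = frozenset(q for q in query if q in self.graph)
        self.query_genes = present
        for n in self.graph.nodes:
            self.graph.nodes[n]["is_query"] = n in present


def expand_seeds(
    net: nx.Graph,
    seeds: Mapping[str, str] | Iterable[str],
    mode: str = "incident",
) -> ExpandedSubnetwork:
    """Expand seed genes to their first-neighbor subnetwork (the eDSi).

    ``seeds`` is either a mapping gene -> region label or a plain iterable.
    ``incident`` mode (default) keeps exactly the source edges with at least
    one seed endpoint, so every seed keeps its full-network degree;
    ``induced`` mode keeps every source edge among the retained nodes.
    Seeds absent from the network are reported, not fatal; an entirely
    absent seed set is an error.
    """
    if mode not in {"incident", "induced"}:
        raise ValueError(f"unknown expansion mode {mode!r}")
    if isinstance(seeds, Mapping):
        seed_region = {g: r for g, r in seeds.items()}
    else:
        seed_region = {g: "" for g in seeds}
    if not seed_region:
        raise ValueError("empty seed set: nothing to expand")
    present = {g: r for g, r in seed_region.items() if g in net}
    missing = frozenset(seed_region) - frozenset(present)
    if not present:
        raise ValueError("no seed gene is present in the network")
    if missing:
        logger.warning("expand_seeds: %d seeds absent from network", len(missing))

    nodes = set(present)
    for s in present:
        nodes.update(net.neighbors(s))
    H = nx.Graph()
    for n in sorted(nodes):
        H.add_node(n, **net.nodes[n])
        H.nodes[n]["is_seed"] = n in present
        H.nodes[n]["region"] = present.get(n, "")
    if mode == "incident":
        for s in present:
            for nbr in net.neighbors(s):
                H.add_edge(s, nbr, **net.edges[s, nbr])
    else:
        for u, v, d in net.subgraph(nodes).edges(data=True):
            H.add_edge(u, v, **d)
    H.graph["provenance"] = list(net.graph.get("provenance", []))
    _log_provenance(
        H,
        f"expand_seeds: mode={mode}, {len(present)} seeds present, "
        f"{len(missing)} missing, {H.number_of_nodes()} nodes, "
        f"{H.number_of_edges()} edges",
    )
    H.graph["expansion_mode"] = mode
    return ExpandedSubnetwork(
        graph=H, seed_genes=present, expansion_mode=mode, missing_seeds=missing
    )
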