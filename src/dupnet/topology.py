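"""Per-node centrality profiling and hub / bottleneck classification.

Definitions (unweighted, undirected):

* degree — incident edge count;
* betweenness — fraction of non-redundant shortest paths through the node,
  normalized by ``(n-1)(n-2)/2`` within the node's connected component of
  size ``n``;
* closeness — ``(reachable count) / (sum of hop distances)``, computed within
  the component, so ``closeness = 1 / avg_shortest_path`` on connected graphs;
* avg_shortest_path — mean hop distance to reachable nodes (undefined, NaN,
  for singletons).

A node is a *hub* when its degree strictly exceeds a threshold (default 100
links) and a *bottleneck* when its betweenness strictly exceeds the
background interactome mean. Ties at exactly a threshold are classified
negative.

Exact (non-sampled) betweenness and all-pairs distances are computed with
igraph's C routines; correctness is pinned by brute-force oracle tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "centrality_profile",
    "BackgroundStats",
    "background_stats",
    "classify",
    "summarize_flags",
]

PROFILE_COLUMNS = ["degree", "betweenness", "closeness", "avg_shortest_path"]


def centrality_profile(net: nx.Graph) -> pd.DataFrame:
    """Exact centralities for every node, computed per connected component.

    Returns a DataFrame indexed by node (sorted) with columns ``degree``,
    ``betweenness``, ``closeness``, ``avg_shortest_path``. Singleton nodes
    get betweenness 0, closeness 0 and NaN path length.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot profile an empty graph")
    rows: dict[str, list] = {c: [] for c in PROFILE_COLUMNS}
    index: list = []
    for comp in nx.connected_components(net):
        nodes = sorted(comp)
        nc = len(nodes)
        index.extend(nodes)
        if nc == 1:
            n = nodes[0]
            rows["degree"].append(net.degree(n))
            rows["betweenness"].append(0.0)
            rows["closeness"].append(0.0)
            rows["avg_shortest_path"].append(math.nan)
            continue
        pos = {n: i for i, n in enumerate(nodes)}
        g = ig.Graph(
            n=nc,
            edges=[
                (pos[u], pos[v]) for u, v in net.subgraph(comp).edges()
            ],
            directed=False,
        )
        bet = np.asarray(g.betweenness(directed=False), dtype=float)
        norm = (nc - 1) * (nc - 2) / 2.0
        bet = bet / norm if norm > 0 else np.zeros(nc)
        dist = np.asarray(g.distances(), dtype=float)
        dist_sums = dist.sum(axis=1)  # self-distance is 0
        closeness = (nc - 1) / dist_sums
        asp = dist_sums / (nc - 1)
        for i, n in enumerate(nodes):
            rows["degree"].append(net.degree(n))
            rows["betweenness"].append(float(bet[i]))
            rows["closeness"].append(float(closeness[i]))
            rows["avg_shortest_path"].append(float(asp[i]))
    df = pd.DataFrame(rows, index=pd.Index(index, name="node"))
    return df.sort_index()


@dataclass(frozen=True)
class BackgroundStats:
    """Reference (interactome-wide) centrality means."""

    mean_degree: float
    mean_betweenness: float
    mean_closeness: float
    mean_avg_shortest_path: float
    n_nodes: int
    n_edges: int

    def as_dict(self) -> dict:
        return {
            "mean_degree": self.mean_degree,
            "mean_betweenness": self.mean_betweenness,
            "mean_closeness": self.mean_closeness,
            "mean_avg_shortest_path": self.mean_avg_shortest_path,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
        }


def background_stats(net: nx.Graph, profile: pd.DataFrame | None = None) -> BackgroundStats:
    """Arithmetic means of the centrality profile over a reference graph.

    Singleton nodes' undefined path lengths are excluded from the path-length
    mean. ``mean_degree`` always equals ``2 * edges / nodes``.
    """
    if profile is None:
        profile = centrality_profile(net)
    return BackgroundStats(
        mean_degree=float(profile["degree"].mean()),
        mean_betweenness=float(profile["betweenness"].mean()),
        mean_closeness=float(profile["closeness"].mean()),
        mean_avg_shortest_path=float(profile["avg_shortest_path"].mean(skipna=True)),
        n_nodes=net.number_of_nodes(),
        n_edges=net.number_of_edges(),
    )


def classify(
    profile: pd.DataFrame,
    background: BackgroundStats,
    hub_threshold: int = 100,
) -> pd.DataFrame:
    """Boolean topology flags per node, all with strict inequalities.

    ``is_hub``: degree > hub_threshold; ``is_bottleneck``: betweenness >
    background mean; ``high_closeness``: closeness > background mean;
    ``short_paths``: avg_shortest_path < background mean (NaN -> False).
    """
    flags = pd.DataFrame(index=profile.index)
    flags["is_hub"] = profile["degree"] > hub_threshold
    flags["is_bottleneck"] = profile["betweenness"] > background.mean_betweenness
    flags["high_closeness"] = profile["closeness"] > background.mean_closeness
    flags["short_paths"] = (
        profile["avg_shortest_path"] < background.mean_avg_shortest_path
    ).fillna(False)
    return flags


def summarize_flags(classification: pd.DataFrame, subset: Iterable[str] | None = None) -> dict:
    """Per-flag percentages (rounded to the nearest integer) over ``subset``.

    ``subset`` defaults to every profiled node; typically it is the seed-gene
    set, matching how summary fractions are reported for duplicated-region
    proteins.
    """
    if subset is None:
        sub = classification
    else:
        members = [g for g in subset if g in classification.index]
        if not members:
            raise ValueError("subset has no overlap with the classified nodes")
        sub = classification.loc[members]
    return {
        col: int(round(100.0 * float(sub[col].mean()))) for col in sub.columns
    }
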