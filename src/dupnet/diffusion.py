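"""Heat-diffusion network propagation and max-rank candidate prioritization.

Starting heat h0 places 1.0 on every query gene present in the network
(e.g. curated intellectual-disability genes) and 0 elsewhere; propagated
heat is the heat-kernel action

    h(t) = exp(-t * L) . h0

with L the (unweighted, by default) graph Laplacian. Because L's columns
sum to zero, total heat is conserved at every diffusion time. Nodes are then
ranked by heat (descending, ties broken lexicographically) and the top
``max_rank`` nodes form the selected set; duplicated-region seed genes
inside that window are the prioritized candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply

logger = logging.getLogger(__name__)

__all__ = ["HeatVector", "diffuse", "DiffusionResult", "rank_and_select", "prioritize_candidates"]

DEFAULT_TIME = 0.1
DEFAULT_MAX_RANK = 302


@dataclass
class HeatVector:
    """Per-node heat after diffusion for time ``time`` from ``query_genes``."""

    heat: pd.Series  # indexed by node, sorted
    time: float
    query_genes: frozenset

    def total(self) -> float:
        return float(self.heat.sum())


def diffuse(
    net: nx.Graph,
    query: Iterable[str],
    t: float = DEFAULT_TIME,
    weighted: bool = False,
) -> HeatVector:
    """Propagate unit heat from ``query`` genes through ``net`` for time ``t``.

    ``weighted=True`` uses the confidence-weighted Laplacian (edge ``score``
    attribute); the default treats the graph as unweighted. Query genes
    absent from the network are ignored; an empty effective query or a
    non-positive ``t`` is an error.
    """
    if t <= 0:
        raise ValueError(f"diffusion time must be positive, got {t}")
    nodes = sorted(net.nodes)
    if not nodes:
        raise ValueError("cannot diffuse on an empty graph")
    present = frozenset(q for q in query if q in net)
    if not present:
        raise ValueError("no query gene is present in the network")
    A = nx.to_scipy_sparse_array(
        net, nodelist=nodes, weight="score" if weighted else None, format="csr", dtype=float
    )
    L = sp.csgraph.laplacian(A, normed=False).tocsc()
    h0 = np.zeros(len(nodes))
    idx = {n: i for i, n in enumerate(nodes)}
    for q in present:
        h0[idx[q]] = 1.0
    heat = expm_multiply(-t * L, h0)
    return HeatVector(
        heat=pd.Series(heat, index=pd.Index(nodes, name="gene")),
        time=t,
        query_genes=present,
    )


@dataclass
class DiffusionResult:
    """Heat-ranked node table with the max-rank selection applied.

    ``table`` columns: gene, heat, rank (1-based), selected. ``max_rank`` is
    the rank cutoff (published value 302).
    """

    table: pd.DataFrame
    max_rank: int
    time: float
    query_genes: frozenset
    include_query: bool = True

    @property
    def selected(self) -> frozenset:
        return frozenset(self.table.loc[self.table["selected"], "gene"])


def rank_and_select(
    heat: HeatVector, max_rank: int = DEFAULT_MAX_RANK, include_query: bool = True
) -> DiffusionResult:
    """Rank nodes by heat (descending) and keep the top ``max_rank``.

    Ties are broken by lexicographic gene symbol, making the ranking
    deterministic. ``include_query=False`` removes the query genes before
    ranking, so the window holds only newly reached nodes.
    """
    if max_rank < 1:
        raise ValueError(f"max_rank must be >= 1, got {max_rank}")
    s = heat.heat
    if not include_query:
        s = s.drop(labels=[g for g in heat.query_genes if g in s.index])
    df = s.rename("heat").reset_index()
    df = df.sort_values(["heat", "gene"], ascending=[False, True], kind="mergesort")
    df = df.reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["selected"] = df["rank"] <= max_rank
    return DiffusionResult(
        table=df,
        max_rank=max_rank,
        time=heat.time,
        query_genes=heat.query_genes,
        include_query=include_query,
    )


def prioritize_candidates(
    result: DiffusionResult, seeds: Mapping[str, str] | Mapping[str, set] | Iterable[str]
) -> pd.DataFrame:
    """Duplicated-region genes inside the selected top-``max_rank`` window.

    ``seeds`` may be a mapping gene -> region label, a mapping region ->
    gene set, or a plain iterable of genes. Returns a DataFrame with columns
    gene, region, rank, heat, sorted by rank. Empty results are allowed
    (logged).
    """
    gene_region: dict[str, str] = {}
    if isinstance(seeds, Mapping):
        for k, v in seeds.items():
            if isinstance(v, (set, frozenset, list, tuple)):
                for g in v:
                    gene_region[g] = k  # region -> genes orientation
            else:
                gene_region[k] = v
    else:
        gene_region = {g: "" for g in seeds}
    sel = result.table[result.table["selected"]]
    hits = sel[sel["gene"].isin(gene_region)]
    out = hits.assign(region=[gene_region[g] for g in hits["gene"]])[
        ["gene", "region", "rank", "heat"]
    ].reset_index(drop=True)
    if out.empty:
        logger.warning("prioritize_candidates: no seed gene in the selected window")
    return out
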