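"""Independent brute-force oracles used to pin the fast implementations.

These deliberately avoid the code paths (and, where possible, the libraries)
they verify: centralities come from explicit enumeration of every shortest
path, the heat kernel from a truncated Taylor series with a remainder bound,
the hypergeometric tail from exact rational arithmetic, and BH from the
textbook step-up formula.
"""

from __future__ import annotations

import math
from collections import deque
from fractions import Fraction
from itertools import combinations

import numpy as np


def bfs_distances(adj: dict, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def enumerate_shortest_paths(adj: dict, dist_from_s: dict, s, t):
    """All shortest s->t paths, by DFS through strictly distance-increasing edges."""
    if t not in dist_from_s:
        return []
    paths = []

    def walk(node, path):
        if node == t:
            paths.append(path)
            return
        for nbr in adj[node]:
            if dist_from_s.get(nbr) == dist_from_s[node] + 1 and dist_from_s[nbr] <= dist_from_s[t]:
                walk(nbr, path + [nbr])

    walk(s, [s])
    return paths


def brute_force_centralities(nodes, edges):
    """Degree / normalized betweenness / closeness / mean path length by
    explicit shortest-path enumeration. Returns dict node -> dict.

    Betweenness is normalized by (n-1)(n-2)/2 within the node's component;
    closeness and path length are component-relative; singletons get
    closeness 0 and path length NaN.
    """
    nodes = list(nodes)
    adj = {n: set() for n in nodes}
    for u, v in edges:
        if u != v:
            adj[u].add(v)
            adj[v].add(u)
    # components by BFS
    seen = set()
    components = []
    for n in nodes:
        if n in seen:
            continue
        comp = set(bfs_distances(adj, n))
        seen |= comp
        components.append(sorted(comp))
    out = {}
    for comp in components:
        nc = len(comp)
        pair_dep = {n: 0.0 for n in comp}
        dist_sums = {n: 0 for n in comp}
        dists = {s: bfs_distances(adj, s) for s in comp}
        for s, t in combinations(comp, 2):
            paths = enumerate_shortest_paths(adj, dists[s], s, t)
            dist_sums[s] += dists[s][t]
            dist_sums[t] += dists[s][t]
            sigma = len(paths)
            for p in paths:
                for inner in p[1:-1]:
                    pair_dep[inner] += 1.0 / sigma
        norm = (nc - 1) * (nc - 2) / 2.0
        for n in comp:
            out[n] = {
                "degree": len(adj[n]),
                "betweenness": pair_dep[n] / norm if norm > 0 else 0.0,
                "closeness": (nc - 1) / dist_sums[n] if nc > 1 else 0.0,
                "avg_shortest_path": dist_sums[n] / (nc - 1) if nc > 1 else math.nan,
            }
    return out


def taylor_heat(nodes, edges, query, t, tol=1e-12):
    """exp(-tL) h0 by truncated Taylor series with an explicit remainder bound.

    Returns dict node -> heat. The series is summed until the tail bound
    ||tL||_1^j / j! (geometric beyond the switch point) drops below ``tol``.
    """
    nodes = sorted(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    L = np.zeros((n, n))
    for u, v in edges:
        if u == v:
            continue
        i, j = idx[u], idx[v]
        if L[i, j] == 0.0:
            L[i, j] = L[j, i] = -1.0
            L[i, i] += 1.0
            L[j, j] += 1.0
    h = np.zeros(n)
    for q in query:
        if q in idx:
            h[idx[q]] = 1.0
    M = -t * L
    # scale so the series has norm <= 0.5 (avoids cancellation), then square
    norm = np.linalg.norm(M, 1)
    s = max(0, math.ceil(math.log2(norm / 0.5))) if norm > 0.5 else 0
    Ms = M / (2**s)
    norm_s = np.linalg.norm(Ms, 1)
    E = np.eye(n)
    term = np.eye(n)
    j = 0
    while True:
        j += 1
        term = Ms @ term / j
        E = E + term
        tail = (norm_s ** (j + 1)) / math.factorial(j + 1)
        tail /= max(1e-300, 1.0 - norm_s / (j + 2))
        if tail < tol:
            break
        if j > 1000:
            raise RuntimeError("Taylor series did not converge")
    for _ in range(s):
        E = E @ E
    result = E @ h
    return {node: float(result[idx[node]]) for node in nodes}


def exact_hypergeom_tail(k, N, K, n) -> Fraction:
    """P(X >= k) by exact enumeration of all 2x2 tables with the margins."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for j in range(max(k, max(0, n + K - N)), min(n, K) + 1):
        acc += Fraction(math.comb(K, j) * math.comb(N - K, n - j), total)
    return acc


def naive_bh(pvals):
    """Textbook step-up BH: q(i) = min_{j>=i} (m * p(j) / j) after sorting."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = math.inf
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, m * pvals[i] / (rank_idx + 1))
        q[i] = min(running, 1.0)
    return q


def partitions(items):
    """All set partitions (Bell-number enumeration) of a small list."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def modularity(nodes, edges, communities):
    """Newman modularity of an unweighted partition, from the definition."""
    m = len(edges)
    if m == 0:
        return 0.0
    deg = {n: 0 for n in nodes}
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    label = {}
    for ci, comm in enumerate(communities):
        for n in comm:
            label[n] = ci
    q = 0.0
    inside = [0] * len(communities)
    deg_sum = [0] * len(communities)
    for u, v in edges:
        if label[u] == label[v]:
            inside[label[u]] += 1
    for n in nodes:
        deg_sum[label[n]] += deg[n]
    for c in range(len(communities)):
        q += inside[c] / m - (deg_sum[c] / (2 * m)) ** 2
    return q
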