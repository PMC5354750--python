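"""Brute-force reference implementations used only to cross-check results.

Each oracle favours transparency over speed: exact rational arithmetic,
explicit enumeration of subsets and paths, no shared code with the package
paths it validates.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import networkx as nx


def hypergeom_tail(N: int, K: int, M: int, x: int, tail: str) -> Fraction:
    """Exact tail probability by binomial-coefficient enumeration."""
    lo, hi = max(0, K + M - N), min(K, M)
    start = x + 1 if tail == "gt" else x
    num = sum(comb(K, t) * comb(N - K, M - t) for t in range(start, hi + 1))
    return Fraction(num, comb(N, M))


def cpm_communities(graph: nx.Graph, k: int):
    """Clique percolation by explicit k-subset enumeration and clique graph."""
    nodes = sorted(graph)
    kcliques = [
        frozenset(c)
        for c in combinations(nodes, k)
        if all(graph.has_edge(u, v) for u, v in combinations(c, 2))
    ]
    cg = nx.Graph()
    cg.add_nodes_from(range(len(kcliques)))
    for i, j in combinations(range(len(kcliques)), 2):
        if len(kcliques[i] & kcliques[j]) == k - 1:
            cg.add_edge(i, j)
    return {
        frozenset().union(*(kcliques[i] for i in comp))
        for comp in nx.connected_components(cg)
    }


def maximal_cliques(graph: nx.Graph):
    """All-subset clique enumeration, subset-maximal filter."""
    nodes = sorted(graph)
    cliques = [
        set(c)
        for r in range(1, len(nodes) + 1)
        for c in combinations(nodes, r)
        if all(graph.has_edge(u, v) for u, v in combinations(c, 2))
    ]
    return {
        frozenset(c)
        for c in cliques
        if not any(c < other for other in cliques)
    }


def _all_shortest_paths(graph: nx.Graph, s, t):
    """Shortest s-t paths by explicit simple-path enumeration (tiny graphs)."""
    paths = list(nx.all_simple_paths(graph, s, t))
    if s == t or not paths:
        return []
    d = min(len(p) for p in paths) - 1
    return [p for p in paths if len(p) - 1 == d]


def centralities(graph: nx.Graph):
    """Degree, normalized betweenness, per-component closeness by enumeration."""
    nodes = sorted(graph)
    n = len(nodes)
    degree = {v: graph.degree(v) for v in nodes}
    through = {v: 0.0 for v in nodes}
    dist = {}
    for s, t in combinations(nodes, 2):
        sps = _all_shortest_paths(graph, s, t)
        if not sps:
            continue
        dist[(s, t)] = len(sps[0]) - 1
        for v in nodes:
            if v in (s, t):
                continue
            frac = sum(1 for p in sps if v in p) / len(sps)
            through[v] += frac
    scale = (n - 1) * (n - 2) / 2
    betweenness = {v: (through[v] / scale if scale > 0 else 0.0) for v in nodes}
    closeness = {}
    for v in nodes:
        ds = [
            dist[tuple(sorted((v, u), key=nodes.index))]
            for u in nodes
            if u != v and tuple(sorted((v, u), key=nodes.index)) in dist
        ]
        closeness[v] = (len(ds) / sum(ds)) if ds else 0.0
    return degree, betweenness, closeness


def least_squares_loglog(xs, ys):
    """Hand-rolled OLS of log10(y) on log10(x): returns (slope, r_squared)."""
    import math

    lx = [math.log10(v) for v in xs]
    ly = [math.log10(v) for v in ys]
    n = len(lx)
    mx = sum(lx) / n
    my = sum(ly) / n
    sxx = sum((v - mx) ** 2 for v in lx)
    sxy = sum((a - mx) * (b - my) for a, b in zip(lx, ly))
    syy = sum((v - my) ** 2 for v in ly)
    slope = sxy / sxx
    r2 = (sxy * sxy) / (sxx * syy) if syy > 0 else 1.0
    return slope, r2
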