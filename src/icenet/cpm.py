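"""Overlapping community detection by clique percolation.

A k-clique community is the union of all k-cliques reachable from one
another through steps between k-cliques that share k-1 nodes.  Communities
may overlap in nodes.  (Two communities never share a full k-clique, but
their node overlap can reach or exceed k-1 when the shared nodes enter the
two communities through different cliques.)  k-cliques are generated by
expanding maximal cliques of size >= k; percolation is resolved with a
union-find keyed on (k-1)-subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import networkx as nx


@dataclass(frozen=True)
class CliqueCommunity:
    k: int
    members: frozenset
    clique_count: int


def maximal_cliques(graph: nx.Graph) -> list[frozenset]:
    """All maximal cliques (Bron-Kerbosch); isolated nodes come out as singletons."""
    return [frozenset(c) for c in nx.find_cliques(graph)]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _k_cliques(graph: nx.Graph, k: int, max_kcliques: int) -> list[frozenset]:
    maximal = [c for c in maximal_cliques(graph) if len(c) >= k]
    budget = sum(comb(len(c), k) for c in maximal)
    if budget > max_kcliques:
        raise RuntimeError(
            f"k-clique expansion would enumerate up to {budget} {k}-cliques "
            f"(ceiling {max_kcliques}); raise max_kcliques or increase k"
        )
    out: set[frozenset] = set()
    for c in maximal:
        out.update(frozenset(s) for s in combinations(sorted(c), k))
    return sorted(out, key=sorted)


def cpm_communities(
    graph: nx.Graph, k: int, max_kcliques: int = 10**6
) -> list[CliqueCommunity]:
    """Clique-percolation communities at parameter k (k >= 3).

    Two k-cliques are adjacent iff they share exactly k-1 nodes; each
    connected component of that adjacency is reported as the union of its
    k-cliques.  Output is sorted by (-size, smallest member id).
    """
    if k < 3:
        raise ValueError("clique percolation requires k >= 3")
    cliques = _k_cliques(graph, k, max_kcliques)
    if not cliques:
        return []
    uf = _UnionFind(len(cliques))
    owner: dict[frozenset, int] = {}
    for i, c in enumerate(cliques):
        for sub in combinations(sorted(c), k - 1):
            key = frozenset(sub)
            j = owner.setdefault(key, i)
            if j != i:
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(cliques)):
        groups.setdefault(uf.find(i), []).append(i)
    comms = []
    for idxs in groups.values():
        members = frozenset().union(*(cliques[i] for i in idxs))
        comms.append(CliqueCommunity(k=k, members=members, clique_count=len(idxs)))
    comms.sort(key=lambda c: (-len(c.members), min(c.members)))
    return comms


def modules_at_all_k(
    graph: nx.Graph, k_min: int = 3, k_max: int | None = None,
    max_kcliques: int = 10**6,
) -> dict[int, list[CliqueCommunity]]:
    """Communities for every k from k_min up to the largest clique size."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    largest = max((len(c) for c in maximal_cliques(graph)), default=0)
    top = largest if k_max is None else min(k_max, largest)
    return {
        k: cpm_communities(graph, k, max_kcliques=max_kcliques)
        for k in range(k_min, top + 1)
    }
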