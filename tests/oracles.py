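"""Independent brute-force oracles used to cross-check the fast routines.

Everything here is deliberately naive: exhaustive path enumeration,
transitive closures by repeated squaring of boolean matrices, hypergeometric
masses summed term by term, and a motif classifier that scans vertex
permutations directly. Each oracle is only ever run on tiny instances.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def brute_betweenness(nodes, edges) -> dict:
    """Raw betweenness by enumerating every shortest path (BFS levels)."""
    adj = {v: [] for v in nodes}
    for u, v in edges:
        adj[u].append(v)

    def all_shortest_paths(s, t):
        # breadth-first layering, then backtrack every geodesic
        if s == t:
            return []
        dist = {s: 0}
        frontier = [s]
        while frontier and t not in dist:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        nxt.append(w)
            frontier = nxt
        if t not in dist:
            return []
        paths = [[s]]
        for _ in range(dist[t]):
            paths = [p + [w] for p in paths for w in adj[p[-1]]
                     if dist.get(w) == len(p)]
        return [p for p in paths if p[-1] == t]

    score = {v: 0.0 for v in nodes}
    for s, t in itertools.permutations(nodes, 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for p in paths:
            for interior in p[1:-1]:
                score[interior] += 1.0 / len(paths)
    return score


def brute_krackhardt(nodes, edges) -> float:
    """Hierarchy via an explicit transitive closure."""
    nodes = list(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    reach = np.zeros((n, n), dtype=bool)
    for u, v in edges:
        reach[index[u], index[v]] = True
    for _ in range(n):
        reach = reach | (reach @ reach)
    reachable = [(i, j) for i in range(n) for j in range(n)
                 if i != j and reach[i, j]]
    if not reachable:
        return float("nan")
    mutual = sum(1 for i, j in reachable if reach[j, i])
    return 1.0 - mutual / len(reachable)


def brute_hypergeom_upper(k, N, K, n) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), summed term by term."""
    total = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x)
               for x in range(k, min(K, n) + 1)) / total


def brute_fisher_greater(table) -> float:
    """One-sided Fisher p by enumerating all tables with fixed margins."""
    (a, b), (c, d) = table
    r1, c1, N = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    mass = {x: comb(c1, x) * comb(N - c1, r1 - x) for x in range(lo, hi + 1)}
    total = sum(mass.values())
    return sum(m for x, m in mass.items() if x >= a) / total


def brute_motif_counts(nodes, kinds, signed_edges) -> dict[str, int]:
    """Count FFL/FBL instances by scanning every vertex triple.

    ``kinds`` maps vertex -> 'TF' | 'miR' | 'gene'; ``signed_edges`` maps
    (u, v) -> +1/-1. Returns counts keyed by the same labels the package
    uses, restricted to triples whose induced edge set has exactly three
    edges and matches one skeleton.
    """
    sign = {1: "+", -1: "-"}
    counts: dict[str, int] = {}
    edge = set(signed_edges)
    for triple in itertools.combinations(nodes, 3):
        induced = [(u, v) for u, v in itertools.permutations(triple, 2)
                   if (u, v) in edge]
        if len(induced) != 3:
            continue
        label = None
        for a, b, c in itertools.permutations(triple):
            if {(a, b), (b, c), (a, c)} == set(induced):
                ka, kb, kc = kinds[a], kinds[b], kinds[c]
                sab, sbc, sac = (sign[signed_edges[a, b]],
                                 sign[signed_edges[b, c]],
                                 sign[signed_edges[a, c]])
                label = f"FFL:{ka}-{sab}->{kb}-{sbc}->{kc}|{ka}-{sac}->{kc}"
                break
        if label is None:
            for a, b, c in itertools.permutations(triple):
                if {(a, b), (b, c), (c, a)} == set(induced) and kinds[a] == "miR":
                    ka, kb, kc = kinds[a], kinds[b], kinds[c]
                    sab, sbc, sca = (sign[signed_edges[a, b]],
                                     sign[signed_edges[b, c]],
                                     sign[signed_edges[c, a]])
                    label = f"FBL:{ka}-{sab}->{kb}-{sbc}->{kc}-{sca}->{ka}"
                    break
        if label is not None:
            counts[label] = counts.get(label, 0) + 1
    return counts
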