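"""Independent brute-force oracles used to check the production code.

These deliberately avoid the production algorithms: the importance oracle
enumerates every shortest path explicitly via networkx path generators, the
hypergeometric oracle sums binomial-coefficient ratios, and the coverage
oracle enumerates component subsets.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from math import comb

import networkx as nx


def brute_importance(g: nx.Graph) -> dict:
    """Composite importance by explicit enumeration of all shortest paths.

    For each node i: closeness = (n-1)/sum_k d(i,k); bridging = sum over
    unordered pairs {j,k} (both != i) of (#shortest j-k paths through i) /
    (#shortest j-k paths), divided by n(n-1)/2. Assumes a connected graph.
    """
    n = g.number_of_nodes()
    nodes = list(g.nodes)
    dist = dict(nx.all_pairs_shortest_path_length(g))
    interior = {v: 0.0 for v in nodes}
    for j, k in itertools.combinations(nodes, 2):
        paths = list(nx.all_shortest_paths(g, j, k))
        t_jk = len(paths)
        for v in nodes:
            if v in (j, k):
                continue
            through = sum(1 for p in paths if v in p[1:-1])
            if through:
                interior[v] += through / t_jk
    out = {}
    pairs = n * (n - 1) / 2
    for v in nodes:
        closeness = (n - 1) / sum(dist[v][u] for u in nodes if u != v)
        bridging = interior[v] / pairs
        out[v] = {
            "closeness": closeness,
            "bridging": bridging,
            "wi": closeness * bridging,
        }
    return out


@lru_cache(maxsize=None)
def brute_hypergeom_upper_tail(M: int, K: int, N: int, k: int) -> float:
    """P[overlap >= k] when drawing N from a universe of M containing K
    successes, by direct summation of the hypergeometric mass."""
    denom = comb(M, N)
    total = 0
    for i in range(k, min(K, N) + 1):
        if N - i <= M - K:
            total += comb(K, i) * comb(M - K, N - i)
    return total / denom


def brute_best_coverage(
    sets: dict[str, frozenset], universe: frozenset, k: int
) -> int:
    """Maximal number of universe elements coverable by k sets, by
    enumerating every k-subset."""
    best = 0
    for combo in itertools.combinations(sets, k):
        covered = frozenset().union(*(sets[c] for c in combo)) & universe
        best = max(best, len(covered))
    return best
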