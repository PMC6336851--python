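"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (pair enumeration, exhaustive
combination scans, plain recursion) and shares no code with the package.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np


def naive_kendall_distance(order1, order2) -> int:
    """O(n^2) discordant-pair count between two orderings of the same items."""
    items = list(order1)
    pos1 = {g: i for i, g in enumerate(order1)}
    pos2 = {g: i for i, g in enumerate(order2)}
    count = 0
    for a, b in combinations(items, 2):
        d1 = pos1[a] - pos1[b]
        d2 = pos2[a] - pos2[b]
        if d1 * d2 < 0:
            count += 1
    return count


def naive_signed_ks(positions, n_total: int) -> float:
    """Signed KS statistic by evaluating F_n - F at every integer position."""
    positions = sorted(positions)
    m = len(positions)
    best = 0.0
    best_abs = -1.0
    for x in range(0, n_total + 1):
        fn = sum(1 for p in positions if p <= x) / m
        d = fn - x / n_total
        if abs(d) > best_abs + 1e-12:
            best_abs = abs(d)
            best = d
    return best


def naive_heterogeneous_cliques(n_nodes, classes, adjacency, size):
    """All complete class-distinct subgraphs via full combination scan."""
    out = set()
    for combo in combinations(range(n_nodes), size):
        if len({classes[i] for i in combo}) != size:
            continue
        if all(adjacency[a, b] for a, b in combinations(combo, 2)):
            out.add(frozenset(combo))
    return out


def naive_mutual_rank_filter(weights, adjacency, th):
    """Double-rank edge filter via per-node sorting, O(n^2 log n)."""
    import math

    n = weights.shape[0]
    keep = np.zeros((n, n), dtype=bool)
    for i in range(n):
        nbrs = [j for j in range(n) if adjacency[i, j]]
        if not nbrs:
            continue
        ranked = sorted(nbrs, key=lambda j: -weights[i, j])
        k = math.ceil(th * len(nbrs))
        cutoff = weights[i, ranked[k - 1]]
        for j in nbrs:
            if weights[i, j] >= cutoff:
                keep[i, j] = True
    return keep & keep.T


def naive_osa(s1: str, s2: str) -> int:
    """Recursive (memoized) optimal string alignment distance."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        cost = 0 if s1[i - 1] == s2[j - 1] else 1
        best = min(d(i - 1, j) + 1, d(i, j - 1) + 1, d(i - 1, j - 1) + cost)
        if i > 1 and j > 1 and s1[i - 1] == s2[j - 2] and s1[i - 2] == s2[j - 1]:
            best = min(best, d(i - 2, j - 2) + 1)
        return best

    return d(len(s1), len(s2))


def naive_bh(p):
    """Benjamini-Hochberg step-up by direct arithmetic."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q
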