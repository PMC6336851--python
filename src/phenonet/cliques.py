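"""Heterogeneous clique mining and permutation significance.

A heterogeneous clique is a complete subgraph of 3 or 4 nodes whose entity
classes are pairwise distinct (the size-4 case is one nanomaterial, one
drug, one chemical and one disease).  Cliques are enumerated exhaustively
in the mutual-rank-pruned network, scored by connection strength (the sum
of the absolute weights of their edges), and assessed against a null built
by shuffling the network's weight multiset; p-values are FDR-adjusted
(Benjamini–Hochberg).
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
from statsmodels.stats.multitest import multipletests

from .network import PhenotypicNetwork
from .validation import KnownAssociationTable

__all__ = [
    "CliqueResult",
    "enumerate_heterogeneous_cliques",
    "clique_strength",
    "permutation_test_cliques",
    "fdr_adjust",
    "filter_significant",
]

#: relative tolerance guard when comparing permuted to original strengths,
#: so exact ties (identical weight multisets) count as >= despite float
#: summation order
_TIE_EPS = 1e-9


@dataclass(frozen=True)
class CliqueResult:
    """A class-heterogeneous complete subgraph with its statistics.

    ``strength`` sums the absolute edge weights (strong discordant edges
    count as strong connections); ``signed_strength`` sums weight·sign and
    is reported alongside so the concordance pattern is not lost.
    """

    members: tuple[str, ...]
    classes: tuple[str, ...]
    edges: tuple[tuple[str, str, float, int], ...]  # (id_a, id_b, weight, sign)
    strength: float
    signed_strength: float
    threshold: float | None
    p_value: float | None = None
    q_value: float | None = None
    known_connection_count: int | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    def member_pairs(self) -> list[frozenset[str]]:
        return [frozenset(p) for p in combinations(self.members, 2)]


def clique_strength(clique: CliqueResult) -> float:
    """Connection strength: sum of absolute edge weights of the clique.

    A size-k clique must carry all k(k−1)/2 edges; anything less is
    rejected.  Invariant under member reordering.
    """
    k = clique.size
    expected = k * (k - 1) // 2
    if len(clique.edges) != expected:
        raise ValueError(
            f"clique {clique.members} has {len(clique.edges)} edges, expected {expected}"
        )
    return float(sum(abs(w) for _, _, w, _ in clique.edges))


def _build_clique(net: PhenotypicNetwork, idx: Sequence[int], th: float | None) -> CliqueResult:
    ids = sorted(net.entities[i].id for i in idx)
    order = [net.index_of(i) for i in ids]
    edges = []
    strength = 0.0
    signed = 0.0
    for a, b in combinations(order, 2):
        if not net.adjacency[a, b]:
            raise ValueError(
                f"members {ids} are not fully interconnected: missing edge "
                f"({net.entities[a].id}, {net.entities[b].id})"
            )
        w = float(net.weights[a, b])
        s = int(net.signs[a, b])
        edges.append((net.entities[a].id, net.entities[b].id, w, s))
        strength += abs(w)
        signed += w * s
    return CliqueResult(
        members=tuple(ids),
        classes=tuple(net.entities[i].entity_class.value for i in order),
        edges=tuple(edges),
        strength=strength,
        signed_strength=signed,
        threshold=th,
    )


def enumerate_heterogeneous_cliques(
    net: PhenotypicNetwork, size: int, th: float | None = None
) -> list[CliqueResult]:
    """Every complete subgraph of ``size`` nodes with pairwise-distinct classes.

    Exhaustive: for each combination of ``size`` distinct entity classes the
    search iterates over the smallest class first and intersects adjacency
    masks, which prunes without ever missing a clique.  Member sets are
    unordered, emitted once each, in deterministic sorted-id order.

    ``th`` records the mutual-rank threshold the network was pruned at
    (defaults to ``net.threshold``).
    """
    if size not in (3, 4):
        raise ValueError(f"clique size must be 3 or 4, got {size!r}")
    if th is None:
        th = net.threshold
    by_class: dict[str, list[int]] = {}
    for i, e in enumerate(net.entities):
        by_class.setdefault(e.entity_class.value, []).append(i)
    adj = net.adjacency
    found: list[tuple[int, ...]] = []

    def extend(chosen: tuple[int, ...], remaining: list[list[int]], cand_mask: np.ndarray):
        if not remaining:
            found.append(chosen)
            return
        head, *rest = remaining
        for v in head:
            if cand_mask[v]:
                extend(chosen + (v,), rest, cand_mask & adj[v])

    for class_combo in combinations(sorted(by_class), size):
        groups = sorted((by_class[c] for c in class_combo), key=len)
        first, *rest = groups
        full = np.ones(net.n_nodes, dtype=bool)
        for v in first:
            extend((v,), rest, full & adj[v])

    cliques = [_build_clique(net, idx, th) for idx in found]
    cliques.sort(key=lambda c: c.members)
    return cliques


def _upper_weights(net: PhenotypicNetwork) -> tuple[np.ndarray, dict[frozenset[int], int]]:
    """Absolute upper-triangle weight vector and (i,j)->position lookup."""
    n = net.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    pos = {frozenset((int(a), int(b))): k for k, (a, b) in enumerate(zip(iu, ju))}
    return np.abs(net.weights[iu, ju]), pos


def permutation_test_cliques(
    net: PhenotypicNetwork,
    cliques: Sequence[CliqueResult],
    n_perm: int = 1000,
    seed: int = 0,
) -> list[CliqueResult]:
    """Permutation p-value for each clique's connection strength.

    The null shuffles the multiset of off-diagonal upper-triangular weights
    of the (complete) weighted matrix uniformly, mirroring to keep symmetry;
    node labels and degrees are not preserved.  For each shuffle every
    clique's strength is recomputed over its member pairs, and

        p = (1 + #{permuted strength ≥ original}) / (n_perm + 1),

    the add-one estimator, with ties counting against the clique, so
    p ∈ (0, 1].  Each permutation draws from its own seed stream
    ``(seed, permutation index)``, making runs reproducible and
    order-independent.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm!r}")
    if not cliques:
        return []
    w, pos = _upper_weights(net)
    # cliques of different sizes carry different edge counts; vectorize per size
    by_count: dict[int, list[int]] = {}
    for k, c in enumerate(cliques):
        by_count.setdefault(len(c.edges), []).append(k)
    edge_idx = {
        count: np.array(
            [
                [
                    pos[frozenset((net.index_of(a), net.index_of(b)))]
                    for a, b, _, _ in cliques[k].edges
                ]
                for k in idxs
            ],
            dtype=np.intp,
        )
        for count, idxs in by_count.items()
    }
    orig = np.array([c.strength for c in cliques])
    exceed = np.zeros(len(cliques), dtype=np.int64)
    m = w.size
    for b in range(n_perm):
        rng = np.random.default_rng([seed, b])
        perm_w = w[rng.permutation(m)]
        for count, idxs in by_count.items():
            strengths = perm_w[edge_idx[count]].sum(axis=1)
            sel = np.array(idxs, dtype=np.intp)
            exceed[sel] += strengths >= orig[sel] * (1.0 - _TIE_EPS) - _TIE_EPS
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    return [replace(c, p_value=float(p)) for c, p in zip(cliques, pvals)]


def fdr_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values.

    Elementwise q ≥ p, and the order of q follows the order of p.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_q_values(cliques: Sequence[CliqueResult]) -> list[CliqueResult]:
    """FDR-adjust the cliques' permutation p-values in place of q_value."""
    if not cliques:
        return []
    if any(c.p_value is None for c in cliques):
        raise ValueError("all cliques must carry a p_value before adjustment")
    q = fdr_adjust([c.p_value for c in cliques])  # type: ignore[misc]
    return [replace(c, q_value=float(qi)) for c, qi in zip(cliques, q)]


def count_known_connections(clique: CliqueResult, known: KnownAssociationTable) -> int:
    return sum(1 for pair in clique.member_pairs() if pair in known)


def filter_significant(
    cliques: Sequence[CliqueResult],
    known: KnownAssociationTable,
    th_max: float = 0.4,
    alpha: float = 0.05,
) -> list[CliqueResult]:
    """Select the robust cliques, mirroring the published selection rule.

    Keeps cliques that were discovered at a mutual-rank threshold ≤ ``th_max``
    (lower thresholds mean stronger connectivity), contain at least one
    member pair present in the known-association table, and have an
    FDR-adjusted q-value below ``alpha``.  Output order follows input order;
    the empty result is valid.
    """
    out = []
    for c in cliques:
        if c.threshold is None or c.threshold > th_max:
            continue
        n_known = count_known_connections(c, known)
        if n_known < 1:
            continue
        if c.q_value is None or not (c.q_value < alpha):
            continue
        out.append(replace(c, known_connection_count=n_known))
    return out
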