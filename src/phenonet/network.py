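"""Phenotypic network inference.

Turns the signed similarity matrix into a weighted undirected network:

1. **ECDF scaling** — the three metrics (Kendall, Jaccard, KS) have
   incommensurate value distributions, so within each metric stratum the
   absolute similarities are mapped onto (0, 1] by their empirical
   cumulative distribution; the concordance signs pass through untouched.
2. **Mutual-rank pruning** — the scaled network is complete; strong
   connections are selected by keeping edge (i, j) only when each endpoint
   ranks the other within the top fraction ``th`` of its own
   weight-ordered neighbor list.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Mapping
from dataclasses import dataclass, field, replace

import numpy as np

from .signatures import EntityClass, PhenotypicEntity
from .similarity import SimilarityMatrix

__all__ = [
    "PhenotypicNetwork",
    "NetworkSizeReport",
    "scale_weights_ecdf",
    "mutual_rank_subnetwork",
    "network_size_report",
    "neighbors_query",
]


@dataclass
class PhenotypicNetwork:
    """Weighted signed undirected graph over phenotypic entities.

    Edge weights live in (0, 1] (ECDF-scaled similarity magnitudes); each
    edge carries a concordance sign and the metric that produced it.  The
    graph is stored as symmetric arrays plus a boolean adjacency mask; the
    diagonal is never an edge.
    """

    entities: list[PhenotypicEntity]
    weights: np.ndarray  # (n, n) float, symmetric, 0 on diagonal
    signs: np.ndarray  # (n, n) int8 in {+1, -1}
    metrics: np.ndarray  # (n, n) object, metric name per cell
    adjacency: np.ndarray  # (n, n) bool, symmetric, False on diagonal
    threshold: float | None = None  # mutual-rank fraction this graph was pruned at
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        n = len(self.entities)
        for name in ("weights", "signs", "metrics", "adjacency"):
            if getattr(self, name).shape != (n, n):
                raise ValueError(f"{name} must be {n} x {n}")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if self.adjacency.diagonal().any():
            raise ValueError("self-loops are not allowed")
        w = self.weights[self.adjacency]
        if w.size and (w.min() < 0 or w.max() > 1):
            raise ValueError("edge weights must lie in [0, 1]")
        self._index = {e.id: i for i, e in enumerate(self.entities)}
        if len(self._index) != n:
            raise ValueError("duplicate entity ids")

    @property
    def n_nodes(self) -> int:
        return len(self.entities)

    @property
    def n_edges(self) -> int:
        """Stored undirected edges (one per unordered pair)."""
        return int(self.adjacency.sum()) // 2

    def index_of(self, entity_id: str) -> int:
        try:
            return self._index[entity_id]
        except KeyError:
            raise ValueError(f"unknown node id: {entity_id}") from None

    def edge_pairs(self) -> np.ndarray:
        """Array of (i, j) index pairs with i < j for every stored edge."""
        iu, ju = np.where(np.triu(self.adjacency, k=1))
        return np.column_stack([iu, ju])

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def has_edge(self, id_a: str, id_b: str) -> bool:
        return bool(self.adjacency[self.index_of(id_a), self.index_of(id_b)])

    def to_networkx(self):
        """Export as a networkx Graph with class/weight/sign/metric attributes."""
        import networkx as nx

        g = nx.Graph()
        for e in self.entities:
            g.add_node(e.id, entity_class=e.entity_class.value, label=e.label)
        for i, j in self.edge_pairs():
            g.add_edge(
                self.entities[i].id,
                self.entities[j].id,
                weight=float(self.weights[i, j]),
                sign=int(self.signs[i, j]),
                metric=str(self.metrics[i, j]),
            )
        return g


@dataclass(frozen=True)
class NetworkSizeReport:
    """Node counts plus the full-matrix entry count.

    ``n_matrix_entries`` is n_nodes² — every ordered pair including
    self-pairs, the convention the published network size uses — while the
    stored graph keeps a single undirected edge per unordered pair.
    """

    n_nodes: int
    n_matrix_entries: int
    per_class: dict[str, int]

    @classmethod
    def from_class_counts(cls, per_class: Mapping[EntityClass | str, int]) -> "NetworkSizeReport":
        counts = {EntityClass(k).value: int(v) for k, v in per_class.items()}
        n = sum(counts.values())
        return cls(n_nodes=n, n_matrix_entries=n * n, per_class=counts)


def network_size_report(net: PhenotypicNetwork) -> NetworkSizeReport:
    """Size report for a network (see :class:`NetworkSizeReport`)."""
    per_class: dict[str, int] = {c.value: 0 for c in EntityClass}
    for e in net.entities:
        per_class[e.entity_class.value] += 1
    return NetworkSizeReport.from_class_counts(per_class)


def scale_weights_ecdf(matrix: SimilarityMatrix) -> PhenotypicNetwork:
    """Homogenize similarities into edge weights via per-metric ECDF.

    Within each metric stratum (all off-diagonal cells produced by that
    metric), an edge's weight is the empirical CDF of |similarity| evaluated
    at its own |similarity| — i.e. the fraction of stratum values with
    magnitude ≤ its magnitude — giving weights in (0, 1] whose order matches
    the magnitude order.  Signs are copied unchanged from the raw
    similarities (zero similarity gets sign +).  The result is a complete
    network.
    """
    n = matrix.n
    values = matrix.values
    metrics = matrix.metrics
    weights = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    cell_metrics = np.array([str(m) for m in metrics[iu, ju]], dtype=object)
    strata = sorted(set(cell_metrics))
    for metric in strata:
        mask = cell_metrics == metric
        if not mask.any():  # pragma: no cover - defensive
            warnings.warn(f"empty metric stratum: {metric}")
            continue
        mags = np.abs(values[iu[mask], ju[mask]])
        sorted_mags = np.sort(mags)
        w = np.searchsorted(sorted_mags, mags, side="right") / mags.size
        weights[iu[mask], ju[mask]] = w
        weights[ju[mask], iu[mask]] = w
    signs = np.where(values < 0, -1, 1).astype(np.int8)
    adjacency = ~np.eye(n, dtype=bool)
    return PhenotypicNetwork(
        entities=list(matrix.entities),
        weights=weights,
        signs=signs,
        metrics=metrics.copy(),
        adjacency=adjacency,
        threshold=None,
    )


def mutual_rank_subnetwork(net: PhenotypicNetwork, th: float) -> PhenotypicNetwork:
    """Keep edge (i, j) only when i and j mutually rank each other on top.

    Each node ranks its current neighbors by weight, descending; the edge
    survives iff j is within the top ⌈th·deg(i)⌉ of i's list *and* i is
    within the top ⌈th·deg(j)⌉ of j's.  Neighbors whose weight ties the
    boundary weight are all retained, which keeps the rule symmetric and
    deterministic.  Lower ``th`` means stronger connections.
    """
    if not (0.0 < th <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {th!r}")
    n = net.n_nodes
    keep_one_sided = np.zeros((n, n), dtype=bool)
    for i in range(n):
        nbrs = np.where(net.adjacency[i])[0]
        if nbrs.size == 0:
            continue
        k = math.ceil(th * nbrs.size)
        w = net.weights[i, nbrs]
        cutoff = np.sort(w)[::-1][k - 1]
        keep_one_sided[i, nbrs[w >= cutoff]] = True
    adjacency = keep_one_sided & keep_one_sided.T
    return replace(net, adjacency=adjacency, threshold=th)


def neighbors_query(
    net: PhenotypicNetwork, node_id: str, th: float | None = None
) -> dict[str, list[tuple[str, float, int]]]:
    """Mutual-rank neighbors of a node, partitioned by entity class.

    Returns a mapping class name -> list of (neighbor id, weight, sign),
    sorted by weight descending, for all four classes (possibly empty).  If
    ``th`` is given the network is pruned at that threshold first.
    """
    i = net.index_of(node_id)  # raises for unknown nodes
    if th is not None:
        net = mutual_rank_subnetwork(net, th)
    groups: dict[str, list[tuple[str, float, int]]] = {c.value: [] for c in EntityClass}
    for j in np.where(net.adjacency[i])[0]:
        e = net.entities[j]
        groups[e.entity_class.value].append(
            (e.id, float(net.weights[i, j]), int(net.signs[i, j]))
        )
    for lst in groups.values():
        lst.sort(key=lambda t: (-t[1], t[0]))
    return groups
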