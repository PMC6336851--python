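"""Signed pairwise tMOA similarity.

The metric for a pair of entities is dictated by their signature kinds:

========================  =====================  =========
pair                      metric                 range
========================  =====================  =========
gene set vs gene set      signed Jaccard         [-1, 1]
ranking vs ranking        normalized Kendall tau [-1, 1]
ranking vs gene set       signed KS (GSEA-style) [-1, 1]
========================  =====================  =========

All three carry a concordance sign: negative values mean the two signatures
alter shared genes in opposite directions (a drug counteracting a disease,
say), positive values mean they push the same genes the same way.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence, Set
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signatures import (
    GeneSetSignature,
    PhenotypicEntity,
    RankedSignature,
    Signature,
    signature_for_class,
)

__all__ = [
    "METRIC_JACCARD",
    "METRIC_KENDALL",
    "METRIC_KS",
    "jaccard",
    "signed_jaccard",
    "kendall_tau_raw",
    "kendall_tau_normalized",
    "signed_ks_statistic",
    "directional_ks_similarity",
    "SimilarityMatrix",
    "compute_similarity_matrix",
    "metric_for_pair",
]

METRIC_JACCARD = "jaccard"
METRIC_KENDALL = "kendall"
METRIC_KS = "ks"


def jaccard(a: Set[str], b: Set[str]) -> float:
    """Plain Jaccard index |A∩B| / |A∪B| in [0, 1].

    0 when the sets are disjoint, 1 when they contain exactly the same
    elements; symmetric.  Both sets empty is degenerate and rejected.
    """
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(a & b) / len(union)


def signed_jaccard(sig_a: GeneSetSignature, sig_b: GeneSetSignature) -> float:
    """Direction-aware Jaccard similarity of two gene-set signatures.

    Each signature is viewed as a ±1-signed gene vector; the score is

        (shared genes altered the same way − shared genes altered oppositely)
        ─────────────────────────────────────────────────────────────────────
                 genes appearing in either signature (union size)

    It reduces to the plain Jaccard index when only up sets exist, reaches +1
    only for identical signatures, −1 for exactly direction-swapped ones, and
    always lies in [−1, 1].
    """
    agree = len(sig_a.up_genes & sig_b.up_genes) + len(sig_a.down_genes & sig_b.down_genes)
    disagree = len(sig_a.up_genes & sig_b.down_genes) + len(
        sig_a.down_genes & sig_b.up_genes
    )
    union = len(sig_a.genes | sig_b.genes)
    # GeneSetSignature guarantees each signature non-empty, so union > 0
    return (agree - disagree) / union


def _count_inversions(seq: np.ndarray) -> int:
    """Number of inversions in ``seq`` (merge-sort, O(n log n))."""
    n = seq.size
    if n < 2:
        return 0
    arr = seq.astype(np.int64, copy=True)
    buf = np.empty_like(arr)
    total = 0
    width = 1
    while width < n:
        for lo in range(0, n, 2 * width):
            mid = min(lo + width, n)
            hi = min(lo + 2 * width, n)
            if mid >= hi:
                continue
            i, j, k = lo, mid, lo
            while i < mid and j < hi:
                if arr[i] <= arr[j]:
                    buf[k] = arr[i]
                    i += 1
                else:
                    buf[k] = arr[j]
                    j += 1
                    total += mid - i  # arr[i:mid] all exceed arr[j]
                k += 1
            if i < mid:
                buf[k:hi] = arr[i:mid]
            else:
                buf[k:hi] = arr[j:hi]
            arr[lo:hi] = buf[lo:hi]
        width *= 2
    return int(total)


def _check_same_universe(t1: RankedSignature, t2: RankedSignature) -> None:
    if t1.universe != t2.universe:
        raise ValueError(
            f"ranked signatures {t1.entity.id} and {t2.entity.id} "
            "are over different gene universes"
        )


def kendall_tau_raw(t1: RankedSignature, t2: RankedSignature) -> int:
    """Kendall tau distance: unordered gene pairs ranked in opposite order.

    0 when the two orderings are identical; n(n−1)/2 (every pair discordant)
    when one is the exact reversal of the other.
    """
    _check_same_universe(t1, t2)
    pos2 = t2.positions()
    # positions of T2, visited in T1 order: discordant pairs become inversions
    seq = pos2[t1.order_indices()]
    return _count_inversions(seq)


def kendall_tau_normalized(t1: RankedSignature, t2: RankedSignature) -> float:
    """Kendall distance mapped linearly onto [−1, 1].

    The raw distance K is normalized by its attainable maximum
    K_max = n(n−1)/2, giving 1 − 2·K/K_max: identical orderings map to +1,
    exactly reversed orderings to −1.
    """
    _check_same_universe(t1, t2)
    n = t1.universe.size
    if n < 2:
        raise ValueError("Kendall normalization undefined for universe size < 2")
    k_max = n * (n - 1) // 2
    return 1.0 - 2.0 * kendall_tau_raw(t1, t2) / k_max


def signed_ks_statistic(ranked: RankedSignature, geneset: Set[str]) -> float:
    """Kolmogorov–Smirnov statistic of a gene set against a ranking, signed.

    Compares the empirical distribution F_n of the set members' rank
    positions (1 = most up-regulated) with the uniform reference F(x) = x/N
    over positions, and returns F_n − F at the point of largest absolute
    deviation — the KS statistic without the absolute value, so the sign
    says where the set concentrates: positive at the top of the ranking
    (up-regulated), negative at the bottom (down-regulated).

    The deviation is evaluated at every member position and just before each
    one (the extremes of the step functions); ties in |deviation| resolve
    toward the earlier position.
    """
    geneset = set(geneset)
    if not geneset:
        raise ValueError("empty gene set")
    n_total = ranked.universe.size
    if n_total < 2:
        raise ValueError("universe size must be at least 2")
    idx = ranked.universe.indices(geneset)  # raises listing unknown genes
    pos = np.sort(ranked.positions()[idx])  # 1-based, ascending
    m = pos.size
    i = np.arange(1, m + 1)
    # D(x) = F_n(x) - x/N at x = p_i (just after the step) and x = p_i - 1
    d_at = i / m - pos / n_total
    d_before = (i - 1) / m - (pos - 1) / n_total
    xs = np.concatenate([pos, pos - 1])
    ds = np.concatenate([d_at, d_before])
    # max |D| first; |D| quantized so float-noise ties resolve to the earlier x
    order = np.lexsort((xs, -np.round(np.abs(ds), 12)))
    return float(ds[order[0]])


def directional_ks_similarity(ranked: RankedSignature, sig: GeneSetSignature) -> float:
    """GSEA-style similarity between a ranking and a directional gene set.

    Combines the signed KS statistics of the up and down sets as
    (D_up − D_down) / 2 (connectivity-map convention): positive when up
    genes sit high in the ranking and down genes sit low, +1 only at maximal
    concordance of both.  If only one direction is present, its single
    signed statistic is returned unscaled (negated for the down set), which
    keeps the full dynamic range for single-direction signatures.
    """
    sig.validate_universe(ranked.universe)
    d_up = signed_ks_statistic(ranked, sig.up_genes) if sig.up_genes else None
    d_down = signed_ks_statistic(ranked, sig.down_genes) if sig.down_genes else None
    if d_up is not None and d_down is not None:
        return (d_up - d_down) / 2.0
    if d_up is not None:
        return d_up
    return -d_down  # type: ignore[operator]


_METRIC_BY_KINDS = {
    (True, True): METRIC_KENDALL,
    (False, False): METRIC_JACCARD,
    (True, False): METRIC_KS,
    (False, True): METRIC_KS,
}


def metric_for_pair(a: PhenotypicEntity, b: PhenotypicEntity) -> str:
    """Metric name dictated by the two entity classes."""
    return _METRIC_BY_KINDS[(a.is_ranked, b.is_ranked)]


def _pair_similarity(sig_a: Signature, sig_b: Signature) -> float:
    if isinstance(sig_a, RankedSignature) and isinstance(sig_b, RankedSignature):
        return kendall_tau_normalized(sig_a, sig_b)
    if isinstance(sig_a, GeneSetSignature) and isinstance(sig_b, GeneSetSignature):
        return signed_jaccard(sig_a, sig_b)
    if isinstance(sig_a, RankedSignature):
        return directional_ks_similarity(sig_a, sig_b)  # type: ignore[arg-type]
    return directional_ks_similarity(sig_b, sig_a)  # type: ignore[arg-type]


@dataclass
class SimilarityMatrix:
    """Square symmetric signed similarity over all entities.

    ``values[i, j]`` is the class-dispatched similarity of entities i and j;
    ``metrics[i, j]`` records which metric produced it.
    """

    entities: list[PhenotypicEntity]
    values: np.ndarray
    metrics: np.ndarray  # dtype=object, metric name per cell
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        n = len(self.entities)
        if self.values.shape != (n, n) or self.metrics.shape != (n, n):
            raise ValueError("similarity/metric arrays must be n x n")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix must be symmetric")
        self._index = {e.id: i for i, e in enumerate(self.entities)}
        if len(self._index) != n:
            raise ValueError("duplicate entity ids")

    @property
    def n(self) -> int:
        return len(self.entities)

    def index_of(self, entity_id: str) -> int:
        return self._index[entity_id]

    def value(self, id_a: str, id_b: str) -> float:
        return float(self.values[self._index[id_a], self._index[id_b]])

    def metric(self, id_a: str, id_b: str) -> str:
        return str(self.metrics[self._index[id_a], self._index[id_b]])

    def to_dataframe(self) -> pd.DataFrame:
        ids = [e.id for e in self.entities]
        return pd.DataFrame(self.values, index=ids, columns=ids)


def compute_similarity_matrix(
    entities: Sequence[PhenotypicEntity],
    signatures: Mapping[str, Signature],
) -> SimilarityMatrix:
    """All pairwise signed similarities, metric dispatched on class pair.

    Every entity must carry exactly one signature of the kind its class
    requires (nanomaterials and drugs a ranking, chemicals and diseases a
    directional gene set); entities without one are rejected by id.
    """
    entities = list(entities)
    sigs = {e.id: signature_for_class(signatures, e) for e in entities}
    n = len(entities)
    values = np.ones((n, n))
    metrics = np.empty((n, n), dtype=object)
    for i, a in enumerate(entities):
        metrics[i, i] = metric_for_pair(a, a)
        for j in range(i + 1, n):
            b = entities[j]
            v = _pair_similarity(sigs[a.id], sigs[b.id])
            values[i, j] = values[j, i] = v
            metrics[i, j] = metrics[j, i] = metric_for_pair(a, b)
    return SimilarityMatrix(entities=entities, values=values, metrics=metrics)
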