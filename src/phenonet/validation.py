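"""Independent-evidence validation.

The tMOA-derived similarities can be checked against evidence that has
nothing to do with transcription: chemical structure strings, curated
drug–disease / chemical–disease association tables, symptom-based disease
similarities.  Three tools implement this layer:

* :func:`mantel_test` — permutation correlation between two similarity
  matrices over the same entities;
* :func:`osa_distance` / :func:`osa_similarity_matrix` — optimal string
  alignment (restricted Damerau–Levenshtein) similarity for structure
  strings;
* :func:`ks_known_vs_unknown` — two-sample Kolmogorov–Smirnov comparison of
  network edge weights for known versus unknown associations of a class
  pair.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats

__all__ = [
    "ExternalSimilarityMatrix",
    "KnownAssociationTable",
    "MantelResult",
    "KsResult",
    "mantel_test",
    "osa_distance",
    "osa_similarity_matrix",
    "ks_known_vs_unknown",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KnownAssociationTable:
    """Binary known associations: a set of unordered entity-id pairs."""

    pairs: frozenset[frozenset[str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "KnownAssociationTable":
        out = set()
        for a, b in pairs:
            if a == b:
                raise ValueError(f"self-pair not allowed: {a!r}")
            out.add(frozenset((str(a), str(b))))
        return cls(pairs=frozenset(out))

    def __contains__(self, pair) -> bool:
        return frozenset(pair) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def to_tuples(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(p)) for p in self.pairs)


@dataclass
class ExternalSimilarityMatrix:
    """Square symmetric similarity matrix from an independent data source."""

    entities: list[str]
    values: np.ndarray
    source: str = "external"
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        n = len(self.entities)
        self.entities = [str(e) for e in self.entities]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise ValueError("values must be square over the entities")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("external similarity matrix must be symmetric")
        self._index = {e: i for i, e in enumerate(self.entities)}
        if len(self._index) != n:
            raise ValueError("duplicate entity ids")

    def restrict_to(self, ids: Iterable[str]) -> "ExternalSimilarityMatrix":
        """Submatrix over ``ids`` ∩ entities, in the order of ``ids``.

        Unmatched ids are dropped with a logged count so validation can
        proceed on the resolvable overlap.
        """
        ids = list(ids)
        matched = [i for i in ids if i in self._index]
        dropped = len(ids) - len(matched)
        if dropped:
            logger.info("%s: dropped %d unmatched entities", self.source, dropped)
        idx = [self._index[i] for i in matched]
        return ExternalSimilarityMatrix(
            entities=matched, values=self.values[np.ix_(idx, idx)], source=self.source
        )


class MantelResult(NamedTuple):
    r: float
    p_value: float
    n: int


class KsResult(NamedTuple):
    statistic: float
    p_value: float
    direction: str  # "known_higher" or "known_lower"


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel_test(
    m1: np.ndarray,
    m2: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> MantelResult:
    """Mantel permutation test of correlation between two similarity matrices.

    r is the Pearson correlation of the vectorized upper-triangular
    off-diagonal entries.  The null distribution permutes the rows and
    columns of ``m2`` jointly (relabelling its entities), and

        p = (1 + #{permuted r at least as extreme}) / (n_perm + 1).

    ``alternative`` is ``"two-sided"`` (extreme means |r_perm| ≥ |r|; the
    default, since validation claims concern the existence of concordance)
    or ``"greater"`` (r_perm ≥ r).
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape or m1.ndim != 2 or m1.shape[0] != m1.shape[1]:
        raise ValueError("matrices must be square and of equal dimension")
    n = m1.shape[0]
    if n < 3:
        raise ValueError("Mantel test requires dimension >= 3")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("two-sided", "greater"):
        raise ValueError(f"unknown alternative: {alternative!r}")
    x = _upper(m1)
    iu = np.triu_indices(n, k=1)
    y = m2[iu]
    r = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng([seed, 0x4D414E54])  # stream label "MANT"
    xc = x - x.mean()
    xs = xc / np.sqrt((xc**2).sum())
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        yp = m2[np.ix_(idx, idx)][iu]
        yc = yp - yp.mean()
        denom = np.sqrt((yc**2).sum())
        rp = float(xs @ yc / denom) if denom > 0 else 0.0
        if alternative == "two-sided":
            count += abs(rp) >= abs(r) - 1e-12
        else:
            count += rp >= r - 1e-12
    p = (1.0 + count) / (n_perm + 1.0)
    return MantelResult(r=r, p_value=p, n=n)


def osa_distance(s1: str, s2: str) -> int:
    """Optimal string alignment (restricted Damerau–Levenshtein) distance.

    Minimal number of insertions, deletions, substitutions and adjacent
    transpositions transforming ``s1`` into ``s2``, with no substring edited
    twice.  Symmetric; 0 iff the strings are equal.
    """
    n1, n2 = len(s1), len(s2)
    if n1 == 0:
        return n2
    if n2 == 0:
        return n1
    prev2: list[int] = []
    prev = list(range(n2 + 1))
    for i in range(1, n1 + 1):
        cur = [i] + [0] * n2
        for j in range(1, n2 + 1):
            cost = 0 if s1[i - 1] == s2[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                i > 1
                and j > 1
                and s1[i - 1] == s2[j - 2]
                and s1[i - 2] == s2[j - 1]
            ):
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        prev2, prev = prev, cur
    return prev[n2]


def osa_similarity_matrix(
    strings: Mapping[str, str], source: str = "structure"
) -> ExternalSimilarityMatrix:
    """Pairwise structure-string similarity 1 − d/max(len₁, len₂).

    The length normalization bounds values in [0, 1]; the diagonal is 1
    (two empty strings also count as identical).  Entities mapped to
    non-string values are dropped with a log entry.
    """
    ids = []
    for k, v in strings.items():
        if not isinstance(v, str):
            logger.info("%s: dropping entity %r without a structure string", source, k)
            continue
        ids.append(str(k))
    n = len(ids)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = strings[ids[i]], strings[ids[j]]
            maxlen = max(len(a), len(b))
            sim = 1.0 if maxlen == 0 else 1.0 - osa_distance(a, b) / maxlen
            values[i, j] = values[j, i] = sim
    return ExternalSimilarityMatrix(entities=ids, values=values, source=source)


def ks_known_vs_unknown(
    net,
    known: KnownAssociationTable,
    class_pair: tuple[str, str],
) -> KsResult:
    """Two-sample KS test: edge weights of known vs unknown associations.

    Collects the network weights of every pair of entities whose classes
    match ``class_pair`` (unordered), splits them by membership in the
    known-association table, and compares the two weight distributions.
    Both groups must be non-empty.  ``direction`` records which group sits
    higher (by mean weight).
    """
    from .signatures import EntityClass

    ca, cb = (EntityClass(c) for c in class_pair)
    idx_a = [i for i, e in enumerate(net.entities) if e.entity_class == ca]
    idx_b = [i for i, e in enumerate(net.entities) if e.entity_class == cb]
    known_w, unknown_w = [], []
    seen = set()
    for i in idx_a:
        for j in idx_b:
            if i == j or frozenset((i, j)) in seen:
                continue
            seen.add(frozenset((i, j)))
            w = float(net.weights[i, j])
            pair = (net.entities[i].id, net.entities[j].id)
            (known_w if pair in known else unknown_w).append(w)
    if not known_w or not unknown_w:
        raise ValueError(
            f"degenerate split for {class_pair}: known={len(known_w)}, "
            f"unknown={len(unknown_w)}"
        )
    res = stats.ks_2samp(known_w, unknown_w)
    direction = "known_higher" if np.mean(known_w) > np.mean(unknown_w) else "known_lower"
    logger.info(
        "KS %s vs %s: D=%.4f p=%.3g (%s)", ca.value, cb.value, res.statistic, res.pvalue, direction
    )
    return KsResult(statistic=float(res.statistic), p_value=float(res.pvalue), direction=direction)
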