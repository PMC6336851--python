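"""Entity and signature data model.

A phenotypic entity (an engineered nanomaterial, a drug, a chemical or a
disease) is represented solely by its transcriptional mechanism-of-action
(tMOA) signature.  Two signature kinds exist:

* :class:`GeneSetSignature` — directional gene sets (up-regulated and
  down-regulated genes), used for chemicals and diseases, typically curated
  from toxicogenomics databases.
* :class:`RankedSignature` — a total ordering of a shared gene universe by a
  signed differential-expression score, used for nanomaterials and drugs,
  derived from (gene, logFC, p-value) tables.

All signatures in one analysis refer to a single :class:`GeneUniverse`; gene
and entity identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "EntityClass",
    "RANKED_CLASSES",
    "GENESET_CLASSES",
    "GeneUniverse",
    "PhenotypicEntity",
    "GeneSetSignature",
    "ScoredGeneTable",
    "RankedSignature",
    "compute_rank_score",
    "build_ranked_signature",
]


class EntityClass(str, Enum):
    """The four phenotypic entity classes of the network."""

    ENM = "enm"
    DRUG = "drug"
    CHEMICAL = "chemical"
    DISEASE = "disease"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Classes whose tMOA is a full gene ranking (transcriptomics-derived).
RANKED_CLASSES = frozenset({EntityClass.ENM, EntityClass.DRUG})
#: Classes whose tMOA is a directional gene set (database-curated).
GENESET_CLASSES = frozenset({EntityClass.CHEMICAL, EntityClass.DISEASE})


class GeneUniverse:
    """Ordered collection of unique gene identifiers shared by all signatures.

    Ranked signatures must cover the universe exactly; gene-set signatures
    must be subsets of it.
    """

    __slots__ = ("genes", "_index")

    def __init__(self, genes: Iterable[str]):
        genes = tuple(str(g) for g in genes)
        if len(genes) != len(set(genes)):
            seen: set[str] = set()
            dups = sorted({g for g in genes if g in seen or seen.add(g)})
            raise ValueError(f"duplicate gene identifiers in universe: {dups[:10]}")
        if not genes:
            raise ValueError("gene universe must be non-empty")
        self.genes = genes
        self._index = {g: i for i, g in enumerate(genes)}

    @property
    def size(self) -> int:
        return len(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def __iter__(self):
        return iter(self.genes)

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def indices(self, genes: Iterable[str]) -> np.ndarray:
        """Universe indices of ``genes``; raises listing unknown identifiers."""
        missing = [g for g in genes if g not in self._index]
        if missing:
            raise ValueError(f"genes outside the universe: {sorted(missing)[:10]}")
        return np.fromiter((self._index[g] for g in genes), dtype=np.intp)

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneUniverse) and self.genes == other.genes

    def __hash__(self) -> int:
        return hash(self.genes)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneUniverse(N={self.size})"


@dataclass(frozen=True)
class PhenotypicEntity:
    """A node of the phenotypic network."""

    id: str
    entity_class: EntityClass
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "entity_class", EntityClass(self.entity_class))

    @property
    def is_ranked(self) -> bool:
        return self.entity_class in RANKED_CLASSES


@dataclass(frozen=True)
class GeneSetSignature:
    """Directional gene sets representing a chemical's or disease's tMOA."""

    entity: PhenotypicEntity
    up_genes: frozenset[str]
    down_genes: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "up_genes", frozenset(self.up_genes))
        object.__setattr__(self, "down_genes", frozenset(self.down_genes))
        overlap = self.up_genes & self.down_genes
        if overlap:
            raise ValueError(
                f"{self.entity.id}: genes in both up and down sets: {sorted(overlap)[:10]}"
            )
        if not self.up_genes and not self.down_genes:
            raise ValueError(f"{self.entity.id}: both directional sets are empty")

    @property
    def genes(self) -> frozenset[str]:
        return self.up_genes | self.down_genes

    def validate_universe(self, universe: GeneUniverse) -> None:
        outside = [g for g in self.genes if g not in universe]
        if outside:
            raise ValueError(
                f"{self.entity.id}: genes outside the universe: {sorted(outside)[:10]}"
            )

    def swapped(self) -> "GeneSetSignature":
        """Direction-swapped copy (up and down exchanged)."""
        return GeneSetSignature(self.entity, self.down_genes, self.up_genes)


@dataclass(frozen=True)
class ScoredGeneTable:
    """Differential-expression table (gene, logFC, pval) for one entity.

    ``pval`` must lie in [0, 1]; exact zeros are floored downstream (see
    :func:`build_ranked_signature`), keeping ranks intact.
    """

    entity: PhenotypicEntity
    table: pd.DataFrame = field(repr=False)

    REQUIRED_COLUMNS = ("gene", "logFC", "pval")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"{self.entity.id}: missing columns {missing}")
        tab = self.table.loc[:, list(self.REQUIRED_COLUMNS)].copy()
        tab["gene"] = tab["gene"].astype(str)
        logfc = pd.to_numeric(tab["logFC"])
        pval = pd.to_numeric(tab["pval"])
        bad = tab.loc[~np.isfinite(logfc), "gene"]
        if len(bad):
            raise ValueError(
                f"{self.entity.id}: non-finite logFC for genes {list(bad[:10])}"
            )
        bad = tab.loc[~(np.isfinite(pval) & (pval >= 0) & (pval <= 1)), "gene"]
        if len(bad):
            raise ValueError(
                f"{self.entity.id}: p-values outside [0, 1] for genes {list(bad[:10])}"
            )
        tab["logFC"] = logfc.astype(float)
        tab["pval"] = pval.astype(float)
        object.__setattr__(self, "table", tab)

    def floored_pvalues(self) -> np.ndarray:
        """P-values with exact zeros floored to half the smallest positive value.

        Preserves rank order while avoiding infinite scores.  Falls back to
        the smallest positive normal float when every p-value is zero.
        """
        p = self.table["pval"].to_numpy(copy=True)
        zeros = p == 0.0
        if zeros.any():
            positive = p[~zeros]
            floor = 0.5 * positive.min() if positive.size else float(np.finfo(float).tiny)
            p[zeros] = floor
        return p


def compute_rank_score(logfc: float, pval: float, base: float = 10.0) -> float:
    """Signed differential-expression rank score ``±logFC · −log(Pval)``.

    The sign equals the sign of the fold change; the magnitude grows with
    |logFC| and with the evidence −log(p).  The logarithm base (default 10)
    only rescales scores positively, so the induced gene ranking — the
    quantity every downstream step consumes — is base-invariant.
    """
    logfc = float(logfc)
    pval = float(pval)
    if not np.isfinite(logfc):
        raise ValueError(f"non-finite logFC: {logfc!r}")
    if not (0.0 < pval <= 1.0):
        raise ValueError(f"p-value outside (0, 1]: {pval!r}")
    return logfc * (-np.log(pval) / np.log(base))


@dataclass(frozen=True)
class RankedSignature:
    """Total ordering of the gene universe: most up-regulated first."""

    entity: PhenotypicEntity
    universe: GeneUniverse
    order: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self):
        order = tuple(self.order)
        scores = tuple(float(s) for s in self.scores)
        if len(order) != self.universe.size or set(order) != set(self.universe.genes):
            extra = sorted(set(order) - set(self.universe.genes))
            missing = sorted(set(self.universe.genes) - set(order))
            raise ValueError(
                f"{self.entity.id}: order is not a permutation of the universe "
                f"(missing {missing[:5]}, extra {extra[:5]})"
            )
        if len(scores) != len(order):
            raise ValueError(f"{self.entity.id}: scores/order length mismatch")
        if any(scores[i] < scores[i + 1] for i in range(len(scores) - 1)):
            raise ValueError(f"{self.entity.id}: scores not non-increasing along order")
        object.__setattr__(self, "order", order)
        object.__setattr__(self, "scores", scores)

    def positions(self) -> np.ndarray:
        """1-based rank position of each universe gene (universe order)."""
        pos = np.empty(self.universe.size, dtype=np.intp)
        for rank, gene in enumerate(self.order, start=1):
            pos[self.universe.index_of(gene)] = rank
        return pos

    def order_indices(self) -> np.ndarray:
        """Universe index of the gene at each rank."""
        return self.universe.indices(self.order)

    def reversed(self) -> "RankedSignature":
        """Signature with the exact opposite ordering (scores negated)."""
        return RankedSignature(
            self.entity,
            self.universe,
            tuple(reversed(self.order)),
            tuple(-s for s in reversed(self.scores)),
        )


def build_ranked_signature(
    table: ScoredGeneTable, universe: GeneUniverse, base: float = 10.0
) -> RankedSignature:
    """Rank the universe by the signed score ``logFC · −log(p)``, descending.

    The table must cover the universe exactly (one row per gene).  Ties are
    broken by gene identifier, lexicographically, for cross-platform
    determinism; rebuilding from the same table is bitwise reproducible.
    """
    genes = table.table["gene"]
    counts = genes.value_counts()
    dups = sorted(counts.index[counts > 1])
    if dups:
        raise ValueError(f"{table.entity.id}: duplicate genes in table: {dups[:10]}")
    gene_set = set(genes)
    missing = sorted(set(universe.genes) - gene_set)
    extra = sorted(gene_set - set(universe.genes))
    if missing or extra:
        raise ValueError(
            f"{table.entity.id}: table does not cover the universe exactly "
            f"(missing {missing[:10]}, extra {extra[:10]})"
        )
    pvals = table.floored_pvalues()
    logfc = table.table["logFC"].to_numpy()
    scores = logfc * (-np.log(pvals) / np.log(base))
    gene_arr = genes.to_numpy()
    # lexsort: primary key score descending, secondary gene id ascending
    order_idx = np.lexsort((gene_arr, -scores))
    return RankedSignature(
        entity=table.entity,
        universe=universe,
        order=tuple(gene_arr[order_idx]),
        scores=tuple(scores[order_idx]),
    )


Signature = GeneSetSignature | RankedSignature


def signature_for_class(
    signatures: Mapping[str, "Signature"], entity: PhenotypicEntity
) -> "Signature":
    """Fetch and type-check the signature an entity's class requires."""
    try:
        sig = signatures[entity.id]
    except KeyError:
        raise ValueError(f"entity without signature: {entity.id}") from None
    if entity.is_ranked and not isinstance(sig, RankedSignature):
        raise ValueError(f"{entity.id} ({entity.entity_class}) requires a RankedSignature")
    if not entity.is_ranked and not isinstance(sig, GeneSetSignature):
        raise ValueError(f"{entity.id} ({entity.entity_class}) requires a GeneSetSignature")
    return sig
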