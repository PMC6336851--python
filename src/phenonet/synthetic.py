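"""Synthetic signature collections with planted block structure.

The generator emulates the statistical structure the network framework
assumes: a shared gene universe, four entity classes (two represented by
gene rankings, two by directional gene sets), and *blocks* of entities with
concordant transcriptional mechanisms.  Each block owns a template gene
ranking; the block's up- and down-regulated gene-set templates are drawn
from the extremes of that ranking, so that within a block all three
similarity channels are planted coherently:

* rankings of block members are noisy copies of the template order
  (adjacent-swap noise — Kendall distance counts exactly such inversions);
* gene sets of block members share a fraction ρ of the template sets;
* gene sets concentrate at the top/bottom of the block members' rankings.

Anti-correlated entities receive the reversed template order or swapped
directional sets, planting negative similarities.  A truth table records
every planted relation so downstream recovery can be scored.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signatures import (
    GENESET_CLASSES,
    EntityClass,
    GeneSetSignature,
    GeneUniverse,
    PhenotypicEntity,
    RankedSignature,
    Signature,
)
from .validation import KnownAssociationTable

__all__ = [
    "SimulationConfig",
    "SyntheticCollection",
    "generate_collection",
    "generate_known_associations",
]

#: fraction of the ranking's extremes from which set templates are drawn
_TEMPLATE_POOL_FRACTION = 0.15


def _stream(seed: int, label: str, index: int = 0) -> np.random.Generator:
    """Independent generator for (seed, stage label, item index)."""
    return np.random.default_rng([int(seed), zlib.crc32(label.encode()), int(index)])


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic collection.

    Defaults describe a desk-scale version of the real integration: a
    200-gene shared universe, 6 entities per class, 2 planted blocks with
    within-block set overlap ρ = 0.8, rank noise 0.1 (fraction of the
    n(n−1)/2 adjacent swaps applied to the template order) and 20-gene up
    and down sets.
    """

    n_genes: int = 200
    n_per_class: int = 6
    n_blocks: int = 2
    rho: float = 0.8
    anti_fraction: float = 0.0
    set_size_up: int = 20
    set_size_down: int = 20
    rank_noise: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 4 or self.n_per_class < 1 or self.n_blocks < 1:
            raise ValueError("counts must be positive (and universe size >= 4)")
        for name in ("rho", "anti_fraction", "rank_noise"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.set_size_up < 1 or self.set_size_down < 1:
            raise ValueError("set sizes must be positive")
        pool = self.template_pool_size
        if 2 * pool > self.n_genes:
            raise ValueError(
                f"up and down template pools ({pool} genes each) must be disjoint "
                "within the universe; increase n_genes or shrink the sets"
            )
        if round(self.rho * max(self.set_size_up, self.set_size_down)) > self.n_genes:
            raise ValueError("infeasible overlap: rho * set size exceeds universe size")
        if self.set_size_up + self.set_size_down >= self.n_genes:
            raise ValueError("up and down sets must leave free genes in the universe")

    @property
    def template_pool_size(self) -> int:
        return max(
            self.set_size_up,
            self.set_size_down,
            int(np.ceil(_TEMPLATE_POOL_FRACTION * self.n_genes)),
        )


@dataclass
class SyntheticCollection:
    """A generated collection plus its planted-structure truth table."""

    config: SimulationConfig
    universe: GeneUniverse
    entities: list[PhenotypicEntity]
    signatures: dict[str, Signature]
    membership: pd.DataFrame  # columns: entity_id, entity_class, block, anti

    def block_of(self, entity_id: str) -> int:
        row = self.membership.loc[self.membership["entity_id"] == entity_id]
        return int(row["block"].iloc[0])

    def within_block_cross_class_pairs(self, concordant_only: bool = True) -> list[tuple[str, str]]:
        """Planted cross-class relations: same block, distinct classes."""
        rows = list(self.membership.itertuples(index=False))
        out = []
        for i, a in enumerate(rows):
            for b in rows[i + 1 :]:
                if a.block != b.block or a.entity_class == b.entity_class:
                    continue
                if concordant_only and a.anti != b.anti:
                    continue
                out.append(tuple(sorted((a.entity_id, b.entity_id))))
        return sorted(out)


def _adjacent_swaps(order: np.ndarray, n_swaps: int, rng: np.random.Generator) -> np.ndarray:
    out = order.copy()
    n = out.size
    if n < 2 or n_swaps == 0:
        return out
    positions = rng.integers(0, n - 1, size=n_swaps)
    for p in positions:
        out[p], out[p + 1] = out[p + 1], out[p]
    return out


def _planted_gene_set(
    template: np.ndarray,
    forbidden: set[str],
    size: int,
    rho: float,
    free_pool: np.ndarray,
    rng: np.random.Generator,
) -> frozenset[str]:
    """ρ·size genes from the template, the rest from the free pool."""
    n_keep = int(round(rho * size))
    n_keep = min(n_keep, size, template.size)
    kept = rng.choice(template, size=n_keep, replace=False) if n_keep else np.array([], dtype=template.dtype)
    fill_pool = np.array([g for g in free_pool if g not in forbidden and g not in set(kept)])
    n_fill = size - n_keep
    filled = rng.choice(fill_pool, size=n_fill, replace=False) if n_fill else np.array([], dtype=template.dtype)
    return frozenset(map(str, np.concatenate([kept, filled])))


def generate_collection(cfg: SimulationConfig) -> SyntheticCollection:
    """Generate signatures for all four classes with planted blocks.

    Deterministic: identical config (including seed) gives bitwise-identical
    output.  Each entity is assigned a block round-robin within its class;
    the configured fraction of entities per class is flagged anti-correlated
    and receives reversed/swapped templates.
    """
    n = cfg.n_genes
    width = len(str(n))
    universe = GeneUniverse(f"g{i + 1:0{width}d}" for i in range(n))
    genes = np.array(universe.genes)

    pool = cfg.template_pool_size
    templates = []
    for b in range(cfg.n_blocks):
        rng = _stream(cfg.seed, "template", b)
        perm = genes[rng.permutation(n)]
        up = perm[:pool][rng.permutation(pool)[: cfg.set_size_up]]
        # bottom-of-ranking pool, kept disjoint from the up template
        up_set = set(up)
        down_pool = np.array([g for g in perm[::-1] if g not in up_set][:pool])
        down = down_pool[rng.permutation(down_pool.size)[: cfg.set_size_down]]
        templates.append({"order": perm, "up": np.sort(up), "down": np.sort(down)})

    max_swaps = n * (n - 1) // 2
    n_swaps = int(round(cfg.rank_noise * max_swaps))
    n_anti = int(round(cfg.anti_fraction * cfg.n_per_class))

    entities: list[PhenotypicEntity] = []
    signatures: dict[str, Signature] = {}
    rows = []
    for cls in EntityClass:
        anti_rng = _stream(cfg.seed, f"anti-{cls.value}")
        anti_idx = set(anti_rng.permutation(cfg.n_per_class)[:n_anti].tolist())
        for k in range(cfg.n_per_class):
            block = k % cfg.n_blocks
            anti = k in anti_idx
            eid = f"{cls.value}-{k + 1:02d}"
            entity = PhenotypicEntity(eid, cls, label=f"synthetic {cls.value} {k + 1}")
            entities.append(entity)
            tpl = templates[block]
            rng = _stream(cfg.seed, f"sig-{cls.value}", k)
            if cls in GENESET_CLASSES:
                tpl_up, tpl_down = (tpl["down"], tpl["up"]) if anti else (tpl["up"], tpl["down"])
                forbidden = set(map(str, np.concatenate([tpl["up"], tpl["down"]])))
                up = _planted_gene_set(tpl_up, forbidden, cfg.set_size_up, cfg.rho, genes, rng)
                down = _planted_gene_set(
                    tpl_down, forbidden | up, cfg.set_size_down, cfg.rho, genes, rng
                )
                signatures[eid] = GeneSetSignature(entity, up_genes=up, down_genes=down)
            else:
                base = tpl["order"][::-1] if anti else tpl["order"]
                order = _adjacent_swaps(base, n_swaps, rng)
                scores = np.arange(n, 0, -1, dtype=float)
                signatures[eid] = RankedSignature(
                    entity, universe, tuple(map(str, order)), tuple(scores)
                )
            rows.append(
                {"entity_id": eid, "entity_class": cls.value, "block": block, "anti": anti}
            )
    membership = pd.DataFrame(rows, columns=["entity_id", "entity_class", "block", "anti"])
    return SyntheticCollection(
        config=cfg,
        universe=universe,
        entities=entities,
        signatures=signatures,
        membership=membership,
    )


def generate_known_associations(
    collection: SyntheticCollection,
    coverage: float,
    seed: int | None = None,
) -> KnownAssociationTable:
    """Sample a fraction of the planted cross-class pairs as "known".

    Mirrors curated association tables (drug–disease, chemical–disease
    prescriptions and exposures): the candidate pool is the within-block,
    concordant, cross-class pairs, of which exactly
    ``round(coverage · n_candidates)`` are drawn without replacement.
    Deterministic for a fixed seed (defaults to the collection's).
    """
    if not (0.0 < coverage <= 1.0):
        raise ValueError(f"coverage must lie in (0, 1], got {coverage!r}")
    candidates = collection.within_block_cross_class_pairs(concordant_only=True)
    if not candidates:
        raise ValueError("truth table has no planted cross-class pairs")
    if seed is None:
        seed = collection.config.seed
    rng = _stream(seed, "known-associations")
    n_take = int(round(coverage * len(candidates)))
    n_take = max(1, n_take)
    idx = np.sort(rng.permutation(len(candidates))[:n_take])
    return KnownAssociationTable.from_pairs([candidates[i] for i in idx])
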