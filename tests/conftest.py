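from __future__ import annotations

import numpy as np
import pytest

from phenonet.network import PhenotypicNetwork
from phenonet.signatures import (
    EntityClass,
    GeneSetSignature,
    GeneUniverse,
    PhenotypicEntity,
    RankedSignature,
)

CLASS_CYCLE = [EntityClass.ENM, EntityClass.DRUG, EntityClass.CHEMICAL, EntityClass.DISEASE]


@pytest.fixture
def universe10() -> GeneUniverse:
    return GeneUniverse([f"g{i:02d}" for i in range(1, 11)])


def make_entity(i: int, cls: EntityClass | None = None) -> PhenotypicEntity:
    cls = cls if cls is not None else CLASS_CYCLE[i % 4]
    return PhenotypicEntity(f"e{i:02d}", cls)


def ranked_from_order(universe: GeneUniverse, order, entity=None) -> RankedSignature:
    """Ranked signature with scores descending along the given order."""
    order = tuple(order)
    entity = entity or PhenotypicEntity(f"rk-{abs(hash(order)) % 10**6}", EntityClass.ENM)
    return RankedSignature(entity, universe, order, tuple(float(len(order) - i) for i in range(len(order))))


def random_ranked(universe: GeneUniverse, rng, entity=None) -> RankedSignature:
    genes = np.array(universe.genes)
    return ranked_from_order(universe, tuple(genes[rng.permutation(len(genes))]), entity)


def random_geneset(universe: GeneUniverse, rng, entity=None, n_up=3, n_down=3) -> GeneSetSignature:
    genes = np.array(universe.genes)
    pick = genes[rng.permutation(len(genes))[: n_up + n_down]]
    entity = entity or PhenotypicEntity(f"gs-{rng.integers(10**6)}", EntityClass.DISEASE)
    return GeneSetSignature(entity, frozenset(pick[:n_up]), frozenset(pick[n_up:]))


def network_from_weights(
    weights: np.ndarray,
    classes=None,
    adjacency: np.ndarray | None = None,
    signs: np.ndarray | None = None,
    threshold: float | None = None,
) -> PhenotypicNetwork:
    """Assemble a PhenotypicNetwork directly from a symmetric weight matrix."""
    n = weights.shape[0]
    entities = [
        make_entity(i, None if classes is None else EntityClass(classes[i])) for i in range(n)
    ]
    metrics = np.empty((n, n), dtype=object)
    metrics[:] = "test"
    if adjacency is None:
        adjacency = ~np.eye(n, dtype=bool)
    if signs is None:
        signs = np.ones((n, n), dtype=np.int8)
    w = weights.copy()
    np.fill_diagonal(w, 0.0)
    return PhenotypicNetwork(
        entities=entities,
        weights=w,
        signs=signs,
        metrics=metrics,
        adjacency=adjacency,
        threshold=threshold,
    )


def random_network(rng, n=12, classes=None, threshold=None) -> PhenotypicNetwork:
    w = rng.uniform(0.01, 1.0, size=(n, n))
    w = np.triu(w, 1)
    w = w + w.T
    return network_from_weights(w, classes=classes, threshold=threshold)
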