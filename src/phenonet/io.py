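"""Readers and writers for the plain-text formats the toolchain uses.

Formats:

* scored gene tables — 3-column header TSV ``gene  logFC  pval``;
* directional gene sets — GMT dialect, one line per direction:
  ``<entityID>_up`` / ``<entityID>_down``, description, gene ids (tab
  separated); an entity missing one suffix gets an empty set for that
  direction;
* entities — TSV ``id  class  label``;
* similarity matrices — square TSV with id header row/column, plus a
  sidecar TSV of per-cell metric names;
* networks — weighted edge-list TSV (source, target, weight, sign, metric)
  and GraphML;
* known associations — 2-column TSV of entity id pairs;
* structure strings — 2-column TSV ``id  string``.

All identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .network import PhenotypicNetwork
from .signatures import (
    EntityClass,
    GeneSetSignature,
    GeneUniverse,
    PhenotypicEntity,
    RankedSignature,
    ScoredGeneTable,
    Signature,
)
from .similarity import SimilarityMatrix
from .validation import ExternalSimilarityMatrix, KnownAssociationTable

__all__ = [
    "read_scored_table",
    "write_scored_table",
    "read_gmt",
    "write_gmt",
    "read_entities",
    "write_entities",
    "write_similarity_matrix",
    "read_similarity_matrix",
    "write_edge_list",
    "read_network",
    "write_graphml",
    "read_known_associations",
    "write_known_associations",
    "read_external_matrix",
    "write_external_matrix",
    "read_structure_strings",
    "write_structure_strings",
]


# ---------------------------------------------------------------- signatures


def read_scored_table(path: str | Path, entity: PhenotypicEntity) -> ScoredGeneTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    return ScoredGeneTable(entity=entity, table=df)


def write_scored_table(table: ScoredGeneTable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path, entity_class: EntityClass | str) -> list[GeneSetSignature]:
    """Parse directional gene sets from a GMT dialect file.

    Lines are ``<entityID>_up`` or ``<entityID>_down``, a free-text
    description, then gene ids, all tab-separated.
    """
    entity_class = EntityClass(entity_class)
    ups: dict[str, set[str]] = {}
    downs: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least name and description")
        name, description, *gene_ids = fields
        if name.endswith("_up"):
            target, eid = ups, name[: -len("_up")]
        elif name.endswith("_down"):
            target, eid = downs, name[: -len("_down")]
        else:
            raise ValueError(f"{path}:{lineno}: set name must end in _up or _down: {name!r}")
        if eid in target:
            raise ValueError(f"{path}:{lineno}: duplicate set for {name!r}")
        target[eid] = {g for g in gene_ids if g}
        labels.setdefault(eid, description)
    out = []
    for eid in sorted(set(ups) | set(downs)):
        entity = PhenotypicEntity(eid, entity_class, label=labels.get(eid, ""))
        out.append(
            GeneSetSignature(
                entity, up_genes=frozenset(ups.get(eid, ())), down_genes=frozenset(downs.get(eid, ()))
            )
        )
    return out


def write_gmt(signatures: Iterable[GeneSetSignature], path: str | Path) -> None:
    lines = []
    for sig in signatures:
        desc = sig.entity.label or sig.entity.id
        if sig.up_genes:
            lines.append("\t".join([f"{sig.entity.id}_up", desc, *sorted(sig.up_genes)]))
        if sig.down_genes:
            lines.append("\t".join([f"{sig.entity.id}_down", desc, *sorted(sig.down_genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_entities(path: str | Path) -> list[PhenotypicEntity]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        PhenotypicEntity(row["id"], EntityClass(row["class"]), row.get("label", ""))
        for _, row in df.iterrows()
    ]


def write_entities(entities: Iterable[PhenotypicEntity], path: str | Path) -> None:
    pd.DataFrame(
        [{"id": e.id, "class": e.entity_class.value, "label": e.label} for e in entities]
    ).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------- similarity matrices


def write_similarity_matrix(
    matrix: SimilarityMatrix, path: str | Path, metrics_path: str | Path | None = None
) -> None:
    ids = [e.id for e in matrix.entities]
    pd.DataFrame(matrix.values, index=ids, columns=ids).to_csv(
        path, sep="\t", index_label="id"
    )
    if metrics_path is not None:
        pd.DataFrame(matrix.metrics, index=ids, columns=ids).to_csv(
            metrics_path, sep="\t", index_label="id"
        )


def read_similarity_matrix(
    path: str | Path, entities: Sequence[PhenotypicEntity], metrics_path: str | Path | None = None
) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col="id")
    ids = [e.id for e in entities]
    values = df.loc[ids, ids].to_numpy(dtype=float)
    if metrics_path is not None:
        metrics = pd.read_csv(metrics_path, sep="\t", index_col="id").loc[ids, ids].to_numpy(
            dtype=object
        )
    else:
        from .similarity import metric_for_pair

        n = len(entities)
        metrics = np.empty((n, n), dtype=object)
        for i, a in enumerate(entities):
            for j, b in enumerate(entities):
                metrics[i, j] = metric_for_pair(a, b)
    return SimilarityMatrix(entities=list(entities), values=values, metrics=metrics)


# ------------------------------------------------------------------ networks


def write_edge_list(net: PhenotypicNetwork, path: str | Path) -> None:
    rows = []
    for i, j in net.edge_pairs():
        rows.append(
            {
                "source": net.entities[i].id,
                "target": net.entities[j].id,
                "weight": float(net.weights[i, j]),
                "sign": int(net.signs[i, j]),
                "metric": str(net.metrics[i, j]),
            }
        )
    pd.DataFrame(rows, columns=["source", "target", "weight", "sign", "metric"]).to_csv(
        path, sep="\t", index=False
    )


def read_network(
    entities_path: str | Path, edges_path: str | Path, threshold: float | None = None
) -> PhenotypicNetwork:
    entities = read_entities(entities_path)
    index = {e.id: i for i, e in enumerate(entities)}
    n = len(entities)
    weights = np.zeros((n, n))
    signs = np.ones((n, n), dtype=np.int8)
    metrics = np.empty((n, n), dtype=object)
    metrics[:] = ""
    adjacency = np.zeros((n, n), dtype=bool)
    df = pd.read_csv(edges_path, sep="\t", dtype={"source": str, "target": str})
    for row in df.itertuples(index=False):
        i, j = index[row.source], index[row.target]
        weights[i, j] = weights[j, i] = float(row.weight)
        signs[i, j] = signs[j, i] = int(row.sign)
        metrics[i, j] = metrics[j, i] = str(row.metric)
        adjacency[i, j] = adjacency[j, i] = True
    return PhenotypicNetwork(
        entities=entities,
        weights=weights,
        signs=signs,
        metrics=metrics,
        adjacency=adjacency,
        threshold=threshold,
    )


def write_graphml(net: PhenotypicNetwork, path: str | Path) -> None:
    import networkx as nx

    nx.write_graphml(net.to_networkx(), str(path))


# ------------------------------------------------------- associations et al.


def read_known_associations(path: str | Path) -> KnownAssociationTable:
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns of entity ids")
    return KnownAssociationTable.from_pairs(
        [(a, b) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]
    )


def write_known_associations(table: KnownAssociationTable, path: str | Path) -> None:
    lines = [f"{a}\t{b}" for a, b in table.to_tuples()]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_external_matrix(path: str | Path, source: str = "external") -> ExternalSimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col="id")
    return ExternalSimilarityMatrix(
        entities=[str(c) for c in df.columns], values=df.to_numpy(dtype=float), source=source
    )


def write_external_matrix(matrix: ExternalSimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(matrix.values, index=matrix.entities, columns=matrix.entities).to_csv(
        path, sep="\t", index_label="id"
    )


def read_structure_strings(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (id, string)")
    return {str(a): str(b) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])}


def write_structure_strings(strings: Mapping[str, str], path: str | Path) -> None:
    lines = [f"{k}\t{v}" for k, v in sorted(strings.items())]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
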