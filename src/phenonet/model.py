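"""Model/Results facade over the network-inference and clique pipeline.

:class:`PhenotypicNetworkModel` is built from a collection of entities and
their tMOA signatures (or directly from a synthetic collection).  Its
:meth:`~PhenotypicNetworkModel.fit` runs the full procedure — pairwise
similarity, ECDF weight scaling, mutual-rank pruning, exhaustive
heterogeneous clique enumeration, permutation testing and FDR adjustment —
and returns a :class:`NetworkCliqueResults` carrying the networks, the
scored cliques and a ``summary()`` table.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cliques import (
    CliqueResult,
    attach_q_values,
    enumerate_heterogeneous_cliques,
    filter_significant,
    permutation_test_cliques,
)
from .network import (
    NetworkSizeReport,
    PhenotypicNetwork,
    mutual_rank_subnetwork,
    network_size_report,
    scale_weights_ecdf,
)
from .signatures import PhenotypicEntity, Signature
from .similarity import SimilarityMatrix, compute_similarity_matrix
from .validation import KnownAssociationTable

__all__ = ["PhenotypicNetworkModel", "NetworkCliqueResults"]


class PhenotypicNetworkModel:
    """Signed phenotypic similarity network over four entity classes.

    Parameters
    ----------
    entities
        The phenotypic entities (nanomaterials, drugs, chemicals, diseases).
    signatures
        Mapping entity id -> signature of the kind the entity's class
        requires (rankings for nanomaterials/drugs, directional gene sets
        for chemicals/diseases).
    """

    def __init__(
        self,
        entities: Sequence[PhenotypicEntity],
        signatures: Mapping[str, Signature],
    ):
        self.entities = list(entities)
        self.signatures = dict(signatures)
        self._similarity: SimilarityMatrix | None = None
        self._network: PhenotypicNetwork | None = None

    @classmethod
    def from_collection(cls, collection) -> "PhenotypicNetworkModel":
        """Build from a :class:`~phenonet.synthetic.SyntheticCollection`."""
        return cls(collection.entities, collection.signatures)

    @property
    def similarity_(self) -> SimilarityMatrix:
        """Raw signed similarity matrix (computed lazily, cached)."""
        if self._similarity is None:
            self._similarity = compute_similarity_matrix(self.entities, self.signatures)
        return self._similarity

    @property
    def network_(self) -> PhenotypicNetwork:
        """Complete ECDF-weighted network (computed lazily, cached)."""
        if self._network is None:
            self._network = scale_weights_ecdf(self.similarity_)
        return self._network

    def fit(
        self,
        th: float = 0.4,
        clique_sizes: Sequence[int] = (4,),
        n_perm: int = 1000,
        alpha: float = 0.05,
        th_max: float | None = None,
        known: KnownAssociationTable | None = None,
        seed: int = 0,
    ) -> "NetworkCliqueResults":
        """Run the clique analysis at mutual-rank threshold ``th``.

        Parameters
        ----------
        th
            Mutual-rank fraction for pruning (lower = stronger edges).
        clique_sizes
            Heterogeneous clique sizes to enumerate (subset of {3, 4}).
        n_perm
            Permutations for the strength null.
        alpha
            FDR level for the significance filter.
        th_max
            Discovery-threshold ceiling for the filter (defaults to ``th``).
        known
            Known-association table; when given, significant cliques must
            contain at least one known member pair.
        seed
            Seed for the permutation streams.
        """
        pruned = mutual_rank_subnetwork(self.network_, th)
        cliques: list[CliqueResult] = []
        for size in clique_sizes:
            cliques.extend(enumerate_heterogeneous_cliques(pruned, size=size, th=th))
        cliques = permutation_test_cliques(self.network_, cliques, n_perm=n_perm, seed=seed)
        cliques = attach_q_values(cliques)
        significant = None
        if known is not None:
            significant = filter_significant(
                cliques, known, th_max=th if th_max is None else th_max, alpha=alpha
            )
        return NetworkCliqueResults(
            model=self,
            network=self.network_,
            pruned=pruned,
            cliques=cliques,
            significant=significant,
            known=known,
            params={
                "th": th,
                "clique_sizes": tuple(clique_sizes),
                "n_perm": n_perm,
                "alpha": alpha,
                "th_max": th if th_max is None else th_max,
                "seed": seed,
            },
        )


@dataclass
class NetworkCliqueResults:
    """Fitted networks, scored cliques and their significance."""

    model: PhenotypicNetworkModel
    network: PhenotypicNetwork  # complete, ECDF-weighted
    pruned: PhenotypicNetwork  # mutual-rank subnetwork at params["th"]
    cliques: list[CliqueResult]
    significant: list[CliqueResult] | None
    known: KnownAssociationTable | None
    params: dict

    @property
    def size_report(self) -> NetworkSizeReport:
        return network_size_report(self.network)

    def cliques_frame(self, significant_only: bool = False) -> pd.DataFrame:
        """Clique table: members, strength, p, q, known-connection count."""
        rows = []
        source = self.significant if significant_only else self.cliques
        for c in source or []:
            rows.append(
                {
                    "members": "|".join(c.members),
                    "classes": "|".join(c.classes),
                    "size": c.size,
                    "strength": c.strength,
                    "signed_strength": c.signed_strength,
                    "threshold": c.threshold,
                    "p_value": c.p_value,
                    "q_value": c.q_value,
                    "known_connections": c.known_connection_count,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "members",
                "classes",
                "size",
                "strength",
                "signed_strength",
                "threshold",
                "p_value",
                "q_value",
                "known_connections",
            ],
        )

    def summary(self, top: int = 10) -> str:
        """Human-readable account of the fitted network and top cliques."""
        rep = self.size_report
        lines = [
            "Phenotypic network clique analysis",
            "=" * 50,
            f"nodes: {rep.n_nodes}  "
            f"(matrix entries: {rep.n_matrix_entries})",
            "per class: "
            + ", ".join(f"{k}={v}" for k, v in sorted(rep.per_class.items())),
            f"edges stored (complete): {self.network.n_edges}; "
            f"after mutual-rank pruning at th={self.params['th']}: {self.pruned.n_edges}",
            f"cliques enumerated: {len(self.cliques)} "
            f"(sizes {self.params['clique_sizes']}, {self.params['n_perm']} permutations)",
        ]
        if self.significant is not None:
            lines.append(
                f"significant cliques (q<{self.params['alpha']}, >=1 known connection, "
                f"th<={self.params['th_max']}): {len(self.significant)}"
            )
        df = self.cliques_frame()
        if len(df):
            show = df.sort_values(["q_value", "p_value", "strength"], ascending=[True, True, False])
            lines.append("")
            lines.append(show.head(top).to_string(index=False, float_format="%.4f"))
        return "\n".join(lines)

    def plot_weight_ecdf(self, ax=None):
        """Edge-weight distribution of the complete network, per metric."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        net = self.network
        iu, ju = np.triu_indices(net.n_nodes, k=1)
        metrics = np.array([str(m) for m in net.metrics[iu, ju]], dtype=object)
        for metric in sorted(set(metrics)):
            w = np.sort(net.weights[iu, ju][metrics == metric])
            ax.step(w, np.arange(1, w.size + 1) / w.size, where="post", label=metric)
        ax.set_xlabel("edge weight")
        ax.set_ylabel("ECDF")
        ax.legend(title="metric")
        return ax
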