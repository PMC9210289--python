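"""Community detection and counting on network estimates.

The default detector is the Walktrap algorithm with random-walk length
4; its dendrogram is cut at the maximum-modularity level.  Isolated
nodes (degree zero) always receive singleton community labels, so the
number of communities of the empty graph on p nodes is p.  Counting can
optionally discard isolated nodes, which mirrors how cluster counts are
usually reported for very sparse estimates.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph
import numpy as np
import pandas as pd

from .netconstruct import NetworkEstimate

__all__ = ["CommunityPartition", "detect_communities", "count_communities",
           "ALGORITHMS"]

ALGORITHMS = ("walktrap", "fastgreedy", "labelprop")


@dataclass
class CommunityPartition:
    """A hard partition of p nodes into communities."""

    labels: np.ndarray
    algorithm: str
    modularity: float
    walk_length: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D array over nodes")

    @property
    def p(self) -> int:
        return self.labels.size

    @property
    def n_communities(self) -> int:
        return int(np.unique(self.labels).size) if self.p else 0

    def to_tsv(self, path, gene_ids=None) -> None:
        ids = gene_ids if gene_ids is not None else [f"g{i+1}" for i in range(self.p)]
        pd.DataFrame({"gene_id": ids, "community_id": self.labels}).to_csv(
            path, sep="\t", index=False
        )


def _as_igraph(G: NetworkEstimate | np.ndarray) -> igraph.Graph:
    if isinstance(G, NetworkEstimate):
        edges = G.edge_list()
        p = G.p
    else:
        A = np.asarray(G, dtype=bool)
        iu = np.triu_indices(A.shape[0], 1)
        mask = A[iu]
        edges = np.column_stack((iu[0][mask], iu[1][mask]))
        p = A.shape[0]
    return igraph.Graph(n=p, edges=edges.tolist())


def partition_from_edges(edges: np.ndarray, p: int, walk_length: int = 4) -> np.ndarray:
    """Walktrap membership for an edge array on p nodes (internal fast path)."""
    g = igraph.Graph(n=p, edges=edges.tolist())
    clustering = g.community_walktrap(steps=walk_length).as_clustering()
    return np.asarray(clustering.membership, dtype=int)


def detect_communities(
    G: NetworkEstimate | np.ndarray,
    algorithm: str = "walktrap",
    walk_length: int = 4,
    seed: int | None = None,
) -> CommunityPartition:
    """Detect communities and return a hard partition of all nodes.

    walktrap cuts its dendrogram at the maximum-modularity level;
    fastgreedy is the greedy modularity agglomeration; labelprop is
    asynchronous label propagation and is the only stochastic option
    (made reproducible through ``seed``).
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    if walk_length < 1:
        raise ValueError("walk_length must be >= 1")
    g = _as_igraph(G)
    if algorithm == "walktrap":
        clustering = g.community_walktrap(steps=walk_length).as_clustering()
    elif algorithm == "fastgreedy":
        clustering = g.community_fastgreedy().as_clustering()
    else:
        igraph.set_random_number_generator(random.Random(seed))
        clustering = g.community_label_propagation()
        igraph.set_random_number_generator(random)
    labels = np.asarray(clustering.membership, dtype=int)
    modularity = g.modularity(labels) if g.ecount() else 0.0
    return CommunityPartition(
        labels,
        algorithm,
        float(modularity),
        walk_length if algorithm == "walktrap" else None,
    )


def count_communities(
    partition: CommunityPartition,
    remove_isolated: bool = False,
    network: NetworkEstimate | np.ndarray | None = None,
) -> int:
    """Number of distinct community labels, optionally over non-isolated nodes.

    With ``remove_isolated`` the count covers only nodes of degree >= 1
    in ``network`` (required in that case).
    """
    if not remove_isolated:
        return partition.n_communities
    if network is None:
        raise ValueError("remove_isolated=True requires the network")
    if isinstance(network, NetworkEstimate):
        deg = network.degrees()
    else:
        deg = np.asarray(network, dtype=bool).sum(axis=0)
    if deg.size != partition.p:
        raise ValueError("partition and network sizes differ")
    connected = partition.labels[deg > 0]
    return int(np.unique(connected).size)
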