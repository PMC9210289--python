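"""Ground-truth graph generators and Gaussian samplers for simulations.

Four graph families are provided: a cluster graph (disjoint
Erdos-Renyi blocks), a star graph (disjoint hub-and-leaves stars), a
Barabasi-Albert preferential-attachment tree, and a single Erdos-Renyi
graph.  An adjacency is mapped to a valid Gaussian model by placing a
constant ``v`` on the off-diagonal support of the precision matrix and
loading the diagonal by the magnitude of the smallest eigenvalue plus
``0.1 + u``, which guarantees positive definiteness; the covariance is
the inverse precision standardized to unit diagonal.  The constants
``v = 0.3`` and ``u = 0.1`` follow the defaults of the generator
conventionally used for these benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import networkx as nx
import numpy as np

from ._seeding import as_seed_sequence

from .netconstruct import ExpressionMatrix

__all__ = [
    "GroundTruthModel",
    "generate_cluster_graph",
    "generate_star_graph",
    "generate_scalefree_graph",
    "generate_er_graph",
    "graph_to_gaussian",
    "sample_gaussian",
    "delete_edges_random",
    "simulate_family",
    "FAMILIES",
]

FAMILIES = ("cluster", "star", "scalefree", "er")


def _check_adjacency(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=bool)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if A.diagonal().any():
        raise ValueError("adjacency must have a zero diagonal")
    return A


def _block_sizes(p: int, k: int) -> list[int]:
    """Split p nodes into k groups with sizes differing by at most one."""
    base, extra = divmod(p, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def generate_cluster_graph(
    p: int = 500, n_clusters: int = 10, s: float = 0.3, seed=None
) -> np.ndarray:
    """Disjoint union of ``n_clusters`` Erdos-Renyi blocks G(p/n_clusters, s)."""
    if n_clusters < 1 or n_clusters > p:
        raise ValueError("n_clusters must be in [1, p]")
    rng = np.random.default_rng(seed)
    A = np.zeros((p, p), dtype=bool)
    start = 0
    for size in _block_sizes(p, n_clusters):
        blk = np.triu(rng.random((size, size)) < s, 1)
        A[start:start + size, start:start + size] = blk | blk.T
        start += size
    return A


def generate_star_graph(p: int = 500, n_stars: int = 10) -> np.ndarray:
    """Disjoint stars: one hub per component, all other nodes are leaves."""
    if n_stars < 1 or n_stars > p:
        raise ValueError("n_stars must be in [1, p]")
    A = np.zeros((p, p), dtype=bool)
    start = 0
    for size in _block_sizes(p, n_stars):
        hub = start
        A[hub, hub + 1:start + size] = True
        A[hub + 1:start + size, hub] = True
        start += size
    return A


def generate_scalefree_graph(p: int = 500, seed=None) -> np.ndarray:
    """Barabasi-Albert preferential attachment, one edge per incoming node.

    The result is a connected tree on p nodes with a heavy-tailed
    degree distribution.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    seed_int = int(np.random.default_rng(seed).integers(2**31 - 1))
    g = nx.barabasi_albert_graph(p, 1, seed=seed_int)
    A = np.zeros((p, p), dtype=bool)
    for i, j in g.edges():
        A[i, j] = A[j, i] = True
    return A


def generate_er_graph(p: int = 500, s: float = 0.263, seed=None) -> np.ndarray:
    """Erdos-Renyi G(p, s): each unordered pair is an edge with probability s."""
    if not 0.0 <= s <= 1.0:
        raise ValueError("edge probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    A = np.triu(rng.random((p, p)) < s, 1)
    return A | A.T


@dataclass
class GroundTruthModel:
    """Adjacency with matching precision and covariance matrices."""

    adjacency: np.ndarray
    precision: np.ndarray
    covariance: np.ndarray
    family: str = "custom"
    params: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None

    def validate(self) -> None:
        A = _check_adjacency(self.adjacency)
        off = ~np.eye(A.shape[0], dtype=bool)
        if not np.array_equal(self.precision[off] != 0.0, A[off]):
            raise ValueError("precision off-diagonal support must equal adjacency")
        eigvals = np.linalg.eigvalsh(self.precision)
        if eigvals[0] <= 0:
            raise ValueError("precision matrix must be positive definite")
        if not np.allclose(np.diag(self.covariance), 1.0):
            raise ValueError("covariance must have a unit diagonal")

    @property
    def p(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())


def graph_to_gaussian(
    adjacency: np.ndarray,
    v: float = 0.3,
    u: float = 0.1,
    family: str = "custom",
    params: dict[str, Any] | None = None,
) -> GroundTruthModel:
    """Map an adjacency to a positive-definite Gaussian model.

    Precision = v * adjacency off-diagonal, with the diagonal loaded by
    |min eigenvalue| + 0.1 + u; covariance is the standardized inverse.
    """
    A = _check_adjacency(adjacency)
    precision = v * A.astype(float)
    eig_min = float(np.linalg.eigvalsh(precision)[0])
    np.fill_diagonal(precision, abs(eig_min) + 0.1 + u)
    cov = np.linalg.inv(precision)
    d = np.sqrt(np.diag(cov))
    cov = cov / np.outer(d, d)
    np.fill_diagonal(cov, 1.0)
    cov = (cov + cov.T) / 2.0
    return GroundTruthModel(A, precision, cov, family, dict(params or {}))


def sample_gaussian(model: GroundTruthModel, n: int = 200, seed=None) -> ExpressionMatrix:
    """Draw n i.i.d. samples from N(0, covariance)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(model.covariance)
    values = rng.standard_normal((n, model.p)) @ L.T
    return ExpressionMatrix.from_values(values)


def delete_edges_random(adjacency: np.ndarray, fraction: float, seed=None) -> np.ndarray:
    """Remove floor(fraction * |E|) uniformly chosen edges."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    A = _check_adjacency(adjacency).copy()
    iu = np.triu_indices(A.shape[0], 1)
    edge_pos = np.flatnonzero(A[iu])
    n_remove = int(np.floor(fraction * edge_pos.size))
    if n_remove == 0:
        return A
    rng = np.random.default_rng(seed)
    drop = rng.choice(edge_pos, size=n_remove, replace=False)
    rows, cols = iu[0][drop], iu[1][drop]
    A[rows, cols] = False
    A[cols, rows] = False
    return A


def simulate_family(
    family: str,
    p: int = 500,
    n: int = 200,
    seed=None,
    orphan_fraction: float = 0.0,
    **params: Any,
) -> tuple[GroundTruthModel, ExpressionMatrix]:
    """Generate a ground-truth model of the given family and sample data.

    Defaults mirror the benchmark design: cluster = 10 disjoint
    G(50, 0.3) blocks; star = 10 disjoint 50-node stars; scalefree = a
    Barabasi-Albert tree; er = G(p, 0.263).  ``orphan_fraction`` removes
    that fraction of true edges at random before the Gaussian mapping,
    creating zero-degree nodes in the ground truth.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    graph_seed, edge_seed, sample_seed = as_seed_sequence(seed).spawn(3)
    if family == "cluster":
        kwargs = {"n_clusters": 10, "s": 0.3} | params
        A = generate_cluster_graph(p, seed=graph_seed, **kwargs)
    elif family == "star":
        kwargs = {"n_stars": 10} | params
        A = generate_star_graph(p, **kwargs)
    elif family == "scalefree":
        kwargs = dict(params)
        A = generate_scalefree_graph(p, seed=graph_seed)
    else:
        kwargs = {"s": 0.263} | params
        A = generate_er_graph(p, seed=graph_seed, **kwargs)
    if orphan_fraction > 0.0:
        A = delete_edges_random(A, orphan_fraction, seed=edge_seed)
    model = graph_to_gaussian(A, family=family, params=kwargs)
    X = sample_gaussian(model, n, seed=sample_seed)
    return model, X
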