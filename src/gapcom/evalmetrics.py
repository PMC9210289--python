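"""Edge-recovery metrics and partition agreement.

Edge recovery is scored as binary classification over the
``(p**2 - p)/2`` unordered node pairs: sensitivity Sen = TP/(TP+FN),
precision Pre = TP/(TP+FP) and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

with Pre = MCC = 0 when TP+FP = 0 and MCC = 0 whenever any factor of
the denominator vanishes.  Partition agreement uses the normalized
mutual information

    NMI(A, B) = -2 * sum_ij p_ij log(p_ij p / (p_i. p_.j))
                / (sum_i p_i. log(p_i./p) + sum_j p_.j log(p_.j/p)),

evaluated on the contingency table of shared node counts, with
0*log(0) = 0.  NMI is 1 for identical partitions and 0 for independent
ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .community import CommunityPartition
from .netconstruct import NetworkEstimate, possible_edges

__all__ = [
    "ConfusionCounts",
    "PartitionContingency",
    "confusion_counts",
    "sensitivity",
    "precision",
    "mcc",
    "nmi",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Edge-wise confusion counts over unordered node pairs."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _as_edge_vector(G, p_expected: int | None = None) -> np.ndarray:
    if isinstance(G, NetworkEstimate):
        A = G.adjacency
    else:
        A = np.asarray(G, dtype=bool)
    p = A.shape[0]
    if p_expected is not None and p != p_expected:
        raise ValueError(f"dimension mismatch: {p} vs {p_expected} nodes")
    iu = np.triu_indices(p, 1)
    return A[iu]


def confusion_counts(est, truth) -> ConfusionCounts:
    """Compare estimated and true adjacencies over unordered pairs."""
    e = _as_edge_vector(est)
    t = _as_edge_vector(truth, p_expected=int((1 + math.isqrt(1 + 8 * e.size)) // 2))
    if e.size != t.size:
        raise ValueError("dimension mismatch between estimate and truth")
    return ConfusionCounts(
        tp=int((e & t).sum()),
        fp=int((e & ~t).sum()),
        tn=int((~e & ~t).sum()),
        fn=int((~e & t).sum()),
    )


def sensitivity(c: ConfusionCounts) -> float:
    """Sen = TP/(TP+FN); 0 when the truth has no edges."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else 0.0


def precision(c: ConfusionCounts) -> float:
    """Pre = TP/(TP+FP); defined as 0 when TP+FP = 0."""
    denom = c.tp + c.fp
    return c.tp / denom if denom else 0.0


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation; 0 when any denominator factor vanishes."""
    factors = [c.tp + c.fp, c.tp + c.fn, c.tn + c.fp, c.tn + c.fn]
    if any(f == 0 for f in factors):
        return 0.0
    num = c.tp * c.tn - c.fp * c.fn
    denom = math.sqrt(factors[0] * factors[1]) * math.sqrt(factors[2] * factors[3])
    return num / denom


@dataclass
class PartitionContingency:
    """Shared-node counts between the clusters of two partitions."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("contingency table must be 2-D")

    @classmethod
    def from_labels(cls, a: np.ndarray, b: np.ndarray) -> "PartitionContingency":
        a = np.asarray(a)
        b = np.asarray(b)
        if a.size != b.size:
            raise ValueError("partitions must cover the same nodes")
        _, ai = np.unique(a, return_inverse=True)
        _, bi = np.unique(b, return_inverse=True)
        table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
        np.add.at(table, (ai, bi), 1)
        return cls(table)

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def nmi(A, B) -> float:
    """Normalized mutual information between two hard partitions.

    Accepts :class:`~gapcom.community.CommunityPartition` objects or
    plain label arrays over the same nodes.  When both partitions are a
    single cluster the formula is 0/0; by convention the value is 1
    (the partitions are then identical).
    """
    a = A.labels if isinstance(A, CommunityPartition) else np.asarray(A)
    b = B.labels if isinstance(B, CommunityPartition) else np.asarray(B)
    if a.size == 0:
        raise ValueError("cannot compare empty partitions")
    ct = PartitionContingency.from_labels(a, b)
    p = ct.total
    pij = ct.counts
    pi = ct.row_sums.astype(float)
    pj = ct.col_sums.astype(float)
    outer = np.outer(pi, pj)
    nz = pij > 0
    num = -2.0 * float(np.sum(pij[nz] * np.log(pij[nz] * p / outer[nz])))
    denom = float(np.sum(pi * np.log(pi / p)) + np.sum(pj * np.log(pj / p)))
    if denom == 0.0:
        # both partitions are a single cluster: identical by construction
        return 1.0
    return num / denom
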