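"""The gap-com statistic: community-count gap model selection.

For a network estimator ``M_lam`` on expression data Y, the statistic is

    Gap(lam) = E{k(lam)} - k_hat(lam),

where ``k_hat(lam)`` is the number of communities detected in the
network estimated from the observed data at regularization ``lam``, and
``E{k(lam)}`` is the expected number of communities under a null in
which pairwise co-expression is determined by chance alone.  The null
expectation is estimated either by

* ``perm`` — independently shuffling every gene's expression values
  across samples B times, re-estimating the network at ``lam`` from each
  shuffled dataset and averaging the community counts, or
* ``er`` — estimating the chance edge probability ``s_hat(lam)`` as the
  sparsity of the network built from one shuffled dataset and averaging
  community counts over B Erdos-Renyi draws G(p, s_hat(lam)).

The selected regularization value maximizes Gap; exact ties are broken
in favor of the smallest sparsity (parsimony).  Isolated nodes count as
singleton communities in both curves, so at a threshold above every
observed and permuted |r| both curves equal p and the gap vanishes.

All resampling derives from a single master seed through spawned child
seeds, one per resample, so results do not depend on evaluation order
or degree of parallelism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeding import as_seed_sequence
import pandas as pd

from .community import detect_communities, partition_from_edges
from .netconstruct import (
    CorrelationMatrix,
    ExpressionMatrix,
    NetworkEstimate,
    RegularizationPath,
    build_lambda_grid,
    compute_correlation,
    ggm_estimate,
    hard_threshold,
    possible_edges,
)

__all__ = [
    "GapCurve",
    "SelectionResult",
    "permute_expression",
    "expected_k_perm",
    "estimate_edge_prob",
    "expected_k_er",
    "gap_curve",
    "select_lambda",
    "run_gapcom",
]


def permute_expression(X: ExpressionMatrix, seed) -> ExpressionMatrix:
    """Shuffle each gene's values across samples, independently per gene.

    Column marginal distributions are preserved exactly; all inter-gene
    dependence is destroyed.  ``seed`` may be an int or a numpy
    SeedSequence / Generator.
    """
    rng = np.random.default_rng(seed)
    permuted = rng.permuted(X.values, axis=0)
    return ExpressionMatrix(permuted, list(X.gene_ids), list(X.sample_ids))


def _estimate(X: ExpressionMatrix, lam: float, estimator: str) -> NetworkEstimate:
    if estimator == "threshold":
        return hard_threshold(compute_correlation(X), lam)
    if estimator == "ggm":
        return ggm_estimate(X, lam)
    raise ValueError(f"unknown estimator {estimator!r}")


def _count_k(G: NetworkEstimate, walk_length: int) -> int:
    return detect_communities(G, "walktrap", walk_length).n_communities


def expected_k_perm(
    X: ExpressionMatrix,
    lam: float,
    B: int = 50,
    estimator: str = "threshold",
    walk_length: int = 4,
    seed=None,
) -> tuple[float, float]:
    """Mean and standard error of k over B permuted datasets at ``lam``."""
    if B < 1:
        raise ValueError("B must be >= 1")
    children = as_seed_sequence(seed).spawn(B)
    ks = np.empty(B)
    for b in range(B):
        Xp = permute_expression(X, children[b])
        ks[b] = _count_k(_estimate(Xp, lam, estimator), walk_length)
    spread = float(ks.std(ddof=1) / np.sqrt(B)) if B > 1 else 0.0
    return float(ks.mean()), spread


def estimate_edge_prob(
    X: ExpressionMatrix, lam: float, estimator: str = "threshold", seed=None
) -> float:
    """Chance edge probability: sparsity of the estimate from one permuted copy."""
    Xp = permute_expression(X, seed)
    return _estimate(Xp, lam, estimator).sparsity


def _er_edges(p: int, s: float, rng: np.random.Generator) -> np.ndarray:
    iu = np.triu_indices(p, 1)
    mask = rng.random(iu[0].size) < s
    return np.column_stack((iu[0][mask], iu[1][mask]))


def expected_k_er(
    p: int, s: float, B: int = 50, walk_length: int = 4, seed=None
) -> tuple[float, float]:
    """Mean and standard error of k over B Erdos-Renyi draws G(p, s)."""
    if not 0.0 <= s <= 1.0:
        raise ValueError("edge probability must be in [0, 1]")
    if B < 1:
        raise ValueError("B must be >= 1")
    children = as_seed_sequence(seed).spawn(B)
    ks = np.empty(B)
    for b in range(B):
        rng = np.random.default_rng(children[b])
        memb = partition_from_edges(_er_edges(p, s, rng), p, walk_length)
        ks[b] = np.unique(memb).size
    spread = float(ks.std(ddof=1) / np.sqrt(B)) if B > 1 else 0.0
    return float(ks.mean()), spread


@dataclass
class GapCurve:
    """Per-lambda record of k_hat, E{k} and Gap = E{k} - k_hat."""

    lams: np.ndarray
    k_hat: np.ndarray
    e_k: np.ndarray
    e_k_spread: np.ndarray
    sparsities: np.ndarray
    strategy: str
    n_resamples: int

    def __post_init__(self) -> None:
        self.lams = np.asarray(self.lams, dtype=float)
        self.k_hat = np.asarray(self.k_hat, dtype=int)
        self.e_k = np.asarray(self.e_k, dtype=float)
        self.e_k_spread = np.asarray(self.e_k_spread, dtype=float)
        self.sparsities = np.asarray(self.sparsities, dtype=float)
        sizes = {a.size for a in (self.lams, self.k_hat, self.e_k,
                                  self.e_k_spread, self.sparsities)}
        if len(sizes) != 1:
            raise ValueError("all gap-curve columns must have equal length")

    @property
    def gap(self) -> np.ndarray:
        return self.e_k - self.k_hat

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lam": self.lams,
                "sparsity": self.sparsities,
                "k_hat": self.k_hat,
                "e_k": self.e_k,
                "e_k_se": self.e_k_spread,
                "gap": self.gap,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _threshold_counts(absr_triu: np.ndarray, iu, lams: np.ndarray, p: int,
                      walk_length: int) -> np.ndarray:
    """Walktrap community counts of |r|-thresholded graphs at each lambda."""
    ks = np.empty(lams.size, dtype=int)
    for i, lam in enumerate(lams):
        mask = absr_triu > lam
        edges = np.column_stack((iu[0][mask], iu[1][mask]))
        ks[i] = np.unique(partition_from_edges(edges, p, walk_length)).size
    return ks


def gap_curve(
    X: ExpressionMatrix,
    lams: np.ndarray,
    strategy: str = "perm",
    B: int = 50,
    estimator: str = "threshold",
    walk_length: int = 4,
    seed=None,
    share_permutations: bool = True,
    reuse_permutation: bool = False,
) -> GapCurve:
    """Compute k_hat, E{k} and Gap along a regularization path.

    With ``share_permutations`` (default) the ``perm`` strategy draws B
    permuted datasets and evaluates each along the whole path, which is
    how a resample-parallel implementation proceeds; disabling it draws
    B fresh permutations per lambda.  Either way every resample gets its
    own child seed, so results are reproducible and independent of
    evaluation order.  For the ``er`` strategy, ``reuse_permutation``
    estimates the chance edge probability from a single permuted
    dataset for the whole path instead of one per lambda.
    """
    lams = np.asarray(lams, dtype=float)
    if lams.size == 0:
        raise ValueError("empty regularization path")
    if strategy not in ("perm", "er"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if B < 1:
        raise ValueError("B must be >= 1")
    p = X.p
    ss = as_seed_sequence(seed)

    fast = estimator == "threshold"
    if fast:
        iu = np.triu_indices(p, 1)
        absr = compute_correlation(X).offdiag_abs()
        k_hat = _threshold_counts(absr, iu, lams, p, walk_length)
        sparsities = np.array([(absr > l).mean() for l in lams])
    else:
        estimates = [_estimate(X, l, estimator) for l in lams]
        k_hat = np.array([_count_k(G, walk_length) for G in estimates])
        sparsities = np.array([G.sparsity for G in estimates])

    if strategy == "perm":
        if share_permutations:
            children = ss.spawn(B)
            ks = np.empty((B, lams.size))
            for b in range(B):
                Xp = permute_expression(X, children[b])
                if fast:
                    absrp = compute_correlation(Xp).offdiag_abs()
                    ks[b] = _threshold_counts(absrp, iu, lams, p, walk_length)
                else:
                    ks[b] = [
                        _count_k(_estimate(Xp, l, estimator), walk_length)
                        for l in lams
                    ]
        else:
            per_lam = ss.spawn(lams.size)
            ks = np.empty((B, lams.size))
            for i, lam in enumerate(lams):
                for b, child in enumerate(per_lam[i].spawn(B)):
                    Xp = permute_expression(X, child)
                    ks[b, i] = _count_k(_estimate(Xp, lam, estimator), walk_length)
        e_k = ks.mean(axis=0)
        spread = (
            ks.std(axis=0, ddof=1) / np.sqrt(B) if B > 1 else np.zeros(lams.size)
        )
    else:  # er
        per_lam = ss.spawn(lams.size + 1)
        if reuse_permutation:
            Xp_shared = permute_expression(X, per_lam[-1])
            if fast:
                absrp_shared = compute_correlation(Xp_shared).offdiag_abs()
        e_k = np.empty(lams.size)
        spread = np.empty(lams.size)
        n_pairs = possible_edges(p)
        for i, lam in enumerate(lams):
            perm_seed, er_seed = per_lam[i].spawn(2)
            if reuse_permutation:
                if fast:
                    s_hat = (absrp_shared > lam).mean()
                else:
                    s_hat = _estimate(Xp_shared, lam, estimator).sparsity
            else:
                Xp = permute_expression(X, perm_seed)
                if fast:
                    s_hat = (compute_correlation(Xp).offdiag_abs() > lam).mean()
                else:
                    s_hat = _estimate(Xp, lam, estimator).sparsity
            e_k[i], spread[i] = expected_k_er(p, s_hat, B, walk_length, er_seed)
    return GapCurve(lams, k_hat, e_k, spread, sparsities, strategy, B)


@dataclass
class SelectionResult:
    """Outcome of maximizing Gap along the path with parsimony tie-break."""

    lam_star: float
    selected: NetworkEstimate
    k_selected: int
    n_maximizers: int
    all_maximizer_lams: np.ndarray

    @property
    def sparsity(self) -> float:
        return self.selected.sparsity


def select_lambda(
    curve: GapCurve, path: RegularizationPath, gap_tol: float = 0.0
) -> SelectionResult:
    """Pick the gap-maximizing lambda; exact ties go to the sparsest model.

    Gap values are compared exactly (floating point equality) by
    default; ``gap_tol`` widens the tie window for near-maximal values.
    """
    if curve.lams.size != path.lams.size or not np.allclose(curve.lams, path.lams):
        raise ValueError("gap curve and regularization path are not aligned")
    if curve.lams.size == 0:
        raise ValueError("empty gap curve")
    gap = curve.gap
    maximizers = np.flatnonzero(gap >= gap.max() - gap_tol)
    sparsities = np.array([path.estimates[i].sparsity for i in maximizers])
    chosen = maximizers[np.argmin(sparsities)]
    return SelectionResult(
        lam_star=float(curve.lams[chosen]),
        selected=path.estimates[chosen],
        k_selected=int(curve.k_hat[chosen]),
        n_maximizers=int(maximizers.size),
        all_maximizer_lams=curve.lams[maximizers],
    )


def run_gapcom(
    X: ExpressionMatrix,
    estimator: str = "threshold",
    strategy: str = "perm",
    n_lambda: int = 50,
    max_sparsity: float = 0.1,
    B: int = 50,
    walk_length: int = 4,
    seed=None,
    spacing: str = "log",
) -> tuple[RegularizationPath, GapCurve, SelectionResult]:
    """One-shot pipeline: grid, gap curve, and selection.

    Returns the regularization path, the gap curve and the selection
    result.  Only the threshold estimator supports automatic grid
    construction; for the GGM estimator pass an explicit grid to
    :func:`gap_curve` instead.
    """
    if estimator != "threshold":
        raise ValueError("run_gapcom builds |r|-quantile grids; use gap_curve "
                         "with an explicit penalty grid for the GGM estimator")
    R = compute_correlation(X)
    lams = build_lambda_grid(R, n_lambda, max_sparsity, spacing=spacing)
    path = RegularizationPath.from_threshold_grid(R, lams)
    curve = gap_curve(
        X, lams, strategy=strategy, B=B, estimator=estimator,
        walk_length=walk_length, seed=seed,
    )
    selection = select_lambda(curve, path)
    return path, curve, selection
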