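"""Sparse undirected network construction from gene expression data.

Two estimators are provided, both controlled by a single scalar
regularization parameter ``lam``:

* hard thresholding of pairwise Pearson correlations (an edge is kept
  when ``|r_ij| > lam``), and
* an L1-penalized Gaussian graphical model (an edge is kept when the
  penalized precision-matrix estimate has a nonzero off-diagonal entry).

The sparsity of a network on ``p`` nodes is the number of edges divided
by ``(p**2 - p) / 2``, the number of unordered node pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "CorrelationMatrix",
    "NetworkEstimate",
    "RegularizationPath",
    "GGMConvergenceError",
    "load_expression",
    "compute_correlation",
    "hard_threshold",
    "build_lambda_grid",
    "ggm_estimate",
    "nonparanormal_transform",
    "possible_edges",
]


def possible_edges(p: int) -> int:
    """Number of unordered node pairs, ``(p**2 - p) / 2``."""
    return (p * p - p) // 2


@dataclass
class ExpressionMatrix:
    """An n-samples x p-genes matrix of expression levels.

    Genes are columns.  Values must be finite; gene identifiers must be
    unique.  ``n >= 2`` and ``p >= 2`` are required so that pairwise
    correlations are defined.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 2 or p < 2:
            raise ValueError(f"need at least 2 samples and 2 genes, got n={n}, p={p}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at sample {bad[0]}, gene {bad[1]}"
            )
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.gene_ids) != p:
            raise ValueError("gene_ids length does not match number of columns")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")
        if len(set(self.gene_ids)) != p:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene identifiers: {dupes}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_values(cls, values: np.ndarray, gene_ids: Sequence[str] | None = None,
                    sample_ids: Sequence[str] | None = None) -> "ExpressionMatrix":
        values = np.asarray(values, dtype=float)
        n, p = values.shape
        if gene_ids is None:
            gene_ids = [f"g{j + 1}" for j in range(p)]
        if sample_ids is None:
            sample_ids = [f"s{i + 1}" for i in range(n)]
        return cls(values, list(gene_ids), list(sample_ids))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.gene_ids, index=self.sample_ids)

    def save(self, path: str | Path, delimiter: str = "\t") -> None:
        df = pd.DataFrame(self.values, columns=self.gene_ids)
        # %.17g guarantees bit-exact float round trips through text
        df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def load_expression(path: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a delimited expression matrix with genes in columns.

    The first row must be a header of unique gene identifiers; every
    body cell must be numeric.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
    gene_ids = [h.strip() for h in header]
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise ValueError(f"duplicate gene identifiers in header: {dupes}")
    df = pd.read_csv(path, sep=delimiter, header=0, dtype=str)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            # element-wise float() is correctly rounded, unlike the fast
            # pandas string parser, so text round trips are bit-exact
            values[:, j] = df[col].astype(np.float64).to_numpy()
        except (ValueError, TypeError):
            mask = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            row = int(np.argmax(mask.to_numpy()))
            raise ValueError(
                f"non-numeric value {df[col].iloc[row]!r} at data row {row + 1}, "
                f"column {gene_ids[j]!r}"
            ) from None
    sample_ids = [f"s{i + 1}" for i in range(values.shape[0])]
    return ExpressionMatrix(values, gene_ids, sample_ids)


@dataclass
class CorrelationMatrix:
    """A p x p Pearson correlation matrix with its gene identifiers."""

    values: np.ndarray
    gene_ids: list[str]
    method: str = "pearson"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = self.values.shape[0]
        if self.values.shape != (p, p):
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("correlation matrix must be symmetric")

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def offdiag_abs(self) -> np.ndarray:
        """|r| over the upper triangle (unordered pairs), flattened."""
        iu = np.triu_indices(self.p, 1)
        return np.abs(self.values[iu])


def compute_correlation(X: ExpressionMatrix) -> CorrelationMatrix:
    """Pearson correlation over samples for every gene pair.

    A zero-variance gene is assigned correlation 0 with every other gene
    (instead of NaN) so that permutation loops over degenerate data stay
    total; a warning is emitted.
    """
    if X.n < 2:
        raise ValueError("need at least 2 samples to compute correlations")
    vals = X.values
    sd = vals.std(axis=0)
    constant = sd == 0.0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} zero-variance gene(s); their correlations are set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    sd_safe = np.where(constant, 1.0, sd)
    Z = (vals - vals.mean(axis=0)) / sd_safe
    R = (Z.T @ Z) / X.n
    R[constant, :] = 0.0
    R[:, constant] = 0.0
    np.fill_diagonal(R, 1.0)
    np.clip(R, -1.0, 1.0, out=R)
    R = (R + R.T) / 2.0
    return CorrelationMatrix(R, list(X.gene_ids))


@dataclass
class NetworkEstimate:
    """A symmetric, loop-free adjacency with its regularization value.

    ``sparsity`` is |E| / ((p**2 - p) / 2).
    """

    adjacency: np.ndarray
    lam: float
    estimator: str
    gene_ids: list[str] = field(default_factory=list)
    sparsity: float = field(init=False)

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=bool)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if A.diagonal().any():
            raise ValueError("adjacency must have a zero diagonal (no self-loops)")
        self.adjacency = A
        if not self.gene_ids:
            self.gene_ids = [f"g{j + 1}" for j in range(A.shape[0])]
        self.sparsity = self.n_edges / possible_edges(self.p)

    @property
    def p(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)

    def edge_list(self) -> np.ndarray:
        """Edges as an m x 2 array of node indices (i < j)."""
        iu = np.triu_indices(self.p, 1)
        mask = self.adjacency[iu]
        return np.column_stack((iu[0][mask], iu[1][mask]))

    def to_edgelist_tsv(self, path: str | Path, weights: np.ndarray | None = None) -> None:
        """Write an undirected edge list (gene_i, gene_j[, weight])."""
        edges = self.edge_list()
        rows = {"gene_id_i": [self.gene_ids[i] for i in edges[:, 0]],
                "gene_id_j": [self.gene_ids[j] for j in edges[:, 1]]}
        if weights is not None:
            rows["weight"] = np.abs(weights[edges[:, 0], edges[:, 1]])
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def hard_threshold(R: CorrelationMatrix, lam: float) -> NetworkEstimate:
    """Keep edge (i, j) iff ``|r_ij| > lam`` (strict), i != j.

    The strict inequality means ``lam >= 1`` always yields the empty
    graph.
    """
    if lam < 0:
        raise ValueError("threshold must be non-negative")
    A = np.abs(R.values) > lam
    np.fill_diagonal(A, False)
    return NetworkEstimate(A, float(lam), "threshold", list(R.gene_ids))


def build_lambda_grid(
    R: CorrelationMatrix,
    n_values: int = 50,
    max_sparsity: float = 0.1,
    spacing: str = "log",
    min_ratio: float = 0.1,
) -> np.ndarray:
    """Build an ascending grid of hard-threshold values.

    spacing="log" (default) follows the convention of standard
    regularization-path software: ``n_values`` thresholds geometrically
    spaced between the largest off-diagonal |r| and ``min_ratio`` times
    it, after which values whose networks exceed ``max_sparsity`` are
    dropped.  The surviving grid may therefore hold fewer than
    ``n_values`` thresholds.

    spacing="sparsity" instead picks thresholds from the quantiles of
    the off-diagonal |r| distribution so that the resulting sparsity
    levels cover (0, max_sparsity] approximately uniformly; it returns
    ``n_values`` thresholds (fewer, with a warning, when there are not
    enough distinct |r| values).

    spacing="linear" spaces thresholds evenly between the |r| quantile
    at ``1 - max_sparsity`` and the largest off-diagonal |r|.
    """
    if n_values < 1:
        raise ValueError("n_values must be >= 1")
    if not 0 < max_sparsity <= 1:
        raise ValueError("max_sparsity must be in (0, 1]")
    absr = R.offdiag_abs()
    lam_max = float(absr.max())
    if lam_max == 0.0:
        raise ValueError("all off-diagonal correlations are zero; no grid exists")
    if spacing == "log":
        lams = np.geomspace(lam_max, min_ratio * lam_max, n_values)
        sparsities = np.searchsorted(np.sort(absr), lams, side="right")
        sparsities = 1.0 - sparsities / absr.size
        lams = lams[sparsities <= max_sparsity]
    elif spacing == "sparsity":
        targets = max_sparsity * np.arange(1, n_values + 1) / n_values
        lams = np.quantile(absr, 1.0 - targets)
    elif spacing == "linear":
        lam_lo = float(np.quantile(absr, 1.0 - max_sparsity))
        lams = np.linspace(lam_lo, lam_max, n_values)
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    lams = np.unique(lams)  # ascending
    if spacing == "sparsity" and lams.size < n_values:
        warnings.warn(
            f"only {lams.size} distinct thresholds available for the requested "
            f"{n_values}-value grid",
            RuntimeWarning,
            stacklevel=2,
        )
    return lams


@dataclass
class RegularizationPath:
    """Network estimates along an ascending grid of lambda values."""

    lams: np.ndarray
    estimates: list[NetworkEstimate]

    def __post_init__(self) -> None:
        self.lams = np.asarray(self.lams, dtype=float)
        if self.lams.size != len(self.estimates):
            raise ValueError("one estimate per lambda is required")
        if self.lams.size > 1 and not np.all(np.diff(self.lams) > 0):
            raise ValueError("lambda grid must be strictly increasing")

    @property
    def sparsities(self) -> np.ndarray:
        return np.array([e.sparsity for e in self.estimates])

    @classmethod
    def from_threshold_grid(cls, R: CorrelationMatrix, lams: np.ndarray) -> "RegularizationPath":
        return cls(np.asarray(lams, dtype=float), [hard_threshold(R, l) for l in lams])


class GGMConvergenceError(RuntimeError):
    """Raised when the L1-penalized GGM solver fails to converge."""

    def __init__(self, lam: float, n_iter: int, message: str = ""):
        self.lam = lam
        self.n_iter = n_iter
        super().__init__(
            f"graphical lasso did not converge at lam={lam} after {n_iter} iterations"
            + (f": {message}" if message else "")
        )


def ggm_estimate(X: ExpressionMatrix, lam: float, max_iter: int = 500,
                 tol: float = 1e-3) -> NetworkEstimate:
    """L1-penalized Gaussian graphical model support at penalty ``lam``.

    The penalized log-likelihood is maximized on the sample correlation
    matrix; edge (i, j) is reported present when the estimated precision
    matrix has a nonzero (i, j) entry.
    """
    if lam <= 0:
        raise ValueError("the L1 penalty must be positive")
    from sklearn.covariance import graphical_lasso

    R = compute_correlation(X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=UserWarning)
            _, prec = graphical_lasso(R.values, alpha=float(lam),
                                      max_iter=max_iter, tol=tol)
    except (FloatingPointError, UserWarning, np.linalg.LinAlgError) as exc:
        raise GGMConvergenceError(lam, max_iter, str(exc)) from exc
    support = np.abs(prec) > 1e-8
    support = support | support.T  # numerically symmetric support
    np.fill_diagonal(support, False)
    return NetworkEstimate(support, float(lam), "ggm", list(X.gene_ids))


def nonparanormal_transform(X: ExpressionMatrix) -> ExpressionMatrix:
    """Marginal rank-based Gaussianization (truncated-ECDF variant).

    Each column is replaced by standard-normal quantiles of its
    empirical CDF, truncated to ``[delta_n, 1 - delta_n]`` with
    ``delta_n = 1 / (4 n**0.25 sqrt(pi log n))``, then rescaled to unit
    standard deviation.  Because the map is a function of ranks only, it
    is invariant to strictly increasing transformations of a column.
    A constant column cannot be ranked meaningfully and is mapped to
    zeros with a warning.
    """
    n = X.n
    delta = 1.0 / (4.0 * n ** 0.25 * np.sqrt(np.pi * np.log(n)))
    out = np.empty_like(X.values)
    constant_cols = []
    for j in range(X.p):
        col = X.values[:, j]
        if np.all(col == col[0]):
            constant_cols.append(X.gene_ids[j])
            out[:, j] = 0.0
            continue
        ecdf = stats.rankdata(col, method="average") / n
        z = stats.norm.ppf(np.clip(ecdf, delta, 1.0 - delta))
        out[:, j] = z / z.std()
    if constant_cols:
        warnings.warn(
            f"constant column(s) mapped to zeros: {constant_cols}",
            RuntimeWarning,
            stacklevel=2,
        )
    return ExpressionMatrix(out, list(X.gene_ids), list(X.sample_ids))
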