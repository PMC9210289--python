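# Methods

## The selection problem

A sparse undirected co-expression network over `p` genes is estimated
from an `n x p` expression matrix by an estimator with a single
regularization parameter λ — here hard thresholding of pairwise Pearson
correlations (edge iff `|r_ij| > λ`) or an L1-penalized Gaussian
graphical model (edge iff the penalized precision estimate has a
nonzero off-diagonal entry).  Classical tuning criteria (CV, BIC,
stability) do not look at what makes gene networks interesting:
community structure.  The gap-com statistic tunes λ by contrasting the
community count of the fitted network with its expectation under a null
of random edge pairing:

    Gap(λ) = E{k(λ)} − k̂(λ)

`k̂(λ)` is the number of communities the Walktrap algorithm (random
walk length 4, dendrogram cut at maximum modularity) finds in the
network estimated from the observed data at λ.  `E{k(λ)}` is estimated
by resampling under the null; λ* maximizes Gap, and exact ties are
broken toward the smallest sparsity (parsimony).  The selected network
is the sparsest one whose community structure deviates most from what
chance alone produces.

## Null strategies

* **Permutation (`perm`)** — every gene's values are shuffled across
  samples, independently per gene.  Marginals are preserved exactly and
  all inter-gene dependence is destroyed.  The network is re-estimated
  from each of B shuffled datasets at each λ and the community counts
  averaged.
* **Erdős–Rényi resampling (`er`)** — the chance edge probability
  ŝ(λ) is the sparsity of the network built from one shuffled dataset
  at λ; `E{k(λ)}` is the mean community count over B draws of
  G(p, ŝ(λ)).  This is much cheaper: a thresholded permuted correlation
  matrix is already an unstructured graph, so matching only its density
  loses almost nothing.  An option reuses a single permutation for the
  whole path.

Both strategies report the spread of `E{k(λ)}` as the standard error of
the resample mean (sd/√B); the reference analyses show error bars
without defining them, so this definition is a package convention.

## Counting conventions

Isolated (zero-degree) nodes always count as singleton communities in
both `k̂(λ)` and `E{k(λ)}`.  Consequently both curves equal `p` when λ
exceeds every observed and permuted `|r|`, and both equal 1 for the
complete graph, so Gap vanishes at the path extremes.  Alternatives
(counting only communities among connected nodes, or density-matching
the null) were evaluated against the known operating characteristics of
the procedure on star-graph benchmarks and rejected: they push the
selection to much denser models.  Cluster counts *reported* for a
selected network (`# clusters`) are computed after removing isolated
nodes, which mirrors how such tables are usually presented; this
removal never enters the selection itself.

## The λ grid

`build_lambda_grid` defaults to `spacing="log"`: `n_values` thresholds
geometrically spaced from the largest off-diagonal `|r|` down to one
tenth of it, after which grid points whose networks exceed
`max_sparsity` are dropped.  This mirrors the λ-sequence convention of
standard regularization-path software and keeps permuted networks
nearly empty over most of the path, which is what makes the permutation
null affordable.  Two alternatives are provided: `"sparsity"` picks
`|r|`-quantiles so that sparsity levels cover `(0, max_sparsity]`
uniformly (guaranteed coverage, but permuted graphs are dense at many
grid points), and `"linear"` spaces thresholds evenly in λ.  Defaults:
`n_values = 50`, `max_sparsity = 0.1`.

## Resampling layout and seeding

A master seed spawns one child seed per resample (and per λ where
applicable) through `numpy`'s `SeedSequence`, so results are bit-identical
across reruns and invariant to evaluation order or degree of
parallelism.  The permutation strategy draws its B permuted datasets
once and evaluates each along the entire path — the layout a
resample-parallel implementation uses; `E{k(λ)}` is an unbiased mean of
B independent permutations at every λ either way.  A
`share_permutations=False` mode draws B fresh permutations per λ.

## Synthetic data

`simgen` generates the benchmark ground truths on `p = 500` nodes:

| family     | construction                          | edges (typ.) | true communities |
|------------|---------------------------------------|--------------|------------------|
| cluster    | 10 disjoint G(50, 0.3) blocks         | ≈ 3675       | 10               |
| star       | 10 disjoint 50-node stars             | 490          | 10               |
| scalefree  | Barabási–Albert tree (1 edge/node)    | 499          | no clean split   |
| er         | G(500, 0.263)                         | ≈ 32 800     | ≈ 5 (Walktrap)   |

An adjacency is mapped to a Gaussian model by setting the precision
off-diagonals to `v = 0.3` on the support, loading the diagonal with
`|λ_min| + 0.1 + u` (`u = 0.1`), and standardizing the inverse to unit
diagonal — the defaults of the generator conventionally used for these
benchmarks.  Expression data are `n = 200` i.i.d. draws from
N(0, covariance).  With these constants the star hub–leaf marginal
correlation is ≈ 0.29, the cluster within-block edge correlation is
≈ 0.16, and the er family's edge correlations are ≈ 0.05 — so the
families span easy, hard and essentially undetectable regimes.

What the generator does **not** emulate: library-size or batch effects,
heavy-tailed or count-valued expression margins (the nonparanormal
transform addresses the margins, but the simulated data are already
Gaussian), correlated noise across samples, and overlapping or nested
community structure.  Passing benchmarks therefore demonstrates correct
behavior of the selection machinery under the stated Gaussian models,
not robustness to real RNA-seq artifacts.

## Numerical choices

* Strict inequality `|r| > λ` defines a threshold edge, so `λ ≥ 1`
  always yields the empty graph.
* Zero-variance columns (possible after permuting degenerate data) get
  correlation 0 with every other gene rather than NaN, keeping
  resampling loops total; a warning is emitted.
* The graphical lasso runs on the sample correlation matrix with
  `tol = 1e-3` and `max_iter = 500`; near-singular correlation matrices
  make the coordinate-descent dual gap oscillate below ~1e-3, and the
  selection depends only on the support path, which is stable well
  above that tolerance.  Non-convergence raises an error carrying λ and
  the iteration count.  Support is read off at `|precision| > 1e-8`.
* Gap ties are compared with exact floating-point equality before the
  parsimony rule; a `gap_tol` option widens the tie window but is off
  by default.
* The nonparanormal transform uses the truncated empirical CDF with
  `δ_n = 1/(4 n^{1/4} √(π log n))` and rescales each transformed column
  to unit standard deviation; constant columns map to zeros with a
  warning.
* In `expected_k_er`, edge indicators are drawn directly from the
  package RNG (not a graph library's global generator) so that E-R
  resampling obeys the seeding contract.

## Problem sizes used by the test suite and the acceptance script

Full benchmark scale is 100 replications × 50 λ × 50 resamples per
family.  The package's own runs scale this down: the acceptance script
uses 20 replications per family with the 50-value path, B = 50
permutations for the star benchmark and B = 25 for the other three
families (≈ 13 minutes in total on one core); the pytest benchmark
tests use 6–8 replications with B = 20, and the 100-hub star toy
(p = 500, n = 1000) runs on 5 seeds with a 20-value path and B = 10.
Replication count controls the accuracy of reported means, while B
affects only per-replication selection noise, so B is the dimension
scaled first.  All scales are recorded in the scripts themselves.

## Known limitations

* The two-sided benchmark tables for the cluster family report an
  operating point (high sensitivity at very low precision) that implies
  a selected network denser than the stated 0.1 sparsity cap permits;
  under the cap, gap-com on cluster data selects much sparser networks
  (the strongest within-block edges), with correspondingly lower
  sensitivity.  The package reports what its faithful implementation
  computes.
* Gap maximization is sensitive to the extreme tail of the null
  correlation distribution: over ~10^5 independent gene pairs the
  maximum null |r| lands inside any reasonable threshold grid, and a
  single such spurious edge that merges two true communities raises the
  gap by exactly one above an otherwise tied plateau.  On the 100-hub
  toy this makes the selected community count 99 rather than 100 on
  about half the seeds, whenever a grid point falls in the narrow λ
  window just below the most extreme cross pair.
* The permutation and E-R nulls give identical selections, but their
  E{k} curves differ systematically by a few percent of p at the
  densest grid points: a thresholded permuted-correlation matrix
  carries row-effect degree correlation that an independent-edge
  Erdős–Rényi draw lacks, and at small resampling error that
  difference exceeds a two-standard-error band.
* Walktrap on a dense graph (the er family truth) costs ~0.2 s per
  call; dense paths are therefore much slower than sparse ones.
* Only hard partitions are supported; overlapping or hierarchical
  community models are out of scope.
* The GGM estimator targets hundreds of nodes, not the tens of
  thousands a specialized solver would handle.
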