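"""Network construction: loading, correlation, thresholding, grids, GGM, npn."""

import numpy as np
import pytest
from scipy import stats

from gapcom import (
    CorrelationMatrix,
    ExpressionMatrix,
    GGMConvergenceError,
    RegularizationPath,
    build_lambda_grid,
    compute_correlation,
    ggm_estimate,
    hard_threshold,
    load_expression,
    nonparanormal_transform,
    possible_edges,
)


class TestLoadExpression:
    def test_shape_bookkeeping(self, tmp_path):
        f = tmp_path / "x.tsv"
        f.write_text("g1\tg2\n1\t2\n3\t4\n5\t6\n")
        X = load_expression(f)
        assert (X.n, X.p) == (3, 2)
        assert X.gene_ids == ["g1", "g2"]

    def test_duplicate_header_rejected(self, tmp_path):
        f = tmp_path / "x.tsv"
        f.write_text("g1\tg1\n1\t2\n3\t4\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_expression(f)

    def test_non_numeric_cell_named(self, tmp_path):
        f = tmp_path / "x.tsv"
        f.write_text("g1\tg2\n1\t2\nfoo\t4\n")
        with pytest.raises(ValueError, match="g1"):
            load_expression(f)

    def test_round_trip_bit_identical(self, tmp_path):
        rng = np.random.default_rng(0)
        X = ExpressionMatrix.from_values(rng.standard_normal((6, 4)))
        f = tmp_path / "x.tsv"
        X.save(f)
        Y = load_expression(f)
        # full decimal repr is written, so values survive exactly
        np.testing.assert_array_equal(X.values, Y.values)

    def test_csv_delimiter(self, tmp_path):
        f = tmp_path / "x.csv"
        f.write_text("a,b\n1,2\n3,4\n")
        assert load_expression(f, delimiter=",").p == 2

    @pytest.mark.parametrize("n,p", [(1, 5), (5, 1)])
    def test_minimum_dimensions(self, n, p):
        with pytest.raises(ValueError):
            ExpressionMatrix.from_values(np.ones((n, p)))


class TestComputeCorrelation:
    def test_duplicated_column_perfect_correlation(self):
        rng = np.random.default_rng(1)
        col = rng.standard_normal(20)
        X = ExpressionMatrix.from_values(np.column_stack([col, col, rng.standard_normal(20)]))
        R = compute_correlation(X)
        assert R.values[0, 1] == pytest.approx(1.0)

    def test_unit_diagonal(self, tiny_expression):
        R = compute_correlation(tiny_expression)
        np.testing.assert_allclose(np.diag(R.values), 1.0)

    def test_matches_scalar_pearson_formula(self):
        rng = np.random.default_rng(2)
        vals = rng.standard_normal((4, 3))
        R = compute_correlation(ExpressionMatrix.from_values(vals))
        for i in range(3):
            for j in range(3):
                x, y = vals[:, i], vals[:, j]
                num = np.sum((x - x.mean()) * (y - y.mean()))
                den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
                assert R.values[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_column_convention(self):
        vals = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            R = compute_correlation(ExpressionMatrix.from_values(vals))
        assert R.values[0, 1] == 0.0
        assert R.values[0, 0] == 1.0


class TestHardThreshold:
    def _corr(self, offdiag):
        R = np.eye(3)
        R[0, 1] = R[1, 0] = offdiag[0]
        R[0, 2] = R[2, 0] = offdiag[1]
        R[1, 2] = R[2, 1] = offdiag[2]
        return CorrelationMatrix(R, ["a", "b", "c"])

    def test_lam_above_one_gives_empty_graph(self, tiny_expression):
        G = hard_threshold(compute_correlation(tiny_expression), 1.0)
        assert G.n_edges == 0
        assert G.sparsity == 0.0

    def test_lam_zero_gives_complete_graph(self, tiny_expression):
        G = hard_threshold(compute_correlation(tiny_expression), 0.0)
        assert G.sparsity == 1.0

    def test_enumerated_three_node_example(self):
        G = hard_threshold(self._corr([0.9, 0.2, -0.5]), 0.4)
        assert G.n_edges == 2
        assert G.adjacency[0, 1] and G.adjacency[1, 2]
        assert not G.adjacency[0, 2]

    def test_path_nesting_monotonicity(self, tiny_expression):
        R = compute_correlation(tiny_expression)
        lams = build_lambda_grid(R, 8, 0.5, spacing="sparsity")
        prev = None
        for lam in lams:  # ascending lam -> shrinking edge sets
            cur = hard_threshold(R, lam).adjacency
            if prev is not None:
                assert np.all(cur <= prev)
            prev = cur

    def test_pair_count_denominator(self):
        assert possible_edges(2810) == 3_946_645
        assert possible_edges(500) == 124_750


class TestLambdaGrid:
    def test_single_value_respects_cap(self, tiny_expression):
        R = compute_correlation(tiny_expression)
        lams = build_lambda_grid(R, 1, 0.2)
        assert lams.size >= 1
        assert hard_threshold(R, lams[-1]).sparsity <= 0.2

    @pytest.mark.parametrize("spacing", ["log", "linear", "sparsity"])
    def test_every_grid_point_obeys_cap(self, spacing):
        rng = np.random.default_rng(3)
        X = ExpressionMatrix.from_values(rng.standard_normal((40, 25)))
        R = compute_correlation(X)
        lams = build_lambda_grid(R, 50, 0.1, spacing=spacing)
        for lam in lams:
            assert hard_threshold(R, lam).sparsity <= 0.1 + 1e-12

    def test_default_grid_size_is_50(self, tiny_expression):
        import inspect

        assert inspect.signature(build_lambda_grid).parameters["n_values"].default == 50

    def test_too_few_distinct_values_warns(self):
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 0.5
        R[0, 2] = R[2, 0] = 0.5
        R[1, 2] = R[2, 1] = 0.5
        with pytest.warns(RuntimeWarning, match="distinct"):
            lams = build_lambda_grid(CorrelationMatrix(R, list("abc")), 10,
                                     1.0, spacing="sparsity")
        assert lams.size < 10

    def test_sparsity_spacing_covers_range_uniformly(self):
        rng = np.random.default_rng(4)
        X = ExpressionMatrix.from_values(rng.standard_normal((60, 40)))
        R = compute_correlation(X)
        lams = build_lambda_grid(R, 10, 0.5, spacing="sparsity")
        sps = np.sort([hard_threshold(R, l).sparsity for l in lams])
        np.testing.assert_allclose(sps, 0.5 * np.arange(1, 11) / 10, atol=0.01)


class TestGGM:
    def test_large_penalty_empty_graph(self, tiny_expression):
        G = ggm_estimate(tiny_expression, 2.0)
        assert G.n_edges == 0

    def test_two_gene_high_correlation_edge(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(200)
        y = 0.95 * x + np.sqrt(1 - 0.95**2) * rng.standard_normal(200)
        X = ExpressionMatrix.from_values(np.column_stack([x, y]))
        # closed form for 2x2 graphical lasso: the edge survives iff |r| > lam
        assert ggm_estimate(X, 0.2).n_edges == 1
        assert ggm_estimate(X, 0.99).n_edges == 0

    def test_support_symmetric_zero_diagonal(self, tiny_expression):
        G = ggm_estimate(tiny_expression, 0.3)
        assert np.array_equal(G.adjacency, G.adjacency.T)
        assert not G.adjacency.diagonal().any()

    def test_kkt_optimality_on_10x10(self):
        """Support satisfies graphical-lasso stationarity on a 10-gene problem.

        At the optimum W = Theta^{-1} of the penalized likelihood,
        S - W + lam*sign(Theta) = 0 where Theta_ij != 0, and
        |S_ij - W_ij| <= lam where Theta_ij = 0.
        """
        from sklearn.covariance import graphical_lasso

        model, X = None, None
        rng = np.random.default_rng(7)
        vals = rng.standard_normal((80, 10))
        vals[:, 1] += 0.8 * vals[:, 0]
        vals[:, 2] += 0.6 * vals[:, 1]
        X = ExpressionMatrix.from_values(vals)
        lam = 0.15
        G = ggm_estimate(X, lam)
        R = np.corrcoef(vals, rowvar=False)
        cov, prec = graphical_lasso(R, alpha=lam, max_iter=500, tol=1e-6)
        W = np.linalg.inv(prec)
        off = ~np.eye(10, dtype=bool)
        grad = R - W
        nonzero = (np.abs(prec) > 1e-8) & off
        zero = (~(np.abs(prec) > 1e-8)) & off
        assert np.allclose(grad[nonzero], -lam * np.sign(prec[nonzero]), atol=5e-3)
        assert np.all(np.abs(grad[zero]) <= lam + 5e-3)
        assert np.array_equal(G.adjacency, nonzero)

    def test_invalid_penalty(self, tiny_expression):
        with pytest.raises(ValueError):
            ggm_estimate(tiny_expression, 0.0)


class TestNonparanormal:
    def test_rank_invariance_under_monotone_map(self, tiny_expression):
        X = tiny_expression
        warped = ExpressionMatrix.from_values(np.exp(X.values))
        np.testing.assert_allclose(
            nonparanormal_transform(X).values,
            nonparanormal_transform(warped).values,
            atol=1e-12,
        )

    def test_output_shape(self, tiny_expression):
        assert nonparanormal_transform(tiny_expression).values.shape == \
            tiny_expression.values.shape

    def test_matches_truncated_ecdf_quantiles(self):
        rng = np.random.default_rng(8)
        n = 50
        col = rng.exponential(size=n)
        X = ExpressionMatrix.from_values(np.column_stack([col, rng.standard_normal(n)]))
        out = nonparanormal_transform(X).values[:, 0]
        delta = 1.0 / (4.0 * n**0.25 * np.sqrt(np.pi * np.log(n)))
        expected = stats.norm.ppf(np.clip(stats.rankdata(col) / n, delta, 1 - delta))
        expected = expected / expected.std()
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_constant_column_warns_and_zeros(self):
        vals = np.column_stack([np.full(20, 3.0), np.arange(20.0)])
        with pytest.warns(RuntimeWarning, match="constant"):
            out = nonparanormal_transform(ExpressionMatrix.from_values(vals))
        assert np.all(out.values[:, 0] == 0.0)


class TestRegularizationPath:
    def test_sparsity_non_increasing_for_threshold(self, tiny_expression):
        R = compute_correlation(tiny_expression)
        lams = build_lambda_grid(R, 10, 0.8)
        path = RegularizationPath.from_threshold_grid(R, lams)
        sps = path.sparsities
        assert np.all(np.diff(sps) <= 0)

    def test_misaligned_grid_rejected(self, tiny_expression):
        R = compute_correlation(tiny_expression)
        with pytest.raises(ValueError):
            RegularizationPath(np.array([0.2, 0.1]),
                               [hard_threshold(R, 0.2), hard_threshold(R, 0.1)])
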