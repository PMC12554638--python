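import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.stats import pearsonr, spearmanr

import dropfuse as df


def fused_similarity_oracle(M):
    """Independent step-by-step computation of the fused cell similarity."""
    n = M.shape[1]

    def metric_matrix(metric):
        S = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    S[i, j] = 1.0
                    continue
                a, b = M[:, i], M[:, j]
                if metric == "pearson":
                    S[i, j] = 0.0 if np.std(a) == 0 or np.std(b) == 0 else \
                        pearsonr(a, b)[0]
                elif metric == "spearman":
                    S[i, j] = 0.0 if np.std(a) == 0 or np.std(b) == 0 else \
                        spearmanr(a, b)[0]
                else:
                    na, nb = np.linalg.norm(a), np.linalg.norm(b)
                    S[i, j] = 0.0 if na == 0 or nb == 0 else a @ b / (na * nb)
        return S

    def minmax(S):
        out = np.empty_like(S)
        for i in range(n):
            lo, hi = S[i].min(), S[i].max()
            if hi == lo:
                out[i] = 0.0
                out[i, i] = 1.0
            else:
                out[i] = (S[i] - lo) / (hi - lo)
        return out

    factors = [0.5 * (minmax(metric_matrix(m)) + minmax(metric_matrix(m)).T)
               for m in ("pearson", "spearman", "cosine")]
    return np.cbrt(factors[0] * factors[1] * factors[2])


class TestMetricSimilarity:
    @pytest.mark.parametrize("metric", ["pearson", "spearman", "cosine"])
    def test_identical_columns_give_one(self, rng, metric):
        col = rng.random(10)
        M = np.column_stack([col, col, rng.random(10)])
        S = df.metric_similarity(M, metric).values
        assert S[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_pearson_antisymmetry(self, rng):
        a = rng.random(10)
        M = np.column_stack([a, -a + 2 * a.mean()])  # anti-correlated pair
        S = df.metric_similarity(M, "pearson").values
        assert S[0, 1] == pytest.approx(-1.0, abs=1e-12)
        assert S[0, 0] == 1.0

    @pytest.mark.parametrize("metric", ["pearson", "spearman", "cosine"])
    def test_scalar_loop_oracle(self, rng, metric):
        M = rng.random((8, 5))
        S = df.metric_similarity(M, metric).values
        for i in range(5):
            for j in range(5):
                if i == j:
                    assert S[i, j] == 1.0
                    continue
                a, b = M[:, i], M[:, j]
                if metric == "pearson":
                    expected = pearsonr(a, b)[0]
                elif metric == "spearman":
                    expected = spearmanr(a, b)[0]
                else:
                    expected = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
                assert S[i, j] == pytest.approx(expected, abs=1e-12)

    def test_single_cell_is_error(self):
        with pytest.raises(ValueError):
            df.metric_similarity(np.ones((4, 1)), "pearson")


class TestRowwiseMinmax:
    def test_already_framed_row_unchanged(self):
        S = df.SimilarityMatrix(np.array([[1.0, 0.5, 0.0],
                                          [0.5, 1.0, 0.0],
                                          [0.0, 0.0, 1.0]]), "cell")
        out = df.rowwise_minmax(S).values
        np.testing.assert_allclose(out[0], [1.0, 0.5, 0.0])

    def test_degenerate_constant_row(self):
        S = df.SimilarityMatrix(np.full((3, 3), 0.3), "cell")
        out = df.rowwise_minmax(S).values
        np.testing.assert_array_equal(np.diag(out), 1.0)
        assert out[0, 1] == 0.0 and out[0, 2] == 0.0

    def test_rows_span_unit_interval(self, rng):
        S = df.SimilarityMatrix(rng.random((6, 6)), "cell")
        out = df.rowwise_minmax(S).values
        np.testing.assert_allclose(out.min(axis=1), 0.0, atol=1e-15)
        np.testing.assert_allclose(out.max(axis=1), 1.0, atol=1e-15)


class TestSymmetrize:
    def test_symmetric_input_unchanged(self, rng):
        A = rng.random((5, 5))
        A = 0.5 * (A + A.T)
        out = df.symmetrize(df.SimilarityMatrix(A, "cell")).values
        np.testing.assert_array_equal(out, A)

    def test_forced_half(self):
        A = np.eye(2)
        A[0, 1] = 1.0
        out = df.symmetrize(df.SimilarityMatrix(A, "cell")).values
        assert out[0, 1] == 0.5 and out[1, 0] == 0.5

    def test_elementwise_oracle(self, rng):
        A = rng.random((5, 5))
        out = df.symmetrize(df.SimilarityMatrix(A, "cell")).values
        for i in range(5):
            for j in range(5):
                assert out[i, j] == pytest.approx(
                    (A[i, j] + A[j, i]) / 2, abs=1e-15)


class TestFuseCellSimilarity:
    @pytest.mark.parametrize("n_cells", [3, 4, 5, 6, 7, 8])
    def test_step_by_step_oracle(self, rng, n_cells):
        M = rng.random((10, n_cells))
        M[rng.random(M.shape) < 0.3] = 0.0
        fused = df.fuse_cell_similarity(M).values
        np.testing.assert_allclose(fused, fused_similarity_oracle(M),
                                   atol=1e-12)

    def test_symmetric_and_bounded(self, rng):
        M = rng.random((15, 7))
        fused = df.fuse_cell_similarity(M).values
        np.testing.assert_allclose(fused, fused.T, atol=1e-12)
        assert fused.min() >= 0.0 and fused.max() <= 1.0 + 1e-12

    def test_zero_factor_annihilates(self, rng):
        M = rng.random((12, 6))
        fused = df.fuse_cell_similarity(M).values
        # row-wise min-max guarantees each factor has zeros; wherever any
        # factor is zero the geometric mean must be exactly zero
        factors = []
        for metric in ("pearson", "spearman", "cosine"):
            S = df.metric_similarity(M, metric)
            factors.append(df.symmetrize(df.rowwise_minmax(S)).values)
        any_zero = (factors[0] == 0) | (factors[1] == 0) | (factors[2] == 0)
        assert np.all(fused[any_zero] == 0.0)

    def test_cell_permutation_equivariance(self, rng):
        M = rng.random((10, 6))
        perm = rng.permutation(6)
        A = df.fuse_cell_similarity(M).values
        B = df.fuse_cell_similarity(M[:, perm]).values
        np.testing.assert_allclose(B, A[np.ix_(perm, perm)], atol=1e-12)


class TestGeneJaccard:
    def test_forced_examples(self):
        M = np.zeros((3, 5))
        M[0, [1, 2, 3]] = 1.0   # support {1,2,3}
        M[1, [2, 3, 4]] = 2.0   # support {2,3,4}
        M[2, [1, 2, 3]] = 7.0   # same support as gene 0
        S = df.gene_jaccard(M).values
        assert S[0, 1] == pytest.approx(0.5)
        assert S[0, 2] == 1.0
        assert np.all(np.diag(S) == 1.0)

    def test_disjoint_and_empty_supports(self):
        M = np.zeros((3, 4))
        M[0, :2] = 1.0
        M[1, 2:] = 1.0
        S = df.gene_jaccard(M).values
        assert S[0, 1] == 0.0
        assert S[1, 2] == 0.0  # empty support -> 0 off-diagonal
        assert S[2, 2] == 1.0

    def test_set_oracle(self, rng):
        M = (rng.random((20, 15)) < 0.4) * rng.integers(1, 9, (20, 15))
        S = df.gene_jaccard(M).values
        supports = [set(np.flatnonzero(M[i] > 0)) for i in range(20)]
        for i in range(20):
            for j in range(20):
                if i == j:
                    expected = 1.0
                else:
                    u = supports[i] | supports[j]
                    expected = len(supports[i] & supports[j]) / len(u) if u \
                        else 0.0
                assert S[i, j] == expected

    def test_magnitude_invariance(self, rng):
        M = (rng.random((10, 8)) < 0.5) * rng.random((10, 8))
        S1 = df.gene_jaccard(M).values
        S2 = df.gene_jaccard(M * 1000 + (M > 0) * 3).values
        np.testing.assert_array_equal(S1, S2)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(B=hnp.arrays(bool, hnp.array_shapes(min_dims=2, max_dims=2,
                                               min_side=2, max_side=12)),
           scale=st.floats(0.5, 100))
    def test_depends_only_on_support_property(self, B, scale):
        S1 = df.gene_jaccard(B.astype(float)).values
        S2 = df.gene_jaccard(B.astype(float) * scale).values
        np.testing.assert_array_equal(S1, S2)
        np.testing.assert_array_equal(S1, S1.T)
        assert S1.min() >= 0 and S1.max() <= 1
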