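import numpy as np
import pytest

from coexatlas.atlas import AtlasError
from coexatlas.correlation import (
    CorrelationMatrix,
    adjusted_similarity_and_weights,
    mutual_rank,
    pearson_all_pairs,
    sample_similarity,
    weighted_pcc,
)

from conftest import make_atlas


def hand_pearson(x, y):
    """Direct covariance/sd-ratio oracle."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())


class TestPearson:
    def test_self_reversed_and_hand_computed(self):
        atlas = make_atlas([[1, 2, 4], [1, 3, 4], [4, 3, 1]], scale_state="log10")
        corr = pearson_all_pairs(atlas)
        assert corr.values[0, 0] == 1.0
        assert corr.values[0, 2] == pytest.approx(-1.0)  # g2 = 5 - g0
        # x=[1,2,4] vs y=[1,3,4]: cov/sd ratio gives exactly 13/14
        assert corr.values[0, 1] == pytest.approx(13 / 14, abs=1e-12)
        assert corr.values[0, 1] == pytest.approx(hand_pearson([1, 2, 4], [1, 3, 4]))

    def test_fewer_than_three_samples_rejected(self):
        atlas = make_atlas([[1, 2], [2, 1]], scale_state="log10")
        with pytest.raises(AtlasError):
            pearson_all_pairs(atlas)

    def test_requires_log_scale(self):
        atlas = make_atlas([[1, 2, 3], [2, 4, 6]], scale_state="raw")
        with pytest.raises(AtlasError):
            pearson_all_pairs(atlas)

    def test_constant_row_gets_zero_sentinel(self):
        atlas = make_atlas([[1, 1, 1], [1, 2, 3]], scale_state="log10")
        corr = pearson_all_pairs(atlas)
        assert corr.values[0, 1] == 0.0


class TestSampleSimilarity:
    def test_matches_pearson_on_transpose(self):
        rng = np.random.default_rng(3)
        atlas = make_atlas(rng.normal(size=(6, 4)), scale_state="log10")
        J = sample_similarity(atlas)
        transposed = make_atlas(atlas.values.T, scale_state="log10")
        oracle = pearson_all_pairs(transposed)
        np.testing.assert_allclose(J.to_numpy(), oracle.values, atol=1e-12)

    def test_duplicate_and_negated_columns(self):
        base = np.array([[1.0, 1.0, -1.0], [2.0, 2.0, -2.0], [4.0, 4.0, -4.0]])
        atlas = make_atlas(base, scale_state="log10")
        J = sample_similarity(atlas).to_numpy()
        assert J[0, 1] == pytest.approx(1.0)
        assert J[0, 2] == pytest.approx(-1.0)


class TestAdjustedSimilarityWeights:
    def test_rescaling_formula(self):
        J = np.array([[1.0, 0.7], [0.7, 1.0]])
        sw = adjusted_similarity_and_weights(J, C=0.4)
        assert sw.J_adj[0, 1] == pytest.approx(0.5)

    def test_identical_samples_weight(self):
        n = 4
        sw = adjusted_similarity_and_weights(np.ones((n, n)), C=0.4)
        np.testing.assert_allclose(sw.redundancy, n)
        np.testing.assert_allclose(sw.weights, 1 / np.sqrt(n))

    def test_boundary_similarity_is_zero_both_branches(self):
        J = np.array([[1.0, 0.4], [0.4, 1.0]])
        sw = adjusted_similarity_and_weights(J, C=0.4)
        assert sw.J_adj[0, 1] == 0.0

    def test_negative_similarities_zeroed(self):
        J = np.array([[1.0, -0.9], [-0.9, 1.0]])
        sw = adjusted_similarity_and_weights(J)
        assert sw.J_adj[0, 1] == 0.0
        np.testing.assert_allclose(sw.weights, 1.0)

    @pytest.mark.parametrize("C", [-0.1, 1.0, 1.5])
    def test_invalid_threshold(self, C):
        with pytest.raises(ValueError):
            adjusted_similarity_and_weights(np.eye(3), C=C)


class TestWeightedPCC:
    def test_uniform_weights_equal_plain_pcc(self, filtered_log_atlas):
        atlas = filtered_log_atlas
        plain = pearson_all_pairs(atlas)
        weighted = weighted_pcc(atlas, np.full(atlas.n_samples, 0.37))
        assert np.abs(weighted.values - plain.values).max() < 1e-12

    def test_zero_weight_equals_sample_deletion(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(5, 6))
        atlas = make_atlas(values, scale_state="log10")
        w = np.array([1, 1, 1, 1, 1, 0.0])
        weighted = weighted_pcc(atlas, w)
        deleted = pearson_all_pairs(make_atlas(values[:, :5], scale_state="log10"))
        np.testing.assert_allclose(weighted.values, deleted.values, atol=1e-12)

    def test_term_by_term_summation_oracle(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(3, 4))
        w = np.array([1.0, 1.0, 0.5, 0.5])
        atlas = make_atlas(X, scale_state="log10")
        result = weighted_pcc(atlas, w).values

        def oracle(x, y):
            xbar = sum(wi * xi for wi, xi in zip(w, x)) / w.sum()
            ybar = sum(wi * yi for wi, yi in zip(w, y)) / w.sum()
            num = sum(wi * (xi - xbar) * (yi - ybar) for wi, xi, yi in zip(w, x, y))
            den = np.sqrt(
                sum(wi * (xi - xbar) ** 2 for wi, xi in zip(w, x))
                * sum(wi * (yi - ybar) ** 2 for wi, yi in zip(w, y))
            )
            return num / den

        for i in range(3):
            for j in range(i + 1, 3):
                assert result[i, j] == pytest.approx(oracle(X[i], X[j]), abs=1e-12)

    def test_duplicate_sample_leaves_noiseless_weighted_pcc_unchanged(self):
        # perfectly linearly dependent genes: correlations are weight-invariant
        base = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0], [5.0, 4.0, 3.0, 2.0]])
        dup = np.hstack([base, base[:, -1:]])
        a0 = make_atlas(base, scale_state="log10")
        a1 = make_atlas(dup, scale_state="log10")
        sw1 = adjusted_similarity_and_weights(sample_similarity(a1))
        w1 = weighted_pcc(a1, sw1)
        sw0 = adjusted_similarity_and_weights(sample_similarity(a0))
        w0 = weighted_pcc(a0, sw0)
        assert np.abs(w1.values - w0.values).max() < 1e-6

    def test_weight_mismatch_rejected(self, filtered_log_atlas):
        with pytest.raises(AtlasError):
            weighted_pcc(filtered_log_atlas, np.ones(3))


def brute_force_mutual_rank(values):
    """Two-pass sort-and-lookup ranking oracle (average ranks on ties)."""
    n = values.shape[0]
    ranks = np.zeros((n, n))
    for i in range(n):
        partners = [j for j in range(n) if j != i]
        scores = sorted(set(values[i, j] for j in partners), reverse=True)
        for j in partners:
            equal = [k for k in partners if values[i, k] == values[i, j]]
            better = sum(1 for k in partners if values[i, k] > values[i, j])
            ranks[i, j] = better + (1 + len(equal)) / 2
    out = np.sqrt(ranks * ranks.T)
    np.fill_diagonal(out, np.nan)
    return out


class TestMutualRank:
    def test_reciprocal_top_partners(self):
        values = np.array([
            [1.0, 0.9, 0.1],
            [0.9, 1.0, 0.2],
            [0.1, 0.2, 1.0],
        ])
        corr = CorrelationMatrix(ids=list("abc"), values=values, kind="pcc")
        mr = mutual_rank(corr)
        assert mr.values[0, 1] == pytest.approx(1.0)

    def test_geometric_mean_of_ranks(self):
        # construct 9 genes where Rank_{A->B}=2 and Rank_{B->A}=8
        rng = np.random.default_rng(5)
        n = 9
        values = np.eye(n)
        A, B = 0, 1
        values[A, B] = values[B, A] = 0.5
        # A's view: one partner better than B; B's view: seven better than A
        others = list(range(2, n))
        for rank, j in enumerate(others):
            values[A, j] = 0.9 if rank == 0 else 0.1 - 0.01 * rank
            values[B, j] = 0.9 - 0.02 * rank  # all seven better than 0.5
            values[j, A] = values[A, j]
            values[j, B] = values[B, j]
        corr = CorrelationMatrix([f"g{i}" for i in range(n)], values, "pcc")
        mr = mutual_rank(corr)
        assert mr.values[A, B] == pytest.approx(4.0)

    def test_brute_force_oracle_with_tie(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(-1, 1, size=(6, 6))
        values = (values + values.T) / 2
        np.fill_diagonal(values, 1.0)
        values[0, 2] = values[2, 0] = values[0, 3] = values[3, 0] = 0.5  # planted tie
        corr = CorrelationMatrix([f"g{i}" for i in range(6)], values, "pcc")
        mr = mutual_rank(corr)
        oracle = brute_force_mutual_rank(values)
        np.testing.assert_allclose(mr.values, oracle, equal_nan=True)

    def test_symmetry_bounds_and_monotone_invariance(self):
        rng = np.random.default_rng(9)
        values = rng.uniform(-1, 1, size=(12, 12))
        values = (values + values.T) / 2
        np.fill_diagonal(values, 1.0)
        corr = CorrelationMatrix([f"g{i}" for i in range(12)], values, "pcc")
        mr = mutual_rank(corr)
        off = mr.values[~np.isnan(mr.values)]
        assert np.allclose(mr.values, mr.values.T, equal_nan=True)
        assert off.min() >= 1.0 and off.max() <= 11.0
        # rank-preserving transform of correlations leaves MR unchanged
        transformed = CorrelationMatrix(
            list(corr.ids), np.tanh(2.0 * values), "pcc"
        )
        np.testing.assert_allclose(
            mutual_rank(transformed).values, mr.values, equal_nan=True
        )

    def test_requires_correlation_kind_and_size(self):
        corr = CorrelationMatrix(["a", "b"], np.eye(2), "pcc")
        with pytest.raises(ValueError):
            mutual_rank(corr)
        mr_kind = CorrelationMatrix(list("abc"), np.ones((3, 3)), "mutual_rank")
        with pytest.raises(ValueError):
            mutual_rank(mr_kind)
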