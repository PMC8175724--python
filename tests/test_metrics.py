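"""Network statistics: strength distribution, stability RMSE, clusters."""

import numpy as np
import networkx as nx
import pytest

from enform import (
    ClusterCurve,
    cluster_curve,
    degree_product_weights,
    max_cluster_size,
    node_strength,
    stability_rmse,
    strength_distribution,
)


def star_matrix(n):
    """Hub 0 connected symmetrically to all others, weights 1."""
    W = np.zeros((n, n))
    W[0, 1:] = 1.0
    W[1:, 0] = 1.0
    return W


def nx_max_degree(W):
    """Independent oracle: maximum degree of the nonzero-support graph."""
    W = np.asarray(W, float)
    G = nx.Graph()
    G.add_nodes_from(range(W.shape[0]))
    rows, cols = np.nonzero(W)
    G.add_edges_from((i, j) for i, j in zip(rows, cols) if i != j)
    return max(dict(G.degree).values()) if G.number_of_edges() else 0


class TestNodeStrength:
    def test_examples(self):
        np.testing.assert_allclose(node_strength(np.eye(3)), [1, 1, 1])
        np.testing.assert_allclose(node_strength([[0, -3], [2, 0]]), [3, 2])

    def test_trained_network_has_higher_cv_than_its_random_start(
        self, reduced_limited
    ):
        res = reduced_limited[0]
        s_tr = node_strength(res.weights)
        s_in = node_strength(res.initial_weights)
        cv = lambda s: s.std() / s.mean()
        assert cv(s_in) < cv(s_tr)


class TestStrengthDistribution:
    def test_constant_vector_is_flat_at_one(self):
        d = strength_distribution(np.full(300, 4.2))
        np.testing.assert_array_equal(d.strengths, 1.0)
        assert len(d.strengths) == 100

    def test_staircase_matches_direct_rank_lookup(self):
        # 101 values 101, 100, ..., 1: quantile point n must land on the
        # descending-order element of rank round((n+1)/101 * 101) = n+1,
        # i.e. value 101 - (n + 1)
        values = np.arange(101, 0, -1, dtype=float)
        d = strength_distribution(values)
        expected = np.array([101 - (n + 1) for n in range(100)]) / 101.0
        np.testing.assert_allclose(d.strengths, expected)
        np.testing.assert_allclose(d.probabilities, (np.arange(100) + 1) / 101)

    def test_short_input_uses_every_value(self):
        d = strength_distribution(np.arange(65, 0, -1, dtype=float))
        assert len(d.strengths) == 65
        np.testing.assert_allclose(d.probabilities, (np.arange(65) + 1) / 66)

    def test_strengths_nonincreasing_and_in_unit_interval(self, rng):
        d = strength_distribution(rng.exponential(size=500))
        assert (np.diff(d.strengths) <= 1e-15).all()
        assert d.strengths.max() <= 1.0 and d.strengths.min() > 0.0

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            strength_distribution(np.zeros(10))
        with pytest.raises(ValueError):
            strength_distribution([])


class TestStabilityRMSE:
    def test_identical_networks_give_zero(self, rng):
        W = rng.normal(size=(5, 5))
        assert stability_rmse([W, W.copy()]) == 0.0

    def test_permutations_give_zero(self, rng):
        W = rng.normal(size=(4, 4))
        perm = rng.permutation(16).reshape(4, 4)
        assert stability_rmse([W, W.ravel()[perm]]) == pytest.approx(0.0)

    def test_global_rescaling_is_invisible(self, rng):
        W = rng.normal(size=(4, 4))
        V = rng.normal(size=(4, 4))
        assert stability_rmse([W, V]) == pytest.approx(
            stability_rmse([3.7 * W, 0.2 * V]), rel=1e-12
        )

    def test_hand_rmse(self):
        # ordered normalized weights (2,1,.5,.5) vs (1.5,1.5,.5,.5):
        # RMSE = sqrt((.25+.25+0+0)/4) = sqrt(0.125)
        A = np.array([[2.0, 1.0], [0.5, 0.5]])
        B = np.array([[1.5, 1.5], [0.5, 0.5]])
        assert stability_rmse([A, B]) == pytest.approx(np.sqrt(0.125))

    def test_average_over_three_pairs(self, rng):
        mats = [rng.normal(size=(3, 3)) for _ in range(3)]
        pairwise = [
            stability_rmse([mats[i], mats[j]])
            for i, j in ((0, 1), (0, 2), (1, 2))
        ]
        assert stability_rmse(mats) == pytest.approx(np.mean(pairwise))

    def test_shape_mismatch_names_pair(self, rng):
        with pytest.raises(ValueError, match="network 1"):
            stability_rmse([np.eye(2), np.eye(3)])

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            stability_rmse([np.eye(2)])


class TestMaxClusterSize:
    def test_star_full_network(self):
        assert max_cluster_size(star_matrix(12), 1.0) == 11

    def test_full_ratio_matches_networkx_degree_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 15))
            W = rng.normal(size=(n, n)) * (rng.random((n, n)) < 0.4)
            if not (W - np.diag(np.diag(W))).any():
                continue
            assert max_cluster_size(W, 1.0) == nx_max_degree(W)

    def test_perfect_matching_caps_at_one(self):
        W = np.zeros((6, 6))
        for a, b in ((0, 1), (2, 3), (4, 5)):
            W[a, b] = W[b, a] = 1.0
        for r in (0.2, 0.5, 1.0):
            assert max_cluster_size(W, r) <= 1

    def test_tiny_ratio_returns_zero(self):
        assert max_cluster_size(star_matrix(5), 0.01) == 0

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            max_cluster_size(star_matrix(5), 0.0)

    def test_diagonal_is_ignored(self):
        W = np.diag([5.0, 5.0, 5.0])
        W[0, 1] = 1.0
        assert max_cluster_size(W, 1.0) == 1


class TestClusterCurve:
    def test_directed_star_curve_by_enumeration(self):
        # hub -> 19 leaves, n_c = 19 entries; any k of them reach exactly
        # k distinct leaves, so the curve is floor(r * 19) / 19 ~ r
        W = np.zeros((20, 20))
        W[0, 1:] = np.arange(19, 0, -1)  # distinct weights: no tie ambiguity
        curve = cluster_curve(W)
        for r, size in zip(curve.ratios, curve.sizes):
            k = int(np.floor(r * 19))
            assert size == pytest.approx(k / 19.0)
        assert curve.sizes[-1] == 1.0

    def test_monotone_and_ends_at_one_random_matrices(self, rng):
        for _ in range(300):
            n = int(rng.integers(3, 12))
            W = rng.normal(size=(n, n)) * (rng.random((n, n)) < 0.6)
            np.fill_diagonal(W, 0.0)
            if not W.any():
                continue
            curve = cluster_curve(W, r_step=0.05)
            assert (np.diff(curve.sizes) >= -1e-15).all()
            assert curve.sizes[-1] == 1.0

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            cluster_curve(np.zeros((4, 4)))

    def test_at_accessor(self):
        curve = ClusterCurve(ratios=np.array([0.5, 1.0]),
                             sizes=np.array([0.4, 1.0]))
        assert curve.at(0.49) == 0.4


class TestDegreeProductWeights:
    def test_star_graph(self):
        W = degree_product_weights(star_matrix(10))
        # hub degree 9, leaves degree 1: every existing edge weighs 9
        assert set(np.unique(W)) == {0.0, 9.0}
        assert (W[0, 1:] == 9.0).all() and (W[1:, 0] == 9.0).all()

    def test_complete_graph(self):
        n = 5
        A = np.ones((n, n)) - np.eye(n)
        W = degree_product_weights(A)
        off = W[~np.eye(n, dtype=bool)]
        assert (off == (n - 1) ** 2).all()

    def test_empty_graph(self):
        assert not degree_product_weights(np.zeros((4, 4))).any()

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="raw weights"):
            degree_product_weights(np.full((2, 2), 0.5))


class TestTrainedVersusRandomBaselines:
    def test_trained_strength_range_is_wider(self, reduced_limited):
        from enform import strength_distribution

        pooled_tr = np.concatenate(
            [node_strength(r.weights) for r in reduced_limited]
        )
        pooled_in = np.concatenate(
            [node_strength(r.initial_weights) for r in reduced_limited]
        )
        d_tr = strength_distribution(pooled_tr)
        d_in = strength_distribution(pooled_in)
        assert d_tr.value_range < d_in.value_range
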