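import numpy as np
import pytest
from sklearn.base import clone
from sklearn.metrics import adjusted_rand_score

from scnrank.network import IntegratedNetwork
from scnrank.spectral import (NetworkSpectralClustering, build_matrices,
                              choose_k_hartigan, eigendecompose,
                              spectral_cluster)


def two_node_net(fc=(2.0, 2.0), r=1.0):
    return IntegratedNetwork(nodes=["a", "b"],
                             node_weight={"a": fc[0], "b": fc[1]},
                             edge_weight={("a", "b"): r}, context="tissue")


def clique_pair_net(n1=5, n2=5, r=0.9, fc=1.0):
    """Two disconnected cliques with uniform intra-clique correlation."""
    nodes = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    ew = {}
    for grp in (nodes[:n1], nodes[n1:]):
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                ew[(grp[i], grp[j])] = r
    return IntegratedNetwork(nodes=nodes, node_weight={g: fc for g in nodes},
                             edge_weight=ew, context="tissue")


class TestBuildMatrices:
    def test_two_node_hand_example(self):
        # hand evaluation: S'=[[1,1],[1,1]], row sums 2, FC=(2,2)
        mats = build_matrices(two_node_net())
        np.testing.assert_allclose(mats.S_prime, [[1, 1], [1, 1]])
        np.testing.assert_allclose(mats.S_dprime, [[1, 1], [1, 1]])
        np.testing.assert_allclose(mats.L_raw, [[1, -1], [-1, 1]])
        np.testing.assert_allclose(mats.L_norm, [[0.5, -0.5], [-0.5, 0.5]])

    def test_degree_limit_reproduces_standard_laplacian(self):
        # binary correlations + FC = row sums of S' makes S'' = S' and
        # L_raw = (D + I) - (A + I) = D - A, the ordinary graph Laplacian
        rng = np.random.default_rng(0)
        n = 12
        adj = np.triu((rng.random((n, n)) < 0.4).astype(float), k=1)
        adj = adj + adj.T
        adj[0, 1] = adj[1, 0] = 1.0  # ensure no empty rows
        nodes = [f"g{i:02d}" for i in range(n)]
        ew = {(nodes[i], nodes[j]): 1.0
              for i in range(n) for j in range(i + 1, n) if adj[i, j]}
        fc = adj.sum(axis=1) + 1.0  # row sums including the unit diagonal
        net = IntegratedNetwork(nodes=nodes,
                                node_weight=dict(zip(nodes, fc)),
                                edge_weight=ew, context="tissue")
        mats = build_matrices(net)
        degree_laplacian = np.diag(adj.sum(axis=1)) - adj
        np.testing.assert_allclose(mats.L_raw, degree_laplacian, atol=1e-12)
        np.testing.assert_allclose(mats.S_dprime, mats.S_prime, atol=1e-12)

    def test_single_node_degenerate(self):
        net = IntegratedNetwork(nodes=["a"], node_weight={"a": 1.5},
                                edge_weight={}, context="tissue")
        mats = build_matrices(net)
        np.testing.assert_allclose(mats.L_norm, [[0.0]])

    def test_row_sums_match_node_weight(self):
        # each row of S'' sums to FC_a when the row sum is non-degenerate
        net = clique_pair_net(4, 3, r=0.6, fc=1.0)
        for g in net.nodes:
            net.node_weight[g] = 1.0 + net.nodes.index(g) * 0.1
        mats = build_matrices(net)
        np.testing.assert_allclose(mats.S_dprime.sum(axis=1), mats.D_prime,
                                   atol=1e-12)

    def test_nonpositive_weight_rejected(self):
        net = two_node_net()
        net.node_weight["a"] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            build_matrices(net)


class TestEigendecompose:
    def test_two_node_eigenvalues_by_characteristic_polynomial(self):
        mats = build_matrices(two_node_net())
        vals, vecs = eigendecompose(mats, 2)
        np.testing.assert_allclose(vals, [0.0, 1.0], atol=1e-12)

    def test_zero_multiplicity_counts_components(self):
        # standard-Laplacian limit: eigenvalue 0 once per connected block
        net = clique_pair_net(4, 4, r=1.0)
        for g in net.nodes:
            net.node_weight[g] = 4.0  # row sum of binary S' with diagonal
        mats = build_matrices(net)
        vals, _ = eigendecompose(mats, 8)
        assert np.sum(np.abs(vals) < 1e-10) == 2

    def test_full_reconstruction(self):
        net = clique_pair_net(2, 1, r=0.5)
        mats = build_matrices(net)
        vals, vecs = eigendecompose(mats, 3)
        sym = (mats.L_norm + mats.L_norm.T) / 2
        np.testing.assert_allclose(vecs @ np.diag(vals) @ vecs.T, sym, atol=1e-8)
        np.testing.assert_allclose(vecs.T @ vecs, np.eye(3), atol=1e-8)

    def test_deterministic_sign_convention(self):
        mats = build_matrices(clique_pair_net())
        _, v1 = eigendecompose(mats, 4)
        _, v2 = eigendecompose(mats, 4)
        np.testing.assert_array_equal(v1, v2)
        for j in range(4):
            assert v1[np.argmax(np.abs(v1[:, j])), j] > 0


class TestChooseKHartigan:
    def _blobs(self, seed, n=12, sep=5.0):
        # Hartigan's H(k) carries an (n - k - 1) factor, so the 10-rule
        # only stops for modest n; 12-point blobs sit in its regime
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 0.5, size=(n, 2))
        b = rng.normal(sep, 0.5, size=(n, 2))
        return np.vstack([a, b])

    def test_two_blobs_selects_two(self):
        emb = self._blobs(0)
        k, trace = choose_k_hartigan(emb, k_max=5, seed=0, restarts=20)
        assert k == 2
        frame = trace.to_frame().set_index("k")
        assert frame.loc[1, "hartigan"] > 10 > frame.loc[2, "hartigan"]

    def test_hartigan_formula_against_direct_wk(self):
        # oracle: recompute H(k) from the trace's own W_k values
        emb = self._blobs(3)
        n = emb.shape[0]
        _, trace = choose_k_hartigan(emb, k_max=4, seed=0)
        f = trace.to_frame()
        for i in range(len(f) - 1):
            k, wk = int(f.loc[i, "k"]), f.loc[i, "within_ss"]
            wk1 = f.loc[i + 1, "within_ss"]
            expected = (wk / wk1 - 1.0) * (n - k - 1)
            assert f.loc[i, "hartigan"] == pytest.approx(expected, rel=1e-9)

    def test_identical_points_give_k1(self):
        emb = np.ones((5, 2))
        k, _ = choose_k_hartigan(emb, k_max=3, seed=0)
        assert k == 1

    def test_within_ss_nonincreasing(self):
        emb = self._blobs(1)
        _, trace = choose_k_hartigan(emb, k_max=6, seed=0, restarts=10)
        w = trace.to_frame()["within_ss"].to_numpy()
        assert np.all(np.diff(w) <= 1e-9)


class TestSpectralCluster:
    def test_disconnected_cliques_recovered(self):
        net = clique_pair_net(6, 5, r=0.9, fc=1.0)
        res = spectral_cluster(net, k=2, seed=0)
        truth = [0] * 6 + [1] * 5
        pred = [res.assignment[g] for g in net.nodes]
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_k1_single_cluster(self):
        net = clique_pair_net(3, 3)
        res = spectral_cluster(net, k=1, seed=0)
        assert res.K == 1
        assert set(res.assignment.values()) == {0}

    def test_k_equals_n_singletons(self):
        net = clique_pair_net(3, 2, r=0.5)
        res = spectral_cluster(net, k=5, seed=0)
        assert res.K == 5
        assert sorted(res.assignment.values()) == list(range(5))

    def test_auto_k_on_cliques(self):
        net = clique_pair_net(8, 8, r=0.9)
        res = spectral_cluster(net, seed=0, k_max=6)
        assert res.K == 2
        assert res.hartigan_trace is not None

    def test_deterministic_under_seed(self):
        net = clique_pair_net(6, 6, r=0.8)
        r1 = spectral_cluster(net, k=2, seed=42)
        r2 = spectral_cluster(net, k=2, seed=42)
        assert r1.assignment == r2.assignment
        np.testing.assert_array_equal(r1.embedding, r2.embedding)

    def test_invariant_to_node_order(self):
        net = clique_pair_net(5, 4, r=0.8)
        perm = list(reversed(net.nodes))
        net2 = IntegratedNetwork(nodes=perm,
                                 node_weight=dict(net.node_weight),
                                 edge_weight=dict(net.edge_weight),
                                 context="tissue")
        r1 = spectral_cluster(net, k=2, seed=0)
        r2 = spectral_cluster(net2, k=2, seed=0)
        g1 = [set(r1.members(c)) for c in range(r1.K)]
        g2 = [set(r2.members(c)) for c in range(r2.K)]
        assert sorted(map(sorted, g1)) == sorted(map(sorted, g2))


class TestEstimatorInterface:
    def _affinity(self):
        net = clique_pair_net(5, 5, r=0.9)
        from scnrank.spectral import build_matrices
        return build_matrices(net).S_prime

    def test_fit_predict_and_attributes(self):
        S = self._affinity()
        est = NetworkSpectralClustering(n_clusters=2, random_state=0)
        labels = est.fit_predict(S)
        assert est.n_clusters_ == 2
        assert labels.shape == (10,)
        assert adjusted_rand_score([0] * 5 + [1] * 5, labels) == 1.0
        assert est.embedding_.shape[0] == 10

    def test_sklearn_clone_and_params(self):
        est = NetworkSpectralClustering(n_clusters=3, hartigan_threshold=8.0)
        cloned = clone(est)
        assert cloned.get_params()["n_clusters"] == 3
        assert cloned.get_params()["hartigan_threshold"] == 8.0

    def test_auto_k(self):
        est = NetworkSpectralClustering(n_clusters="auto", k_max=5,
                                        random_state=0)
        est.fit(self._affinity())
        assert est.n_clusters_ == 2
        assert est.hartigan_trace_ is not None
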