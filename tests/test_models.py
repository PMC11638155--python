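"""Layer mathematics of the three classifiers, plus gradient checks."""

import numpy as np
import pytest

from cognigraph import ModelSpec, init_params
from cognigraph import autodiff as ad
from cognigraph.models import (forward, gat_attention, gat_forward,
                               gcn_forward, mlp_forward,
                               normalized_adjacency)


def softmax(z):
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def random_instance(kind, n=5, seed=0):
    rng = np.random.default_rng(seed)
    spec = ModelSpec.for_kind(kind)
    x = rng.normal(size=(n, spec.in_features))
    edges = [(i, (i + 1) % n) for i in range(n)]
    edge_index = np.array(edges + [(j, i) for i, j in edges])
    labels = rng.integers(0, 3, size=n)
    params = init_params(spec, seed=seed + 1)
    return spec, x, edge_index, labels, params


class TestInit:
    def test_same_seed_bit_identical(self):
        for kind in ("MLP", "GCN", "GAT"):
            a = init_params(ModelSpec.for_kind(kind), seed=4)
            b = init_params(ModelSpec.for_kind(kind), seed=4)
            assert a.keys() == b.keys()
            for k in a:
                np.testing.assert_array_equal(a[k], b[k])

    def test_different_seeds_differ(self):
        a = init_params(ModelSpec.for_kind("MLP"), seed=0)
        b = init_params(ModelSpec.for_kind("MLP"), seed=1)
        assert any(not np.array_equal(a[k], b[k]) for k in a)

    def test_mlp_shapes(self):
        p = init_params(ModelSpec.for_kind("MLP"), seed=0)
        assert p["W1"].shape == (11, 16)
        assert p["W2"].shape == (16, 8)
        assert p["W3"].shape == (8, 3)
        assert p["b3"].shape == (3,)

    def test_gcn_and_gat_shapes(self):
        p = init_params(ModelSpec.for_kind("GCN"), seed=0)
        assert p["W1"].shape == (11, 16) and p["W2"].shape == (16, 3)
        q = init_params(ModelSpec.for_kind("GAT"), seed=0)
        assert q["W1_h0"].shape == (11, 16) and q["a1_src_h7"].shape == (16,)
        assert q["W2"].shape == (128, 3)


class TestMLP:
    def test_zero_params_give_uniform_probabilities(self):
        p = {k: np.zeros_like(v)
             for k, v in init_params(ModelSpec.for_kind("MLP"), 0).items()}
        logits = mlp_forward(np.random.default_rng(0).normal(size=(4, 11)), p)
        np.testing.assert_allclose(softmax(logits.data), np.full((4, 3), 1 / 3))

    def test_hand_computed_sparse_forward(self):
        """Pencil-and-paper pass with one active unit per layer."""
        p = {k: np.zeros_like(v)
             for k, v in init_params(ModelSpec.for_kind("MLP"), 0).items()}
        x = np.zeros(11)
        x[0] = 2.0
        p["W1"][0, 0] = 1.5        # h1_0 = relu(2*1.5) = 3
        p["b1"][1] = -1.0          # h1_1 = relu(-1) = 0
        p["W2"][0, 2] = 0.5        # h2_2 = relu(3*0.5 + 1) = 2.5
        p["b2"][2] = 1.0
        p["W3"][2, 1] = 2.0        # logit_1 = 2.5*2 - 0.25 = 4.75
        p["b3"][1] = -0.25
        logits = mlp_forward(x, p)
        np.testing.assert_allclose(logits.data, [[0.0, 4.75, 0.0]], atol=1e-12)

    def test_eval_mode_ignores_dropout_seed(self):
        spec, x, _, _, p = random_instance("MLP")
        a = mlp_forward(x, p, training=False, rng=np.random.default_rng(0))
        b = mlp_forward(x, p, training=False, rng=np.random.default_rng(99))
        np.testing.assert_array_equal(a.data, b.data)

    def test_training_dropout_changes_output(self):
        spec, x, _, _, p = random_instance("MLP")
        a = mlp_forward(x, p, training=True, rng=np.random.default_rng(0))
        b = mlp_forward(x, p, training=True, rng=np.random.default_rng(1))
        assert not np.array_equal(a.data, b.data)

    def test_wrong_column_count_raises(self):
        p = init_params(ModelSpec.for_kind("MLP"), 0)
        with pytest.raises(ValueError, match="feature columns"):
            mlp_forward(np.ones((3, 7)), p)


class TestGCN:
    def test_empty_edge_set_equals_nodewise_network(self):
        """With no edges, A_hat = I and the GCN is a per-node 2-layer net."""
        spec, x, _, _, p = random_instance("GCN", n=6, seed=2)
        empty = np.empty((0, 2), dtype=int)
        got = gcn_forward(x, empty, p).data
        h = np.maximum(x @ p["W1"] + p["b1"], 0.0)   # no-graph oracle
        expected = h @ p["W2"] + p["b2"]
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_two_node_hand_propagation(self):
        """Connected pair, scalar weights: A_hat = [[.5,.5],[.5,.5]]."""
        spec = ModelSpec(kind="GCN", in_features=1, gcn_hidden=1, n_classes=1)
        a_hat = normalized_adjacency(np.array([[0, 1], [1, 0]]), 2)
        np.testing.assert_allclose(a_hat, [[0.5, 0.5], [0.5, 0.5]], atol=1e-12)
        x = np.array([[1.0], [3.0]])
        p = {"W1": np.array([[1.0]]), "b1": np.zeros(1),
             "W2": np.array([[1.0]]), "b2": np.zeros(1)}
        out = gcn_forward(x, np.array([[0, 1], [1, 0]]), p, spec=spec).data
        # h = relu(A x) = [2, 2]; out = A h = [2, 2]
        np.testing.assert_allclose(out, [[2.0], [2.0]], atol=1e-12)

    def test_dense_matrix_oracle_on_random_instance(self):
        spec, x, edge_index, _, p = random_instance("GCN", n=6, seed=3)
        got = gcn_forward(x, edge_index, p).data
        # explicit dense oracle
        n = 6
        a = np.zeros((n, n))
        for i, j in edge_index:
            a[i, j] = 1.0
        a_tilde = a + np.eye(n)
        d = a_tilde.sum(1)
        a_hat = a_tilde / np.sqrt(np.outer(d, d))
        h = np.maximum(a_hat @ x @ p["W1"] + p["b1"], 0.0)
        expected = a_hat @ h @ p["W2"] + p["b2"]
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_out_of_range_edge_raises(self):
        spec, x, _, _, p = random_instance("GCN")
        with pytest.raises(IndexError):
            gcn_forward(x, np.array([[0, 9]]), p)


class TestGAT:
    def test_attention_rows_sum_to_one(self):
        spec, x, edge_index, _, p = random_instance("GAT", n=7, seed=4)
        for head in (0, 3, 7):
            alpha = gat_attention(x, edge_index, p, head=head)
            np.testing.assert_allclose(alpha.sum(axis=1), np.ones(7),
                                       atol=1e-12)

    def test_isolated_node_attends_only_to_itself(self):
        spec, x, _, _, p = random_instance("GAT", n=4, seed=5)
        edge_index = np.array([[0, 1], [1, 0]])  # nodes 2, 3 isolated
        alpha = gat_attention(x, edge_index, p, head=0)
        assert alpha[2, 2] == pytest.approx(1.0)
        assert alpha[3, 3] == pytest.approx(1.0)
        # isolated node's head output is its own transformed feature
        h = x @ p["W1_h0"]
        out = gat_forward(x, edge_index, p).data
        assert np.all(np.isfinite(out))
        np.testing.assert_allclose((alpha @ h)[2], h[2], atol=1e-12)

    def test_two_node_hand_computed_attention(self):
        """Single head, scalar features: alpha matches a by-hand softmax."""
        spec = ModelSpec(kind="GAT", in_features=1, gat_heads=1,
                         gat_head_units=1, n_classes=1, dropout=0.2)
        w = np.array([[1.0]])
        a_src, a_dst = np.array([0.5]), np.array([-0.25])
        p = {"W1_h0": w, "a1_src_h0": a_src, "a1_dst_h0": a_dst,
             "b1": np.zeros(1), "W2": np.array([[1.0]]),
             "a2_src": np.zeros(1), "a2_dst": np.zeros(1), "b2": np.zeros(1)}
        x = np.array([[1.0], [2.0]])
        edge_index = np.array([[0, 1], [1, 0]])
        alpha = gat_attention(x, edge_index, p, head=0, spec=spec)
        # h = [1, 2]; e_ij = leakyrelu(0.5 h_i - 0.25 h_j)
        e = np.array([[0.25, 0.0], [0.75, 0.5]])
        expected = softmax(e)
        np.testing.assert_allclose(alpha, expected, atol=1e-12)

    def test_leaky_relu_negative_branch_in_attention(self):
        spec = ModelSpec(kind="GAT", in_features=1, gat_heads=1,
                         gat_head_units=1, n_classes=1, dropout=0.2)
        p = {"W1_h0": np.array([[1.0]]), "a1_src_h0": np.array([-1.0]),
             "a1_dst_h0": np.array([0.0]), "b1": np.zeros(1),
             "W2": np.array([[1.0]]), "a2_src": np.zeros(1),
             "a2_dst": np.zeros(1), "b2": np.zeros(1)}
        x = np.array([[1.0], [2.0]])
        alpha = gat_attention(x, np.array([[0, 1], [1, 0]]), p, spec=spec)
        # raw scores: row0 = [-1, -1], row1 = [-2, -2] -> leaky slope 0.2
        expected = softmax(np.array([[-0.2, -0.2], [-0.4, -0.4]]))
        np.testing.assert_allclose(alpha, expected, atol=1e-12)


class TestSharedProperties:
    @pytest.mark.parametrize("kind", ["MLP", "GCN", "GAT"])
    def test_eval_mode_deterministic(self, kind):
        spec, x, edge_index, _, p = random_instance(kind, seed=6)
        ei = None if kind == "MLP" else edge_index
        a = forward(spec, x, ei, p)
        b = forward(spec, x, ei, p)
        np.testing.assert_array_equal(a.data, b.data)

    @pytest.mark.parametrize("kind", ["MLP", "GCN", "GAT"])
    def test_permutation_equivariance(self, kind):
        spec, x, edge_index, _, p = random_instance(kind, n=6, seed=7)
        perm = np.random.default_rng(0).permutation(6)
        inv = np.argsort(perm)
        ei = None if kind == "MLP" else edge_index
        base = forward(spec, x, ei, p).data
        ei_perm = None if kind == "MLP" else inv[edge_index]
        permuted = forward(spec, x[perm], ei_perm, p).data
        np.testing.assert_allclose(permuted, base[perm], atol=1e-10)

    @pytest.mark.parametrize("kind", ["MLP", "GCN", "GAT"])
    def test_finite_logits_with_isolated_nodes(self, kind):
        spec, x, _, _, p = random_instance(kind, n=5, seed=8)
        ei = None if kind == "MLP" else np.empty((0, 2), dtype=int)
        out = forward(spec, x, ei, p)
        assert np.all(np.isfinite(out.data))

    @pytest.mark.parametrize("kind", ["MLP", "GCN", "GAT"])
    def test_gradients_match_finite_differences(self, kind):
        """Central finite differences vs reverse-mode gradients, 1e-4 relative."""
        spec, x, edge_index, labels, params = random_instance(kind, n=5,
                                                              seed=9)
        ei = None if kind == "MLP" else edge_index

        def loss_value(p):
            logits = forward(spec, x, ei, p)
            return float(ad.cross_entropy_with_logits(
                logits, labels, np.arange(5)).data)

        tensors = {k: ad.Tensor(v, requires_grad=True)
                   for k, v in params.items()}
        loss = ad.cross_entropy_with_logits(
            forward(spec, x, ei, tensors), labels, np.arange(5))
        loss.backward()
        eps = 1e-6
        rng = np.random.default_rng(10)
        for name, value in params.items():
            flat = value.ravel()
            picks = rng.choice(flat.size, size=min(5, flat.size),
                               replace=False)
            for idx in picks:
                bumped = {k: v.copy() for k, v in params.items()}
                bumped[name].ravel()[idx] += eps
                up = loss_value(bumped)
                bumped[name].ravel()[idx] -= 2 * eps
                down = loss_value(bumped)
                fd = (up - down) / (2 * eps)
                an = tensors[name].grad.ravel()[idx]
                assert an == pytest.approx(fd, rel=1e-4, abs=1e-7), \
                    f"{kind} {name}[{idx}]"
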