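"""Message-passing layers against dense-matrix oracles; model properties."""

import numpy as np
import pytest

from moimech._autodiff import Tensor
from moimech.gnn import (
    GNNModel,
    gat_forward,
    gcn_forward,
    gcn_norm,
    gin_forward,
    load_checkpoint,
    make_layer,
    model_forward,
    save_checkpoint,
)
from moimech.graphs import AttributedGraph

from conftest import random_graph


def _identity_layer(arch, d, **kw):
    rng = np.random.default_rng(0)
    p = make_layer(arch, d, d, rng, **kw)
    p.W.data = np.eye(d)
    if p.bias is not None:
        p.bias.data[:] = 0.0
    return p


class TestGCN:
    def test_isolated_node_with_identity_weights_is_fixed_point(self):
        p = _identity_layer("gcn", 3)
        H = np.array([[1.0, -2.0, 0.5]])
        out = gcn_forward(H, np.zeros((1, 1)), p)
        assert np.allclose(out.data, H)

    def test_two_node_worked_example(self):
        # scalar features [1, 3], W = [1]: each node has degree 2 with its
        # self-loop, so both pre-activation outputs are (1/2)*1 + (1/2)*3 = 2
        p = _identity_layer("gcn", 1)
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = gcn_forward(np.array([[1.0], [3.0]]), A, p)
        assert np.allclose(out.data, [[2.0], [2.0]])

    def test_matches_dense_normalized_adjacency_oracle(self, rng):
        for _ in range(30):
            g = random_graph(rng)
            A = g.adjacency()
            p = make_layer("gcn", 4, 3, rng)
            out = gcn_forward(g.X, A, p)
            oracle = gcn_norm(A) @ g.X @ p.W.data + p.bias.data
            assert np.abs(out.data - oracle).max() <= 1e-6

    def test_dimension_mismatch_is_error(self, rng):
        p = make_layer("gcn", 4, 3, rng)
        with pytest.raises(ValueError):
            gcn_forward(np.ones((2, 5)), np.zeros((2, 2)), p)


class TestGIN:
    def test_isolated_node_identity_mlp_is_fixed_point(self):
        p = _identity_layer("gin", 3)
        p.mlp = []
        H = np.array([[0.3, 0.7, -1.0]])
        out = gin_forward(H, np.zeros((1, 1)), p)
        assert np.allclose(out.data, H)

    def test_two_node_hand_example(self):
        # eps=1, identity MLP, features [1, 2]: (2*1)+2 = 4 and (2*2)+1 = 5
        p = _identity_layer("gin", 1)
        p.mlp = []
        p.eps.data = np.asarray(1.0)
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = gin_forward(np.array([[1.0], [2.0]]), A, p)
        assert np.allclose(out.data, [[4.0], [5.0]])

    def test_matches_dense_A_plus_I_oracle(self, rng):
        for _ in range(30):
            g = random_graph(rng)
            A = g.adjacency()
            p = make_layer("gin", 4, 4, rng)
            p.mlp = []
            out = gin_forward(g.X, A, p)
            assert np.abs(out.data - (A + np.eye(g.n_nodes)) @ g.X).max() <= 1e-6


class TestGAT:
    def test_self_only_neighbourhood_gives_alpha_one(self, rng):
        p = make_layer("gat", 3, 2, rng)
        H = rng.normal(size=(1, 3))
        out, alpha = gat_forward(H, np.zeros((1, 1)), p)
        assert alpha.data[0, 0] == pytest.approx(1.0)
        assert np.allclose(out.data, H @ p.W.data + p.bias.data)

    def test_identical_neighbours_share_attention(self, rng):
        p = make_layer("gat", 2, 2, rng)
        # node 0 linked to nodes 1 and 2 with identical features; alphas over
        # {1, 2} must match
        H = np.array([[5.0, -1.0], [2.0, 2.0], [2.0, 2.0]])
        A = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=float)
        _, alpha = gat_forward(H, A, p)
        assert alpha.data[0, 1] == pytest.approx(alpha.data[0, 2])

    def test_matches_bruteforce_softmax_oracle(self, rng):
        for _ in range(30):
            g = random_graph(rng, n_max=10)
            A = g.adjacency()
            p = make_layer("gat", 4, 3, rng)
            out, alpha = gat_forward(g.X, A, p)
            mask = A.copy()
            np.fill_diagonal(mask, 1.0)
            Z = g.X @ p.W.data
            e = (Z @ p.a_src.data).ravel()[:, None] + (Z @ p.a_dst.data).ravel()[None, :]
            e = np.where(e > 0, e, 0.2 * e)
            ex = np.exp(e) * mask
            oracle_alpha = ex / ex.sum(axis=1, keepdims=True)
            assert np.abs(alpha.data - oracle_alpha).max() <= 1e-6
            assert np.abs(out.data - (oracle_alpha @ Z + p.bias.data)).max() <= 1e-6

    def test_attention_rows_sum_to_one(self, rng):
        for _ in range(20):
            g = random_graph(rng)
            p = make_layer("gat", 4, 2, rng)
            _, alpha = gat_forward(g.X, g.adjacency(), p)
            assert np.allclose(alpha.data.sum(axis=1), 1.0, atol=1e-6)


class TestModel:
    def test_zero_weights_give_all_half_probabilities(self, rng):
        for task, n_out in (("node", 2), ("graph", 3)):
            model = GNNModel("gcn", 4, 8, n_out, task, seed=0)
            for p in model.parameters():
                p.data[...] = 0.0
            g = random_graph(rng)
            probs = model_forward(model, g)
            assert np.allclose(probs, 0.5)

    def test_single_node_graph_pooling_is_identity(self, rng):
        model = GNNModel("gcn", 4, 8, 3, "graph", seed=1)
        g = AttributedGraph(["n0"], [], X=rng.normal(size=(1, 4)))
        probs = model_forward(model, g)
        H1 = np.maximum(gcn_norm(g.adjacency()) @ g.X @ model.layer1.W.data
                        + model.layer1.bias.data, 0)
        logits = H1 @ model.head_W.data + model.head_b.data
        assert np.allclose(probs, 1 / (1 + np.exp(-logits)))

    @pytest.mark.parametrize("arch", ["gcn", "gat", "gin"])
    def test_node_task_is_permutation_equivariant(self, arch, rng):
        model = GNNModel(arch, 4, 8, 2, "node", seed=2)
        for _ in range(10):
            g = random_graph(rng)
            perm = rng.permutation(g.n_nodes)
            probs = model_forward(model, g)
            probs_perm = model_forward(model, g.permuted(perm))
            assert np.allclose(probs_perm, probs[perm], atol=1e-8)

    @pytest.mark.parametrize("arch", ["gcn", "gat", "gin"])
    def test_graph_task_is_permutation_invariant(self, arch, rng):
        model = GNNModel(arch, 4, 8, 3, "graph", seed=3)
        for _ in range(10):
            g = random_graph(rng)
            perm = rng.permutation(g.n_nodes)
            assert np.allclose(model_forward(model, g.permuted(perm)),
                               model_forward(model, g), atol=1e-8)

    def test_graph_output_independent_of_edge_list_order(self, rng):
        model = GNNModel("gcn", 4, 8, 3, "graph", seed=4)
        g = random_graph(rng)
        shuffled = AttributedGraph(g.node_ids, list(reversed(g.edges)), X=g.X)
        assert np.allclose(model_forward(model, shuffled), model_forward(model, g))

    def test_feature_dimension_mismatch_is_error(self, rng):
        model = GNNModel("gcn", 4, 8, 2, "node", seed=0)
        g = random_graph(rng, n_feat=5)
        with pytest.raises(ValueError):
            model_forward(model, g)

    def test_dropout_only_active_in_training_mode(self, rng):
        model = GNNModel("gcn", 4, 8, 2, "node", dropout=0.5, seed=0)
        g = random_graph(rng)
        a = model.forward(g.X, g.adjacency(), training=False).data
        b = model.forward(g.X, g.adjacency(), training=False).data
        assert np.array_equal(a, b)
        c = model.forward(g.X, g.adjacency(), training=True).data
        d = model.forward(g.X, g.adjacency(), training=True).data
        assert not np.array_equal(c, d)

    @pytest.mark.parametrize("arch", ["gcn", "gat", "gin"])
    def test_checkpoint_roundtrip(self, arch, rng, tmp_path):
        model = GNNModel(arch, 4, 8, 2, "node", seed=7)
        g = random_graph(rng)
        before = model_forward(model, g)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path, feature_names=list("abcd"))
        restored, names = load_checkpoint(path)
        assert names == list("abcd")
        assert np.allclose(model_forward(restored, g), before)
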