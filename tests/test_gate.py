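import numpy as np
import pytest
import scipy.sparse as sp

import spotdomains as sd
from spotdomains.gate import GateModel, _encode_t
from spotdomains.graphs import NeighborGraph
from spotdomains._autodiff import Tensor


def dense_attention_oracle(H, W, vs, vr, A):
    """Masked-softmax attention computed densely, no shortcuts shared with
    the implementation."""
    M = H @ W
    s = M @ vs
    r = M @ vr
    logits = 1.0 / (1.0 + np.exp(-(s[:, None] + r[None, :])))
    E = np.where(A > 0, np.exp(logits), 0.0)
    return E / E.sum(axis=1, keepdims=True)


def att_to_dense(graph, dst, src, att):
    out = np.zeros((graph.n, graph.n))
    out[dst, src] = att
    return out


@pytest.fixture
def random_graph():
    rng = np.random.default_rng(0)
    coords = rng.uniform(0, 3, size=(5, 2))
    return sd.build_radius_graph(coords, 1.8), rng


class TestAttention:
    def test_equal_logits_uniform(self):
        coords = np.array([[0.0, 0], [1, 0], [0, 1]])  # mutual triangle
        g = sd.build_radius_graph(coords, 1.5)
        H = np.ones((3, 2))
        W = np.ones((2, 2))
        dst, src, att = sd.compute_attention(H, W, np.zeros(2), np.zeros(2), g)
        np.testing.assert_allclose(att, 1.0 / 3.0)

    def test_self_loop_only(self):
        coords = np.array([[0.0, 0], [100.0, 0]])
        g = sd.build_radius_graph(coords, 1.0)
        rng = np.random.default_rng(1)
        dst, src, att = sd.compute_attention(
            rng.normal(size=(2, 3)), rng.normal(size=(3, 2)),
            rng.normal(size=2), rng.normal(size=2), g)
        np.testing.assert_allclose(att, 1.0)

    def test_matches_dense_softmax_oracle(self, random_graph):
        g, rng = random_graph
        H = rng.normal(size=(5, 4))
        W = rng.normal(size=(4, 3))
        vs, vr = rng.normal(size=3), rng.normal(size=3)
        dst, src, att = sd.compute_attention(H, W, vs, vr, g)
        dense = att_to_dense(g, dst, src, att)
        oracle = dense_attention_oracle(H, W, vs, vr, g.adjacency.toarray())
        np.testing.assert_allclose(dense, oracle, atol=1e-7)

    def test_row_stochastic(self, random_graph):
        g, rng = random_graph
        dst, src, att = sd.compute_attention(
            rng.normal(size=(5, 4)), rng.normal(size=(4, 3)),
            rng.normal(size=3), rng.normal(size=3), g)
        sums = np.zeros(g.n)
        np.add.at(sums, dst, att)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_isolated_node_rejected(self):
        A = sp.csr_matrix(np.array([[1.0, 0], [0, 0]]))  # node 1 bare
        g = NeighborGraph(A, kind="radius", param=1.0, has_self_loops=False)
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="softmax"):
            sd.compute_attention(rng.normal(size=(2, 2)),
                                 rng.normal(size=(2, 2)),
                                 rng.normal(size=2), rng.normal(size=2), g)


class TestCombineAttention:
    def test_alpha_zero_is_spatial(self):
        rng = np.random.default_rng(3)
        a_sp = rng.random(10)
        a_aw = rng.random(10)
        np.testing.assert_array_equal(
            sd.combine_attention(a_sp, a_aw, 0.0), a_sp)

    def test_pruned_edge_at_alpha_07(self):
        # aware attention is 0 on a pruned edge: (1-0.7)*1 + 0.7*0 = 0.3
        out = sd.combine_attention(np.array([1.0]), np.array([0.0]), 0.7)
        np.testing.assert_allclose(out, 0.3)

    def test_convexity_fixpoint(self):
        rng = np.random.default_rng(4)
        a = rng.random(6)
        for alpha in (0.0, 0.3, 1.0):
            np.testing.assert_allclose(sd.combine_attention(a, a, alpha), a)

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            sd.combine_attention(np.ones(2), np.ones(2), 1.5)


class TestEncodeDecode:
    def test_isolated_spots_reduce_to_linear(self):
        coords = np.array([[0.0, 0], [50.0, 0]])
        g = sd.build_radius_graph(coords, 1.0)  # loops only
        rng = np.random.default_rng(5)
        X = rng.normal(size=(2, 4))
        model = GateModel.create(4, (3, 2), alpha=0.0, rng=6)
        emb = sd.encode(X, g, None, model)
        expect = X @ model.W[0].data
        expect = np.where(expect > 0, expect, np.expm1(expect))
        np.testing.assert_allclose(emb.Z[0], expect, atol=1e-12)

    def test_zero_input_constant_embeddings(self, random_graph):
        g, _ = random_graph
        model = GateModel.create(4, (3, 2), alpha=0.0, rng=7)
        emb = sd.encode(np.zeros((5, 4)), g, None, model)
        for Z in emb.Z:
            np.testing.assert_allclose(Z, 0.0, atol=1e-12)

    def test_matches_per_node_loop_oracle(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(0, 2.5, size=(6, 2))
        g = sd.build_radius_graph(coords, 1.5)
        X = rng.normal(size=(6, 4))
        model = GateModel.create(4, (3, 2), alpha=0.0, rng=9)
        emb = sd.encode(X, g, None, model)
        A = g.adjacency.toarray()
        att = dense_attention_oracle(X, model.W[0].data, model.v_s[0].data,
                                     model.v_r[0].data, A)

        def elu(x):
            return np.where(x > 0, x, np.expm1(x))

        msgs = X @ model.W[0].data
        Z1 = np.zeros((6, 3))
        for i in range(6):
            acc = np.zeros(3)
            for j in range(6):
                if A[i, j]:
                    acc += att[i, j] * msgs[j]
            Z1[i] = elu(acc)
        np.testing.assert_allclose(emb.Z[0], Z1, atol=1e-6)
        np.testing.assert_allclose(emb.Z[1], elu(Z1 @ model.W[1].data),
                                   atol=1e-6)

    def test_identity_c_matches_pretraining_path(self, random_graph):
        g, rng = random_graph
        X = rng.normal(size=(5, 4))
        model = GateModel.create(4, (3, 2), alpha=0.0, rng=10)
        emb = sd.encode(X, g, None, model)
        direct = sd.decode(emb.Z[-1], model, g)
        via_c = sd.decode(np.eye(5) @ emb.Z[-1], model, g)
        np.testing.assert_allclose(direct, via_c, atol=1e-12)

    def test_zero_embedding_zero_reconstruction(self, random_graph):
        g, rng = random_graph
        X = rng.normal(size=(5, 4))
        model = GateModel.create(4, (3, 2), alpha=0.0, rng=11)
        sd.encode(X, g, None, model)  # caches attention
        np.testing.assert_allclose(sd.decode(np.zeros((5, 2)), model, g), 0.0)

    def test_weight_tying_shared_gradient(self, random_graph):
        """The tape gradient of the reconstruction loss w.r.t. an encoder
        weight must equal the finite difference through the full
        encode+decode pass — i.e. the decoder really reuses W, it has no
        copy of its own."""
        g, rng = random_graph
        X = rng.normal(size=(5, 4))
        model = GateModel.create(4, (3, 2), alpha=0.0, rng=12)

        def loss_t():
            Z = _encode_t(Tensor(X), model, g, None)
            from spotdomains.gate import _decode_t
            X_hat = _decode_t(Z[-1], model, g)
            return (Tensor(X) - X_hat).sumsq() * 0.5

        L = loss_t()
        L.backward()
        analytic = model.W[0].grad[0, 0]
        eps = 1e-6
        model.W[0].data[0, 0] += eps
        lp = float(loss_t().data)
        model.W[0].data[0, 0] -= 2 * eps
        lm = float(loss_t().data)
        model.W[0].data[0, 0] += eps
        np.testing.assert_allclose(analytic, (lp - lm) / (2 * eps),
                                   rtol=1e-4, atol=1e-7)

    def test_parameter_count_is_encoder_only(self):
        g_dim, h1, h2 = 20, 8, 4
        model = GateModel.create(g_dim, (h1, h2), rng=13)
        expect = g_dim * h1 + h1 * h2 + h1 + h1  # W1, W2, v_s, v_r
        assert model.parameter_count() == expect


class TestLosses:
    def test_reconstruction_loss_examples(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(10, 4))
        assert sd.reconstruction_loss(X, X) == 0.0
        ones = np.ones((2, 3))
        assert sd.reconstruction_loss(ones, ones * 2) == pytest.approx(3.0)
        Y = rng.normal(size=(10, 4))
        oracle = 0.5 * sum((X[i, j] - Y[i, j]) ** 2
                           for i in range(10) for j in range(4))
        assert sd.reconstruction_loss(X, Y) == pytest.approx(oracle,
                                                             abs=1e-12)

    def test_gate_total_loss_examples(self):
        assert sd.gate_total_loss(5.0, [np.zeros((2, 2))]) == 5.0
        assert sd.gate_total_loss(0.0, [np.ones((2, 2))], 1.0) == 2.0
        rng = np.random.default_rng(15)
        Ws = [rng.normal(size=(3, 2)), rng.normal(size=(2, 2))]
        oracle = 1.5 + 0.5 * sum((W ** 2).sum() for W in Ws)
        assert sd.gate_total_loss(1.5, Ws) == pytest.approx(oracle)


def test_pretraining_halves_reconstruction_loss():
    """200 epochs on a 100-spot tissue cut L_att by at least half."""
    spec = sd.SyntheticSpec(rows=10, cols=10, k_domains=2, n_genes=30,
                            markers_per_domain=6, seed=21)
    ds, _ = sd.generate_layered_tissue(spec)
    ds = sd.select_hvg(sd.normalize_log1p(sd.drop_empty_spots(ds)), 30)
    snn = sd.build_knn_graph(ds.coords, 6)
    cfg = sd.TrainConfig(m=2, hidden_dims=(32, 8), epochs_pretrain=200,
                         epochs_joint=0, seed=21)
    _, _, _, _, reports = sd.fit(ds, snn, None, cfg)
    pre = [r for r in reports if r.phase == "pretrain"]
    assert pre[-1].L_att <= 0.5 * pre[0].L_att
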