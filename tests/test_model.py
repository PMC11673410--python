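"""Layer formulas against brute-force oracles, and network-level properties."""

import math

import numpy as np
import pytest

import graphaad as g
from graphaad.graphgen import CorrelationGraph, GraphSample
from graphaad.model import (Batch, ModelConfig, SpatioTemporalGraphNet,
                            collate, load_checkpoint, save_checkpoint)

# -- independent brute-force oracles (scalar loops, no shared code) --------


def bf_attention(Q, K, V):
    L, dk = Q.shape
    weights, out = [], []
    for i in range(L):
        scores = [sum(Q[i][d] * K[j][d] for d in range(dk)) / math.sqrt(dk)
                  for j in range(K.shape[0])]
        ex = [math.exp(s) for s in scores]
        z = sum(ex)
        w = [e / z for e in ex]
        weights.append(w)
        out.append([sum(w[j] * V[j][d] for j in range(K.shape[0]))
                    for d in range(V.shape[1])])
    return np.array(out), np.array(weights)


def neighbors(edges, n, self_loops=False):
    nbr = [set() for _ in range(n)]
    for i, j in edges:
        nbr[i].add(j)
        nbr[j].add(i)
    if self_loops:
        for i in range(n):
            nbr[i].add(i)
    return [sorted(s) for s in nbr]


def bf_sage(x, edges, W1, W2):
    n = x.shape[0]
    nbr = neighbors(edges, n)
    out = []
    for i in range(n):
        mean = (np.mean([x[j] for j in nbr[i]], axis=0) if nbr[i]
                else np.zeros(x.shape[1]))
        out.append(W1 @ x[i] + W2 @ mean)
    return np.array(out)


def bf_gcn(H, A, W, slope):
    n = H.shape[0]
    At = A + np.eye(n)
    D = np.diag(At.sum(axis=1) ** -0.5)
    pre = D @ At @ D @ H @ W.T
    return np.where(pre >= 0, pre, slope * pre)


def bf_gat_alpha(x, edges, a, W, slope, self_loops=True):
    n = x.shape[0]
    h = np.array([W @ x[i] for i in range(n)])
    d = h.shape[1]
    nbr = neighbors(edges, n, self_loops)
    alpha = np.zeros((n, n))
    for i in range(n):
        es = {}
        for j in nbr[i]:
            v = float(a[:d] @ h[i] + a[d:] @ h[j])
            es[j] = math.exp(v if v >= 0 else slope * v)
        z = sum(es.values())
        for j, e in es.items():
            alpha[i, j] = e / z
    return alpha


# -- fixtures --------------------------------------------------------------


def random_edges(rng, n, p=0.5):
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)
             if rng.random() < p]
    return edges


def make_sample(rng, montage, n_nodes=4, T=32, label=0, shift=0):
    labels = montage.labels[shift:shift + n_nodes]
    edges = [(i, i + 1) for i in range(n_nodes - 1)]
    graph = CorrelationGraph(
        node_labels=tuple(labels), pcc=np.eye(len(montage)),
        adjacency=np.eye(n_nodes, k=1, dtype=np.int8)
        + np.eye(n_nodes, k=-1, dtype=np.int8),
        edges=edges, channel_labels=montage.labels)
    return GraphSample(x=rng.standard_normal((n_nodes, T)), graph=graph,
                       label=label, source=("s", "t", 0))


def tiny_config(**kw):
    base = dict(d_model=8, n_heads_temporal=2, d_ff=16, patch_len=4,
                node_dim=8, sage_hidden=8, gcn_hidden=8, n_gat_layers=2,
                gat_heads=2, gat_head_dim=4, dropout=0.0)
    base.update(kw)
    return ModelConfig(**base)


def tiny_net(montage, T=32, seed=0, **kw):
    return SpatioTemporalGraphNet(tiny_config(**kw), len(montage), T,
                                  np.random.default_rng(seed))


# -- scaled dot-product attention ------------------------------------------


class TestScaledDotAttention:
    def test_sequence_length_one(self):
        out, w = g.scaled_dot_attention([[1.0, 2.0]], [[3.0, 1.0]], [[5.0]])
        np.testing.assert_allclose(w, [[1.0]])
        np.testing.assert_allclose(out, [[5.0]])

    def test_identical_keys_give_uniform_weights(self, rng):
        K = np.tile([1.0, 2.0], (4, 1))
        V = rng.standard_normal((4, 3))
        out, w = g.scaled_dot_attention(rng.standard_normal((2, 2)), K, V)
        np.testing.assert_allclose(w, 0.25, atol=1e-12)
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (2, 1)))

    def test_hand_evaluated_two_key_example(self):
        out, w = g.scaled_dot_attention([[1.0, 0.0]],
                                        [[1.0, 0.0], [0.0, 1.0]], [[1.0], [0.0]])
        np.testing.assert_allclose(w, [[0.66976, 0.33024]], atol=1e-4)
        np.testing.assert_allclose(out, [[0.66976]], atol=1e-4)

    def test_nan_inputs_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            g.scaled_dot_attention([[np.nan, 0.0]], [[1.0, 0.0]], [[1.0]])

    def test_matches_loop_oracle(self, rng):
        for _ in range(100):
            L, M, dk, dv = rng.integers(1, 8, size=4)
            Q = rng.standard_normal((L, dk))
            K = rng.standard_normal((M, dk))
            V = rng.standard_normal((M, dv))
            out, w = g.scaled_dot_attention(Q, K, V)
            out_bf, w_bf = bf_attention(Q, K, V)
            assert np.abs(out - out_bf).max() < 1e-10
            assert np.abs(w - w_bf).max() < 1e-10
            np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)


# -- GraphSAGE -------------------------------------------------------------


class TestSage:
    def test_star_graph_identity_weights(self):
        x = np.vstack([np.ones(3), np.zeros((3, 3))])
        edges = [(0, 1), (0, 2), (0, 3)]
        out = g.sage_forward(x, edges, np.eye(3), np.eye(3))
        np.testing.assert_allclose(out[0], 1.0)       # own + zero mean
        np.testing.assert_allclose(out[1:], 1.0)      # mean of single nbr

    def test_isolated_node_empty_mean(self, rng):
        x = rng.standard_normal((2, 3))
        out = g.sage_forward(x, [], np.eye(3), rng.standard_normal((3, 3)))
        np.testing.assert_allclose(out, x)

    def test_matches_loop_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 9))
            x = rng.standard_normal((n, 4))
            edges = random_edges(rng, n)
            W1 = rng.standard_normal((5, 4))
            W2 = rng.standard_normal((5, 4))
            out = g.sage_forward(x, edges, W1, W2)
            assert np.abs(out - bf_sage(x, edges, W1, W2)).max() < 1e-10


# -- GCN -------------------------------------------------------------------


class TestGCN:
    def test_single_node_collapses_to_dense_map(self, rng):
        H = rng.standard_normal((1, 3))
        W = rng.standard_normal((2, 3))
        out = g.gcn_forward(H, np.zeros((1, 1)), W, negative_slope=0.2)
        pre = H @ W.T
        np.testing.assert_allclose(out, np.where(pre >= 0, pre, 0.2 * pre))

    def test_two_identical_nodes_preserved_preactivation(self, rng):
        h = rng.standard_normal(3)
        H = np.vstack([h, h])
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = g.gcn_forward(H, A, np.eye(3), activation=False)
        np.testing.assert_allclose(out, H, atol=1e-12)

    def test_asymmetric_adjacency_rejected(self):
        with pytest.raises(ValueError):
            g.gcn_forward(np.zeros((2, 2)),
                          np.array([[0.0, 1.0], [0.0, 0.0]]), np.eye(2))

    def test_matches_dense_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 9))
            H = rng.standard_normal((n, 3))
            A = np.zeros((n, n))
            for i, j in random_edges(rng, n):
                A[i, j] = A[j, i] = 1.0
            W = rng.standard_normal((4, 3))
            out = g.gcn_forward(H, A, W, negative_slope=0.01)
            assert np.abs(out - bf_gcn(H, A, W, 0.01)).max() < 1e-10


# -- graph attention -------------------------------------------------------


class TestGATCoefficients:
    def test_single_neighbor_without_self_loop(self, rng):
        x = rng.standard_normal((2, 3))
        a = rng.standard_normal(4)
        W = rng.standard_normal((2, 3))
        alpha = g.gat_coefficients(x, [(0, 1)], a, W, add_self_loops=False)
        assert alpha[0, 1] == pytest.approx(1.0)
        assert alpha[1, 0] == pytest.approx(1.0)

    def test_identical_neighbors_split_evenly(self, rng):
        x = np.vstack([np.zeros(3), np.ones(3), np.ones(3)])
        a = rng.standard_normal(4)
        W = rng.standard_normal((2, 3))
        alpha = g.gat_coefficients(x, [(0, 1), (0, 2)], a, W,
                                   add_self_loops=False)
        assert alpha[0, 1] == pytest.approx(0.5)
        assert alpha[0, 2] == pytest.approx(0.5)

    def test_rows_normalize_to_one(self, rng):
        x = rng.standard_normal((5, 3))
        alpha = g.gat_coefficients(x, random_edges(rng, 5, 0.8),
                                   rng.standard_normal(4),
                                   rng.standard_normal((2, 3)))
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-6)
        assert (alpha >= 0).all()

    def test_matches_scalar_oracle_on_path(self, rng):
        x = rng.standard_normal((3, 4))
        a = rng.standard_normal(6)
        W = rng.standard_normal((3, 4))
        edges = [(0, 1), (1, 2)]
        alpha = g.gat_coefficients(x, edges, a, W, negative_slope=0.2)
        bf = bf_gat_alpha(x, edges, a, W, 0.2)
        assert np.abs(alpha - bf).max() < 1e-10


class TestGATForward:
    def test_k1_reduces_to_single_mechanism(self, rng):
        """One attention head equals the plain weighted-sum update."""
        x = rng.standard_normal((4, 3))
        edges = [(0, 1), (1, 2), (2, 3), (0, 3)]
        W = rng.standard_normal((5, 3))
        a = rng.standard_normal(10)
        alpha = g.gat_coefficients(x, edges, a, W)
        direct = alpha @ (x @ W.T)
        multi = g.gat_forward(x, edges, [W], [a], mode="concat",
                              activation=False)
        assert np.abs(multi - direct).max() < 1e-12
        with_act = g.gat_forward(x, edges, [W], [a], mode="concat")
        np.testing.assert_allclose(with_act, g.leaky_relu(direct, 0.01))

    def test_identical_features_give_identical_outputs(self, rng):
        x = np.tile(rng.standard_normal(3), (5, 1))
        out = g.gat_forward(x, random_edges(rng, 5, 0.7),
                            [rng.standard_normal((4, 3))] * 2,
                            [rng.standard_normal(8)] * 2)
        np.testing.assert_allclose(out, np.tile(out[0], (5, 1)), atol=1e-12)

    def test_concat_width_and_head_isolation(self, rng):
        x = rng.standard_normal((4, 3))
        edges = [(0, 1), (1, 2), (2, 3)]
        Ws = [rng.standard_normal((4, 3)) for _ in range(2)]
        As = [rng.standard_normal(8) for _ in range(2)]
        out = g.gat_forward(x, edges, Ws, As, mode="concat")
        assert out.shape == (4, 8)
        head1 = g.gat_forward(x, edges, Ws[:1], As[:1], mode="concat")
        np.testing.assert_allclose(out[:, :4], head1, atol=1e-12)

    def test_matches_full_loop_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 9))
            x = rng.standard_normal((n, 3))
            edges = random_edges(rng, n)
            W = rng.standard_normal((4, 3))
            a = rng.standard_normal(8)
            alpha = g.gat_coefficients(x, edges, a, W, negative_slope=0.2)
            bf = bf_gat_alpha(x, edges, a, W, 0.2)
            assert np.abs(alpha - bf).max() < 1e-10
            out = g.gat_forward(x, edges, [W], [a], negative_slope=0.2,
                                activation=False)
            bf_out = bf @ (x @ W.T)
            assert np.abs(out - bf_out).max() < 1e-10


class TestLeakyRelu:
    @pytest.mark.parametrize("x,slope,expected", [
        (3.0, 0.01, 3.0),
        (-2.0, 0.01, -0.02),
        (0.0, 0.01, 0.0),      # boundary belongs to the x >= 0 branch
    ])
    def test_pointwise(self, x, slope, expected):
        assert g.leaky_relu(x, slope) == pytest.approx(expected)


# -- temporal module -------------------------------------------------------


class TestTemporal:
    def test_token_permutation_invariance_without_positions(self, montage16, rng):
        net = tiny_net(montage16, T=32, positional_encoding=False)
        x = rng.standard_normal((32, 16))
        out = net.temporal_forward(x)
        perm = rng.permutation(8)  # permute whole 4-sample patches
        xp = x.reshape(8, 4, 16)[perm].reshape(32, 16)
        out_p = net.temporal_forward(xp)
        np.testing.assert_allclose(out.mean(axis=1), out_p.mean(axis=1),
                                   atol=1e-10)

    def test_positions_break_token_permutation(self, montage16, rng):
        net = tiny_net(montage16, T=32, positional_encoding=True)
        x = rng.standard_normal((32, 16))
        perm = np.array([3, 1, 0, 2, 7, 6, 5, 4])
        xp = x.reshape(8, 4, 16)[perm].reshape(32, 16)
        assert not np.allclose(net.temporal_forward(x).mean(axis=1),
                               net.temporal_forward(xp).mean(axis=1))

    def test_single_layer_single_head_matches_manual_composition(
            self, montage16, rng):
        """Encoder layer == patch embed -> attention -> residual+LN -> FFN
        -> residual+LN -> unprojection, composed by hand in NumPy."""
        net = tiny_net(montage16, T=32, n_transformer_layers=1,
                       n_heads_temporal=1)
        x = rng.standard_normal((32, 16))

        def ln(v, gamma, beta, eps=1e-5):
            mu = v.mean(axis=-1, keepdims=True)
            var = ((v - mu) ** 2).mean(axis=-1, keepdims=True)
            return (v - mu) / np.sqrt(var + eps) * gamma + beta

        lin = lambda v, l: v @ l.W.data.T + l.b.data
        tokens = x.reshape(8, 4 * 16) @ net.patch_embed.W.data.T \
            + net.patch_embed.b.data + net.pos_code
        enc = net.encoders[0]
        q = lin(tokens, enc.attn.wq)
        k = lin(tokens, enc.attn.wk)
        v = lin(tokens, enc.attn.wv)
        att, _ = g.scaled_dot_attention(q, k, v)
        h = ln(tokens + lin(att, enc.attn.wo), enc.ln1.gamma.data,
               enc.ln1.beta.data)
        ff = lin(g.leaky_relu(lin(h, enc.ffn.lin1), 0.01), enc.ffn.lin2)
        h = ln(h + ff, enc.ln2.gamma.data, enc.ln2.beta.data)
        series = x + (lin(h, net.unproject)).reshape(32, 16)
        np.testing.assert_allclose(net.temporal_forward(x), series.T,
                                   atol=1e-10)

    def test_zero_input_is_finite_bias_pattern(self, montage16):
        net = tiny_net(montage16, T=32)
        out = net.temporal_forward(np.zeros((32, 16)))
        assert np.all(np.isfinite(out))
        out2 = net.temporal_forward(np.zeros((32, 16)))
        np.testing.assert_array_equal(out, out2)

    def test_encoder_decoder_mode_runs(self, montage16, rng):
        net = tiny_net(montage16, T=32, temporal_mode="encoder_decoder")
        out = net.temporal_forward(rng.standard_normal((32, 16)))
        assert out.shape == (16, 32)
        assert np.all(np.isfinite(out))

    def test_channel_count_mismatch_is_error(self, montage16, rng):
        net = tiny_net(montage16, T=32)
        with pytest.raises(ValueError, match="channel count"):
            net.temporal_forward(rng.standard_normal((32, 5)))


# -- full network ----------------------------------------------------------


class TestModelForward:
    def test_logits_shape_and_finiteness(self, montage16, rng):
        net = tiny_net(montage16)
        sample = make_sample(rng, montage16)
        logits = g.model_forward(sample, net, montage16)
        assert logits.shape == (2,)
        assert np.all(np.isfinite(logits))

    def test_node_permutation_invariance(self, montage16, rng):
        net = tiny_net(montage16)
        sample = make_sample(rng, montage16, n_nodes=5)
        perm = rng.permutation(5)
        inv = np.argsort(perm)
        graph = sample.graph
        permuted = GraphSample(
            x=sample.x[perm],
            graph=CorrelationGraph(
                node_labels=tuple(graph.node_labels[i] for i in perm),
                pcc=graph.pcc, adjacency=graph.adjacency[perm][:, perm],
                edges=[(int(inv[i]), int(inv[j])) for i, j in graph.edges],
                channel_labels=graph.channel_labels),
            label=sample.label, source=sample.source)
        l1 = g.model_forward(sample, net, montage16)
        l2 = g.model_forward(permuted, net, montage16)
        np.testing.assert_allclose(l1, l2, atol=1e-5)

    def test_eval_mode_bitwise_deterministic(self, montage16, rng):
        net = tiny_net(montage16, dropout=0.2)
        samples = [make_sample(rng, montage16, label=i % 2) for i in range(3)]
        a = net.forward_samples(samples, montage16)
        b = net.forward_samples(samples, montage16)
        assert np.array_equal(a, b)

    def test_empty_graph_rejected(self, montage16):
        graph = CorrelationGraph(node_labels=(), pcc=np.eye(16),
                                 adjacency=np.zeros((0, 0)), edges=[],
                                 channel_labels=montage16.labels, empty=True)
        sample = GraphSample(x=np.zeros((0, 32)), graph=graph, label=0)
        with pytest.raises(ValueError, match="empty graph"):
            collate([sample], montage16, 4)

    def test_gradient_reaches_every_parameter(self, montage16, rng):
        from graphaad.autodiff import cross_entropy

        net = tiny_net(montage16, dropout=0.0,
                       temporal_mode="encoder_decoder")
        samples = [make_sample(rng, montage16, label=i % 2, shift=i)
                   for i in range(4)]
        batch = collate(samples, montage16, net.config.patch_len)
        logits = net.forward(batch, train=True, rng=rng)
        loss = cross_entropy(logits, batch.labels)
        loss.backward()
        for i, p in enumerate(net.parameters()):
            assert p.grad is not None, f"parameter {i} got no gradient"
            assert np.any(p.grad != 0.0), f"parameter {i} gradient all zero"

    def test_attention_simplex_invariants(self, montage16, rng):
        """Temporal rows and GAT per-node alphas are probability vectors."""
        for seed in range(3):
            net = tiny_net(montage16, seed=seed)
            samples = [make_sample(rng, montage16, n_nodes=4 + seed)]
            batch = collate(samples, montage16, net.config.patch_len)
            net.forward(batch, train=False)
            for enc in net.encoders:
                w = enc.attn.last_weights
                assert (w >= 0).all()
                np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)
            asrc, adst = batch.with_self_loops()
            for gat in net.gats:
                alpha = gat.last_alpha
                assert (alpha >= 0).all()
                sums = np.zeros((batch.n_nodes, alpha.shape[1]))
                np.add.at(sums, adst, alpha)
                np.testing.assert_allclose(sums, 1.0, atol=1e-6)


class TestCheckpoint:
    def test_round_trip_preserves_logits(self, tmp_path, montage16, rng):
        net = tiny_net(montage16)
        sample = make_sample(rng, montage16)
        before = g.model_forward(sample, net, montage16)
        save_checkpoint(net, tmp_path / "ckpt.npz")
        net2 = load_checkpoint(tmp_path / "ckpt.npz")
        after = g.model_forward(sample, net2, montage16)
        np.testing.assert_array_equal(before, after)

    def test_mismatched_config_is_error(self, tmp_path, montage16):
        net = tiny_net(montage16)
        save_checkpoint(net, tmp_path / "ckpt.npz")
        with pytest.raises(ValueError, match="match"):
            load_checkpoint(tmp_path / "ckpt.npz",
                            expected_config=tiny_config(d_model=16))


class TestModelConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(dropout=1.0)
        with pytest.raises(ValueError):
            ModelConfig(d_model=10, n_heads_temporal=4)
        with pytest.raises(ValueError):
            ModelConfig(n_sage_layers=0)
        with pytest.raises(ValueError):
            ModelConfig(temporal_mode="decoder_only")
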