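"""Trainable layers built on the autodiff engine.

Contains the temporal pieces (multi-head self-attention, transformer encoder
layer, sinusoidal positional encoding) and the spatial graph pieces
(GraphSAGE mean aggregation, symmetric-normalized graph convolution,
multi-head graph attention).  Graph layers operate on a batch of graphs
concatenated into one node table, with edges as global (src, dst) index
arrays.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Adam  # re-export for convenience  # noqa: F401
from .autodiff import Parameter, Tensor, leaky_relu, segment_sum, softmax


class Module:
    """Parameter container with recursive collection."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                out.append(value)
            elif isinstance(value, Module):
                out.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        self.W = Parameter(glorot(rng, d_in, d_out, (d_out, d_in)))
        self.b = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W.transpose()
        return y + self.b if self.b is not None else y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta


def dropout(x: Tensor, p: float, train: bool,
            rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity in eval mode or at p = 0."""
    if not train or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * mask


def attention_core(q: Tensor, k: Tensor, v: Tensor) -> tuple[Tensor, Tensor]:
    """softmax(Q K^T / sqrt(d_k)) V, returning (output, weights)."""
    d_k = q.shape[-1]
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    weights = softmax(scores, axis=-1)
    return weights @ v, weights


def sinusoidal_encoding(n_positions: int, d_model: int) -> np.ndarray:
    """Standard sine/cosine positional code, shape (n_positions, d_model)."""
    pos = np.arange(n_positions)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe


class MultiHeadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)
        self.last_weights: np.ndarray | None = None  # (B, H, L, L), testability

    def _split(self, x: Tensor, B: int, L: int) -> Tensor:
        return x.reshape(B, L, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        q = self._split(self.wq(x), B, L)
        k = self._split(self.wk(x), B, L)
        v = self._split(self.wv(x), B, L)
        out, w = attention_core(q, k, v)
        self.last_weights = w.data
        out = out.transpose(0, 2, 1, 3).reshape(B, L, self.n_heads * self.d_head)
        return self.wo(out)


class FeedForward(Module):
    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator,
                 negative_slope: float = 0.01):
        self.lin1 = Linear(d_model, d_ff, rng)
        self.lin2 = Linear(d_ff, d_model, rng)
        self.negative_slope = negative_slope

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(leaky_relu(self.lin1(x), self.negative_slope))


class EncoderLayer(Module):
    """Post-norm transformer encoder layer: MHSA and FFN sublayers with
    residual connections and layer normalization."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int,
                 rng: np.random.Generator, p_drop: float = 0.0,
                 negative_slope: float = 0.01):
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.ffn = FeedForward(d_model, d_ff, rng, negative_slope)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)
        self.p_drop = p_drop

    def __call__(self, x: Tensor, train: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        x = self.ln1(x + dropout(self.attn(x), self.p_drop, train, rng))
        x = self.ln2(x + dropout(self.ffn(x), self.p_drop, train, rng))
        return x


class SingleQueryDecoder(Module):
    """Decoder block with one learned query cross-attending to the encoder
    states; produces a global context vector per sequence."""

    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator,
                 negative_slope: float = 0.01):
        self.query = Parameter(glorot(rng, d_model, d_model, (1, d_model)))
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.ffn = FeedForward(d_model, d_ff, rng, negative_slope)
        self.ln = LayerNorm(d_model)

    def __call__(self, z: Tensor) -> Tensor:
        # z: (B, L, D) encoder states -> (B, 1, D) context
        k, v = self.wk(z), self.wv(z)
        ctx, _ = attention_core(self.query, k, v)
        return self.ln(ctx + self.ffn(ctx))


# -- graph layers ----------------------------------------------------------

def neighbor_mean(x: Tensor, src: np.ndarray, dst: np.ndarray,
                  n_nodes: int) -> Tensor:
    """Mean of neighbor features per destination node; zero vector for an
    empty neighborhood."""
    s = segment_sum(x[src], dst, n_nodes)
    deg = np.bincount(dst, minlength=n_nodes)
    inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
    return s * inv[:, None]


class SageLayer(Module):
    """GraphSAGE with mean aggregation: x_i' = W1 x_i + W2 mean_{j in N(i)} x_j."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w1 = Linear(d_in, d_out, rng)
        self.w2 = Linear(d_in, d_out, rng, bias=False)

    def __call__(self, x: Tensor, src: np.ndarray, dst: np.ndarray,
                 n_nodes: int) -> Tensor:
        return self.w1(x) + self.w2(neighbor_mean(x, src, dst, n_nodes))


def gcn_norm_edges(src: np.ndarray, dst: np.ndarray, n_nodes: int,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Add self-loops and return (src, dst, coef) implementing the
    symmetric renormalization D~^{-1/2} (A + I) D~^{-1/2}."""
    loops = np.arange(n_nodes)
    src = np.concatenate([src, loops])
    dst = np.concatenate([dst, loops])
    deg = np.bincount(dst, minlength=n_nodes).astype(float)
    assert np.all(deg > 0), "degree cannot be zero after self-loops"
    inv_sqrt = deg ** -0.5
    coef = inv_sqrt[src] * inv_sqrt[dst]
    return src, dst, coef


class GCNLayer(Module):
    """Graph convolution H' = sigma(D~^{-1/2} A~ D~^{-1/2} H W)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 negative_slope: float = 0.01):
        self.lin = Linear(d_in, d_out, rng)
        self.negative_slope = negative_slope

    def __call__(self, x: Tensor, src: np.ndarray, dst: np.ndarray,
                 coef: np.ndarray, n_nodes: int) -> Tensor:
        agg = segment_sum(x[src] * coef[:, None], dst, n_nodes)
        return leaky_relu(self.lin(agg), self.negative_slope)


class GATLayer(Module):
    """Multi-head graph attention.

    Per head k, alpha_ij = softmax_j LeakyReLU(a_k^T [W_k x_i || W_k x_j])
    over j in N(i) (self-loop included), then x_i' = sum_j alpha_ij W_k x_j.
    Heads are concatenated (hidden layers) or averaged (final layer).
    """

    def __init__(self, d_in: int, n_heads: int, d_head: int,
                 rng: np.random.Generator, concat: bool = True,
                 negative_slope: float = 0.01):
        self.n_heads = n_heads
        self.d_head = d_head
        self.concat = concat
        self.negative_slope = negative_slope
        self.lin = Linear(d_in, n_heads * d_head, rng, bias=False)
        self.a_dst = Parameter(glorot(rng, d_head, 1, (n_heads, d_head)))
        self.a_src = Parameter(glorot(rng, d_head, 1, (n_heads, d_head)))
        self.last_alpha: np.ndarray | None = None  # (E, H), testability

    def __call__(self, x: Tensor, src: np.ndarray, dst: np.ndarray,
                 n_nodes: int) -> Tensor:
        # edge lists must include self-loops
        h = self.lin(x).reshape(n_nodes, self.n_heads, self.d_head)
        score_dst = (h * self.a_dst).sum(axis=-1)   # (N, H); destination term
        score_src = (h * self.a_src).sum(axis=-1)
        e = leaky_relu(score_dst[dst] + score_src[src], self.negative_slope)
        # numerically stabilized softmax over each destination's neighborhood
        m = np.full((n_nodes, self.n_heads), -np.inf)
        np.maximum.at(m, dst, e.data)
        t = (e - m[dst]).exp()
        denom = segment_sum(t, dst, n_nodes)
        alpha = t * (denom[dst] ** -1.0)
        self.last_alpha = alpha.data
        msg = h[src] * alpha.reshape(-1, self.n_heads, 1)
        out = segment_sum(msg, dst, n_nodes)        # (N, H, d_head)
        if self.concat:
            out = leaky_relu(out, self.negative_slope)
            return out.reshape(n_nodes, self.n_heads * self.d_head)
        return leaky_relu(out.mean(axis=1), self.negative_slope)


def mean_pool(x: Tensor, graph_id: np.ndarray, n_graphs: int) -> Tensor:
    """Global mean pooling of node features per graph."""
    s = segment_sum(x, graph_id, n_graphs)
    counts = np.bincount(graph_id, minlength=n_graphs).astype(float)
    return s * (1.0 / np.maximum(counts, 1.0))[:, None]
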