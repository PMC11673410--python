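"""The spatio-temporal EEG graph classifier.

A temporal transformer encoder contextualizes each surviving electrode's
windowed series (tokens = non-overlapping time patches, token features =
the full montage's channel values within the patch, non-surviving channels
zeroed).  The contextualized per-electrode series then flow through the
spatial module — GraphSAGE layers, one symmetric-normalized graph
convolution, and multi-head graph-attention layers — followed by global
mean pooling and a linear two-class head (attended side: left vs. right).

Module-level functions (`scaled_dot_attention`, `sage_forward`,
`gcn_forward`, `gat_coefficients`, `gat_forward`, `leaky_relu`) are plain
NumPy reference implementations of the individual layer formulas, exposed
for inspection and cross-checking against the trainable layers.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor
from .graphgen import GraphSample
from .layers import (EncoderLayer, GATLayer, GCNLayer, Linear, Module,
                     SageLayer, SingleQueryDecoder, attention_core, dropout,
                     gcn_norm_edges, glorot, mean_pool, neighbor_mean,
                     sinusoidal_encoding)
from .montage import MontageLayout


@dataclass
class ModelConfig:
    """Architecture hyperparameters.  Table-style training constants
    (learning rate, batch size, epochs, loss) live in TrainConfig."""

    d_model: int = 64
    n_transformer_layers: int = 2
    n_heads_temporal: int = 4
    d_ff: int = 128
    patch_len: int = 16              # samples per temporal token
    temporal_mode: str = "encoder_only"   # or "encoder_decoder"
    positional_encoding: bool = True
    node_dim: int = 64               # spatial-module input width per node
    n_sage_layers: int = 2
    sage_hidden: int = 64
    gcn_hidden: int = 64
    n_gat_layers: int = 2
    gat_heads: int = 4
    gat_head_dim: int = 16
    electrode_embedding: bool = True
    negative_slope: float = 0.01
    dropout: float = 0.2
    n_classes: int = 2

    def __post_init__(self):
        for name in ("n_transformer_layers", "n_sage_layers", "n_gat_layers",
                     "n_heads_temporal", "gat_heads"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.d_model % self.n_heads_temporal:
            raise ValueError("d_model must be divisible by n_heads_temporal")
        if self.temporal_mode not in ("encoder_only", "encoder_decoder"):
            raise ValueError(f"unknown temporal_mode {self.temporal_mode!r}")


def small_model_config(**overrides) -> ModelConfig:
    """Compact architecture used for the CPU-scale experiments shipped with
    the package (reduced montage, minutes-scale cross-validation)."""
    base = dict(d_model=32, n_heads_temporal=4, d_ff=64, patch_len=16,
                node_dim=32, sage_hidden=32, gcn_hidden=32,
                gat_heads=4, gat_head_dim=8)
    base.update(overrides)
    return ModelConfig(**base)


# -- reference implementations of the layer formulas -----------------------

def leaky_relu(x, negative_slope: float = 0.01):
    """x for x >= 0 (boundary included), negative_slope * x otherwise."""
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, x, negative_slope * x)


def scaled_dot_attention(Q, K, V) -> tuple[np.ndarray, np.ndarray]:
    """softmax(Q K^T / sqrt(d_k)) V; returns (output, attention weights)."""
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    if np.isnan(Q).any() or np.isnan(K).any() or np.isnan(V).any():
        raise ValueError("NaN in attention inputs (Q/K/V)")
    out, w = attention_core(Tensor(Q), Tensor(K), Tensor(V))
    return out.data, w.data


def sage_forward(x, edges, W1, W2) -> np.ndarray:
    """GraphSAGE mean update x_i' = W1 x_i + W2 mean_{j in N(i)} x_j.

    `edges` are undirected (i, j) pairs; an empty neighborhood contributes
    a zero vector.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    src, dst = _bidirectional(edges)
    nm = neighbor_mean(Tensor(x), src, dst, n).data
    return x @ np.asarray(W1, dtype=float).T + nm @ np.asarray(W2, dtype=float).T


def gcn_forward(H, A, W, negative_slope: float = 0.01,
                activation: bool = True) -> np.ndarray:
    """Graph convolution sigma(D~^{-1/2} (A + I) D~^{-1/2} H W)."""
    H = np.asarray(H, dtype=float)
    A = np.asarray(A, dtype=float)
    if not np.array_equal(A, A.T) or np.any(np.diag(A) != 0):
        raise ValueError("A must be symmetric with zero diagonal")
    ii, jj = np.nonzero(A)
    src, dst, coef = gcn_norm_edges(jj, ii, H.shape[0])
    agg = np.zeros_like(H)
    np.add.at(agg, dst, H[src] * coef[:, None])
    out = agg @ np.asarray(W, dtype=float).T
    return leaky_relu(out, negative_slope) if activation else out


def gat_coefficients(x, edges, a, W, negative_slope: float = 0.01,
                     add_self_loops: bool = True) -> np.ndarray:
    """Attention coefficients alpha_ij (dense N x N, zero off-neighborhood).

    alpha_ij = exp(LeakyReLU(a^T [W x_i || W x_j])) normalized over
    j in N(i); by default the neighborhood includes the self-loop (the
    trainable layers' convention), so every row of the restricted matrix
    sums to 1.  Numerically stabilized by max-subtraction.
    """
    x = np.asarray(x, dtype=float)
    W = np.asarray(W, dtype=float)
    a = np.asarray(a, dtype=float)
    n = x.shape[0]
    h = x @ W.T
    d = h.shape[1]
    a_i, a_j = a[:d], a[d:]
    nbr = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        nbr[i, j] = nbr[j, i] = True
    if add_self_loops:
        np.fill_diagonal(nbr, True)
    if not nbr.any(axis=1).all():
        raise ValueError("every node needs a nonempty neighborhood")
    e = leaky_relu(h @ a_i[:, None] + (h @ a_j)[None, :], negative_slope)
    e = np.where(nbr, e, -np.inf)
    e -= e.max(axis=1, keepdims=True)
    ex = np.where(nbr, np.exp(e), 0.0)
    return ex / ex.sum(axis=1, keepdims=True)


def gat_forward(x, edges, weights, attn_vectors, mode: str = "concat",
                negative_slope: float = 0.01, activation: bool = True,
                add_self_loops: bool = True) -> np.ndarray:
    """Multi-head graph attention.

    Per head k: x_i' = sum_{j in N(i)} alpha_ij^k W_k x_j with the
    coefficients of `gat_coefficients`; heads concatenated
    (``mode="concat"``) or averaged (``mode="average"``).  With a single
    head this is exactly the single-mechanism update.  ``activation``
    applies the LeakyReLU sigma per head (concat) or after averaging.
    """
    x = np.asarray(x, dtype=float)
    heads = []
    for W, a in zip(weights, attn_vectors):
        W = np.asarray(W, dtype=float)
        alpha = gat_coefficients(x, edges, a, W, negative_slope,
                                 add_self_loops)
        out = alpha @ (x @ W.T)
        if activation and mode == "concat":
            out = leaky_relu(out, negative_slope)
        heads.append(out)
    if mode == "concat":
        return np.concatenate(heads, axis=1)
    if mode == "average":
        out = np.mean(heads, axis=0)
        return leaky_relu(out, negative_slope) if activation else out
    raise ValueError(f"unknown mode {mode!r}")


def _bidirectional(edges) -> tuple[np.ndarray, np.ndarray]:
    if len(edges) == 0:
        return np.zeros(0, dtype=np.intp), np.zeros(0, dtype=np.intp)
    e = np.asarray(edges, dtype=np.intp)
    src = np.concatenate([e[:, 0], e[:, 1]])
    dst = np.concatenate([e[:, 1], e[:, 0]])
    return src, dst


# -- batching --------------------------------------------------------------

@dataclass
class Batch:
    """A list of graph samples collated for one forward pass."""

    x_dense: np.ndarray        # (B, T_eff, C) series, non-survivors zeroed
    node_graph: np.ndarray     # (N,) graph index of each node
    node_channel: np.ndarray   # (N,) montage channel index of each node
    src: np.ndarray            # bidirectional edges, global node indices
    dst: np.ndarray
    labels: np.ndarray         # (B,)
    n_graphs: int
    n_nodes: int

    def with_self_loops(self) -> tuple[np.ndarray, np.ndarray]:
        loops = np.arange(self.n_nodes)
        return (np.concatenate([self.src, loops]),
                np.concatenate([self.dst, loops]))


def collate(samples: list[GraphSample], montage: MontageLayout,
            patch_len: int) -> Batch:
    idx_of = montage.index()
    C = len(montage)
    T = samples[0].x.shape[1]
    T_eff = (T // patch_len) * patch_len
    if T_eff < patch_len:
        raise ValueError(f"window of {T} samples shorter than one "
                         f"{patch_len}-sample patch")
    B = len(samples)
    x_dense = np.zeros((B, T_eff, C))
    node_graph, node_channel, src, dst = [], [], [], []
    labels = np.empty(B, dtype=np.intp)
    offset = 0
    for b, s in enumerate(samples):
        if s.n_nodes == 0:
            raise ValueError("empty graph reached the model; filter upstream")
        if s.x.shape[1] != T:
            raise ValueError("all samples in a batch must share window length")
        chans = [idx_of[lab] for lab in s.graph.node_labels]
        x_dense[b, :, chans] = s.x[:, :T_eff]
        node_graph.extend([b] * s.n_nodes)
        node_channel.extend(chans)
        for i, j in s.graph.edges:
            src.extend((offset + i, offset + j))
            dst.extend((offset + j, offset + i))
        labels[b] = s.label
        offset += s.n_nodes
    return Batch(
        x_dense=x_dense,
        node_graph=np.asarray(node_graph, dtype=np.intp),
        node_channel=np.asarray(node_channel, dtype=np.intp),
        src=np.asarray(src, dtype=np.intp),
        dst=np.asarray(dst, dtype=np.intp),
        labels=labels,
        n_graphs=B,
        n_nodes=offset,
    )


# -- the network -----------------------------------------------------------

class SpatioTemporalGraphNet(Module):
    """Temporal transformer -> GraphSAGE x2 -> GCN -> GAT stack -> mean pool
    -> linear head."""

    def __init__(self, config: ModelConfig, n_channels: int,
                 window_samples: int, rng: np.random.Generator):
        cfg = config
        self.config = cfg
        self.n_channels = n_channels
        self.window_samples = window_samples
        self.t_eff = (window_samples // cfg.patch_len) * cfg.patch_len
        self.n_tokens = self.t_eff // cfg.patch_len
        if self.n_tokens < 1:
            raise ValueError("window shorter than one temporal patch")
        d_patch = cfg.patch_len * n_channels

        self.patch_embed = Linear(d_patch, cfg.d_model, rng)
        self.pos_code = (sinusoidal_encoding(self.n_tokens, cfg.d_model)
                         if cfg.positional_encoding else None)
        self.encoders = [EncoderLayer(cfg.d_model, cfg.n_heads_temporal,
                                      cfg.d_ff, rng, cfg.dropout,
                                      cfg.negative_slope)
                         for _ in range(cfg.n_transformer_layers)]
        self.decoder = (SingleQueryDecoder(cfg.d_model, cfg.d_ff, rng,
                                           cfg.negative_slope)
                        if cfg.temporal_mode == "encoder_decoder" else None)
        self.unproject = Linear(cfg.d_model, d_patch, rng)

        self.node_proj = Linear(self.t_eff, cfg.node_dim, rng)
        self.elec_embed = (Parameter(glorot(rng, n_channels, cfg.node_dim,
                                            (n_channels, cfg.node_dim)))
                           if cfg.electrode_embedding else None)
        dims = [cfg.node_dim] + [cfg.sage_hidden] * cfg.n_sage_layers
        self.sages = [SageLayer(dims[i], dims[i + 1], rng)
                      for i in range(cfg.n_sage_layers)]
        self.gcn = GCNLayer(dims[-1], cfg.gcn_hidden, rng, cfg.negative_slope)
        gat_in = cfg.gcn_hidden
        self.gats = []
        for layer in range(cfg.n_gat_layers):
            last = layer == cfg.n_gat_layers - 1
            self.gats.append(GATLayer(gat_in, cfg.gat_heads, cfg.gat_head_dim,
                                      rng, concat=not last,
                                      negative_slope=cfg.negative_slope))
            gat_in = cfg.gat_head_dim if last else cfg.gat_heads * cfg.gat_head_dim
        self.classifier = Linear(gat_in, cfg.n_classes, rng)

    # -- temporal module ---------------------------------------------------
    def _temporal(self, x_dense: np.ndarray, train: bool,
                  rng: np.random.Generator | None) -> Tensor:
        cfg = self.config
        B = x_dense.shape[0]
        x = Tensor(x_dense)
        tokens = x.reshape(B, self.n_tokens, cfg.patch_len * self.n_channels)
        h = self.patch_embed(tokens)
        if self.pos_code is not None:
            h = h + self.pos_code
        for enc in self.encoders:
            h = enc(h, train, rng)
        if self.decoder is not None:
            h = h + self.decoder(h)          # broadcast global context
        u = self.unproject(h).reshape(B, self.t_eff, self.n_channels)
        return x + u                         # residual refinement of the series

    def temporal_forward(self, segment_features: np.ndarray) -> np.ndarray:
        """Contextualized series per electrode, (channels x T_eff), for one
        segment given as (time x channels).  Eval mode."""
        x = np.asarray(segment_features, dtype=float)[None, :self.t_eff, :]
        if x.shape[2] != self.n_channels:
            raise ValueError("channel count mismatch with the built model")
        out = self._temporal(x, train=False, rng=None)
        return out.data[0].T

    # -- full forward ------------------------------------------------------
    def forward(self, batch: Batch, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        cfg = self.config
        series = self._temporal(batch.x_dense, train, rng)   # (B, T_eff, C)
        node_series = series.transpose(0, 2, 1)[
            (batch.node_graph, batch.node_channel)]          # (N, T_eff)
        feats = self.node_proj(node_series)
        if self.elec_embed is not None:
            feats = feats + self.elec_embed[batch.node_channel]
        feats = ad.leaky_relu(feats, cfg.negative_slope)
        for sage in self.sages:
            feats = ad.leaky_relu(sage(feats, batch.src, batch.dst,
                                       batch.n_nodes), cfg.negative_slope)
        gsrc, gdst, coef = gcn_norm_edges(batch.src, batch.dst, batch.n_nodes)
        feats = self.gcn(feats, gsrc, gdst, coef, batch.n_nodes)
        asrc, adst = batch.with_self_loops()
        for gat in self.gats:
            feats = gat(feats, asrc, adst, batch.n_nodes)
        pooled = mean_pool(feats, batch.node_graph, batch.n_graphs)
        pooled = dropout(pooled, cfg.dropout, train, rng)
        logits = self.classifier(pooled)
        if not np.all(np.isfinite(logits.data)):
            raise FloatingPointError("non-finite logits")
        return logits

    def forward_samples(self, samples: list[GraphSample],
                        montage: MontageLayout) -> np.ndarray:
        """Eval-mode logits for a list of samples."""
        batch = collate(samples, montage, self.config.patch_len)
        return self.forward(batch, train=False).data


def model_forward(sample: GraphSample, net: SpatioTemporalGraphNet,
                  montage: MontageLayout) -> np.ndarray:
    """Class logits (length 2) for a single sample, eval mode."""
    return net.forward_samples([sample], montage)[0]


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(net: SpatioTemporalGraphNet, path) -> None:
    """Single-file parameter checkpoint with the config embedded."""
    meta = {"config": asdict(net.config), "n_channels": net.n_channels,
            "window_samples": net.window_samples}
    arrays = {f"p{i}": p.data for i, p in enumerate(net.parameters())}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, expected_config: ModelConfig | None = None,
                    ) -> SpatioTemporalGraphNet:
    """Rebuild a network from a checkpoint; a config/shape mismatch while
    restoring parameters is an error, never a silent reshape."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if expected_config is not None and asdict(expected_config) != meta["config"]:
            raise ValueError("checkpoint config does not match the expected "
                             "model configuration")
        net = SpatioTemporalGraphNet(
            ModelConfig(**meta["config"]), meta["n_channels"],
            meta["window_samples"], np.random.default_rng(0))
        params = net.parameters()
        for i, p in enumerate(params):
            stored = z[f"p{i}"]
            if stored.shape != p.data.shape:
                raise ValueError(
                    f"checkpoint/config mismatch at parameter {i}: "
                    f"{stored.shape} vs {p.data.shape}")
            p.data = stored.astype(np.float64)
    return net
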