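"""Electrode graphs from Pearson-correlation pruning.

Each windowed EEG segment becomes a graph whose nodes are electrodes and
whose edges connect pairs with correlation above a threshold (default
r > 0.7, signed).  Nodes left without any edge are removed; the surviving
topology plus each electrode's own windowed series form one model-ready
training sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import MontageLayout
from .preprocess import CLASSES, EEGRecording, EEGSegment, normalize, window_segments

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.7


class DatasetError(RuntimeError):
    """No usable samples could be produced from the given recordings."""


@dataclass
class GraphConfig:
    """Knobs of the graph-dataset generation stage."""

    window_s: float = 10.0
    overlap: float = 0.0
    resample_hz: float | None = None
    threshold: float = DEFAULT_THRESHOLD
    mode: str = "signed"          # "signed": r > t;  "absolute": |r| > t
    min_nodes: int = 2


@dataclass
class CorrelationGraph:
    """Pruned electrode graph for one segment.

    `pcc` is kept over the ORIGINAL channel set (montage order); `adjacency`
    and `edges` live on the surviving nodes only, with local indices
    following `node_labels` order.
    """

    node_labels: tuple[str, ...]
    pcc: np.ndarray
    adjacency: np.ndarray
    edges: list[tuple[int, int]]
    channel_labels: tuple[str, ...]
    empty: bool = False
    degenerate_channels: tuple[str, ...] = ()


@dataclass
class GraphSample:
    """Model-ready (node features, topology, label) triple."""

    x: np.ndarray                   # (n_surviving_nodes, window_samples)
    graph: CorrelationGraph
    label: int                      # index into CLASSES
    source: tuple[str, str, int] = ("", "", 0)

    @property
    def n_nodes(self) -> int:
        return self.x.shape[0]


def pearson_corr(x, y) -> float:
    """Pearson correlation in the raw-sums form.

    r = (n Σxy − Σx Σy) / (sqrt(n Σx² − (Σx)²) · sqrt(n Σy² − (Σy)²)),
    clamped to [−1, 1] only against floating-point overshoot.  A
    zero-variance input yields r = 0 (the pair can never pass a threshold).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    dx = n * (x * x).sum() - sx * sx
    dy = n * (y * y).sum() - sy * sy
    if dx <= 0.0 or dy <= 0.0:
        return 0.0
    r = num / (np.sqrt(dx) * np.sqrt(dy))
    return float(min(1.0, max(-1.0, r)))


def pcc_matrix(segment: EEGSegment | np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations of all channels of a segment.

    Computed on the upper triangle and mirrored, so the result equals its
    own transpose bitwise.  Diagonal is 1 for non-degenerate channels and 0
    for zero-variance ones.
    """
    data = segment.data if isinstance(segment, EEGSegment) else np.asarray(segment, float)
    c, n = data.shape
    if c < 2:
        raise ValueError("need at least 2 channels")
    s1 = data.sum(axis=1)
    d = n * (data * data).sum(axis=1) - s1 * s1
    good = d > 0.0
    num = n * (data @ data.T) - np.outer(s1, s1)
    root = np.sqrt(np.where(good, d, 1.0))
    r = num / np.outer(root, root)
    r[~good, :] = 0.0
    r[:, ~good] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    upper = np.triu(r, k=1)
    out = upper + upper.T
    np.fill_diagonal(out, np.where(good, 1.0, 0.0))
    return out


def prune_edges(pcc: np.ndarray, threshold: float = DEFAULT_THRESHOLD,
                mode: str = "signed") -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Apply the correlation threshold; return surviving node indices + edges.

    Edge (i, j) survives iff r_ij > threshold (signed mode) or
    |r_ij| > threshold (absolute mode); strict inequality.  Nodes with no
    surviving edge are removed.  Edges are (i, j) pairs with i < j in the
    ORIGINAL indexing.
    """
    if mode not in ("signed", "absolute"):
        raise ValueError(f"unknown pruning mode {mode!r}")
    score = np.abs(pcc) if mode == "absolute" else pcc
    mask = score > threshold
    np.fill_diagonal(mask, False)
    keep = np.flatnonzero(mask.any(axis=1))
    ii, jj = np.nonzero(np.triu(mask, k=1))
    return keep, list(zip(ii.tolist(), jj.tolist()))


def build_graph(segment: EEGSegment, montage: MontageLayout,
                threshold: float = DEFAULT_THRESHOLD,
                mode: str = "signed") -> CorrelationGraph:
    """Correlation graph of one segment under the r > threshold rule.

    Channels are first put in montage order; the full PCC matrix is kept,
    while adjacency/edges cover surviving nodes only.  If every edge is
    pruned an empty graph is returned with ``empty=True`` and the caller
    decides whether to skip the sample.
    """
    idx_of = montage.index()
    unresolved = [lab for lab in segment.channel_names if lab not in idx_of]
    if unresolved:
        raise KeyError(f"channels not in montage: {unresolved}")
    order = sorted(range(segment.n_channels),
                   key=lambda i: idx_of[segment.channel_names[i]])
    labels = tuple(segment.channel_names[i] for i in order)
    data = segment.data[order]

    pcc = pcc_matrix(data)
    degenerate = tuple(labels[i] for i in range(len(labels)) if pcc[i, i] == 0.0)
    keep, edges_orig = prune_edges(pcc, threshold, mode)
    local = {orig: k for k, orig in enumerate(keep.tolist())}
    edges = [(local[i], local[j]) for i, j in edges_orig]
    n_keep = len(keep)
    adj = np.zeros((n_keep, n_keep), dtype=np.int8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return CorrelationGraph(
        node_labels=tuple(labels[i] for i in keep),
        pcc=pcc,
        adjacency=adj,
        edges=edges,
        channel_labels=labels,
        empty=n_keep == 0,
        degenerate_channels=degenerate,
    )


def graph_sample(segment: EEGSegment, graph: CorrelationGraph) -> GraphSample:
    """Pair a pruned graph with its surviving electrodes' windowed series."""
    pos = {lab: i for i, lab in enumerate(segment.channel_names)}
    rows = [pos[lab] for lab in graph.node_labels]
    return GraphSample(
        x=segment.data[rows],
        graph=graph,
        label=CLASSES.index(segment.label),
        source=segment.source,
    )


def build_dataset(recordings: list[EEGRecording], montage: MontageLayout,
                  config: GraphConfig | None = None,
                  ) -> tuple[list[GraphSample], pd.DataFrame]:
    """normalize -> window -> graph per segment, over a list of trials.

    Returns the usable samples plus a manifest with one row per segment
    (including skipped empty-graph segments).  Deterministic given inputs
    and config.
    """
    from .preprocess import resample_recording, restrict_to_montage

    if not recordings:
        raise DatasetError("no recordings given")
    config = config or GraphConfig()
    samples: list[GraphSample] = []
    rows = []
    for rec in recordings:
        rec = restrict_to_montage(rec, montage)
        if config.resample_hz is not None:
            rec = resample_recording(rec, config.resample_hz)
        rec = normalize(rec)
        for seg in window_segments(rec, config.window_s, config.overlap):
            graph = build_graph(seg, montage, config.threshold, config.mode)
            skipped = graph.empty or len(graph.node_labels) < config.min_nodes
            rows.append({
                "subject_id": seg.source[0],
                "trial_id": seg.source[1],
                "start_sample": seg.source[2],
                "label": seg.label,
                "n_nodes": len(graph.node_labels),
                "n_edges": len(graph.edges),
                "skipped": skipped,
            })
            if skipped:
                log.warning("skipping segment %s: %d surviving nodes",
                            seg.source, len(graph.node_labels))
                continue
            samples.append(graph_sample(seg, graph))
    manifest = pd.DataFrame(rows)
    if not samples:
        raise DatasetError(
            f"every segment was pruned empty at threshold {config.threshold}")
    return samples, manifest
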