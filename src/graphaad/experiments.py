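"""Canned end-to-end experiments on the synthetic study.

These functions reproduce, at desk scale, the behaviors the pipeline is
built around: recovery of the planted connectivity block by correlation
pruning, cross-validated decodability of the attended side, the chance-level
null under label shuffling, and the dependence of accuracy on segment
duration.  They are used by both the test suite and the results script.
"""

from __future__ import annotations

import copy

import numpy as np
import pandas as pd

from .graphgen import GraphConfig, build_dataset, build_graph
from .model import ModelConfig, small_model_config
from .montage import standard_montage
from .preprocess import CLASSES, normalize, window_segments
from .synthdata import SynthConfig, generate_dataset, generate_trial
from .training import CVReport, TrainConfig, duration_sweep, run_cv


def pruning_identifiability(n_trials: int = 100, window_s: float = 10.0,
                            seed: int = 0,
                            config: SynthConfig | None = None) -> float:
    """Fraction of trials whose surviving edge set equals exactly the
    planted block's pairs in the first window."""
    config = config or SynthConfig()
    montage = standard_montage(config.n_channels)
    root = np.random.default_rng(seed)
    hits = 0
    for t in range(n_trials):
        label = CLASSES[t % 2]
        rec = generate_trial(config, label,
                             np.random.default_rng(int(root.integers(2**31))))
        seg = window_segments(normalize(rec), window_s)[0]
        graph = build_graph(seg, montage)
        block = sorted(config.block_for(label))
        k = len(block)
        hits += (sorted(graph.node_labels) == block
                 and len(graph.edges) == k * (k - 1) // 2)
    return hits / n_trials


def _shuffle_labels(samples, seed: int):
    rng = np.random.default_rng(seed)
    labels = np.array([s.label for s in samples])
    rng.shuffle(labels)
    out = []
    for s, lab in zip(samples, labels):
        s = copy.copy(s)
        s.label = int(lab)
        out.append(s)
    return out


def learnability(seed: int = 7, n_subjects: int = 4,
                 trials_per_subject: int = 50, shuffle: bool = False,
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None) -> CVReport:
    """4-fold cross-validated decoding of the attended side on the synthetic
    study; with ``shuffle=True`` the labels are permuted to produce the
    chance-level null."""
    synth = SynthConfig(n_subjects=n_subjects,
                        trials_per_subject=trials_per_subject, seed=seed)
    montage = standard_montage(synth.n_channels)
    recordings, _ = generate_dataset(synth)
    samples, _ = build_dataset(recordings, montage, GraphConfig(window_s=10.0))
    if shuffle:
        samples = _shuffle_labels(samples, seed + 1)
    mc = model_config or small_model_config()
    tc = train_config or TrainConfig(seed=seed)
    return run_cv(samples, mc, tc, montage)


def duration_trend(durations=(10.0, 1.0), seeds=(0, 1, 2, 3, 4),
                   n_subjects: int = 2, trials_per_subject: int = 10,
                   model_config: ModelConfig | None = None) -> pd.DataFrame:
    """Aggregate CV accuracy per segment duration, repeated over seeds.

    Longer windows give lower-variance correlation estimates, so accuracy
    is expected not to improve when the window is shortened.
    """
    mc = model_config or small_model_config()
    rows = []
    for seed in seeds:
        synth = SynthConfig(n_subjects=n_subjects,
                            trials_per_subject=trials_per_subject, seed=seed)
        montage = standard_montage(synth.n_channels)
        recordings, _ = generate_dataset(synth)
        table = duration_sweep(recordings, list(durations), mc,
                               TrainConfig(seed=seed), montage)
        for _, r in table.iterrows():
            rows.append({"seed": seed, "duration_s": r["duration_s"],
                         "accuracy": r["accuracy_mean"]})
    return pd.DataFrame(rows)
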