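"""Cross-validated training and evaluation.

Mini-batch Adam on cross-entropy, 4-fold cross-validation by default,
confusion-count metrics (accuracy, precision, recall, F1) and the
window-duration sweep.  Folds are trial-grouped by default so overlapping
windows of one trial can never straddle the train/validation boundary.
"""

from __future__ import annotations

import json
import logging
import time
import warnings as _warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Adam, cross_entropy
from .graphgen import GraphConfig, GraphSample, build_dataset
from .model import ModelConfig, SpatioTemporalGraphNet, collate
from .montage import MontageLayout
from .preprocess import CLASSES

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    lr: float = 1e-3
    optimizer: str = "adam"
    loss: str = "cross_entropy"
    batch_size: int = 64
    epochs_per_fold: int = 15
    n_folds: int = 4
    seed: int = 0
    group_by: str = "trial"          # none | trial | subject
    positive_class: str = "left"     # anchor class for precision/recall/F1
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.epochs_per_fold < 1:
            raise ValueError("epochs_per_fold must be >= 1")
        if self.lr < 0:
            raise ValueError("lr must be nonnegative")
        if self.positive_class not in CLASSES:
            raise ValueError(f"positive_class must be one of {CLASSES}")


@dataclass
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    flags: tuple[str, ...] = ()


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy, precision, recall, F1 from the four confusion counts.

    Undefined ratios (empty denominators) are reported as 0 with a flag
    rather than raising.
    """
    if c.total <= 0:
        raise ValueError("no evaluated samples")
    flags = []
    accuracy = (c.TP + c.TN) / c.total
    if c.TP + c.FP > 0:
        precision = c.TP / (c.TP + c.FP)
    else:
        precision, flags = 0.0, flags + ["precision_undefined"]
    if c.TP + c.FN > 0:
        recall = c.TP / (c.TP + c.FN)
    else:
        recall, flags = 0.0, flags + ["recall_undefined"]
    if precision + recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    else:
        f1, flags = 0.0, flags + ["f1_undefined"]
    return Metrics(accuracy, precision, recall, f1, tuple(flags))


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                               positive_class: str = "left") -> ConfusionCounts:
    pos = CLASSES.index(positive_class)
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        TP=int(np.sum((y_true == pos) & (y_pred == pos))),
        TN=int(np.sum((y_true != pos) & (y_pred != pos))),
        FP=int(np.sum((y_true != pos) & (y_pred == pos))),
        FN=int(np.sum((y_true == pos) & (y_pred != pos))),
    )


def kfold_split(samples: list[GraphSample], k: int, seed: int,
                group_by: str = "none") -> list[np.ndarray]:
    """Disjoint index folds covering all samples.

    ``group_by="trial"`` (or ``"subject"``) keeps all segments of one trial
    (subject) in the same fold.  Deterministic given the seed; ungrouped
    fold sizes differ by at most one.
    """
    n = len(samples)
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    rng = np.random.default_rng(seed)
    if group_by == "none":
        perm = rng.permutation(n)
        return [np.sort(part) for part in np.array_split(perm, k)]
    if group_by == "trial":
        keys = [s.source[:2] for s in samples]
    elif group_by == "subject":
        keys = [s.source[:1] for s in samples]
    else:
        raise ValueError(f"unknown group_by {group_by!r}")
    groups = sorted(set(keys))
    if k > len(groups):
        raise ValueError(f"cannot make {k} folds from {len(groups)} groups")
    order = rng.permutation(len(groups))
    folds: list[list[int]] = [[] for _ in range(k)]
    for pos, gi in enumerate(order):
        fold = pos % k
        g = groups[gi]
        folds[fold].extend(i for i, key in enumerate(keys) if key == g)
    return [np.sort(np.asarray(f, dtype=np.intp)) for f in folds]


@dataclass
class FoldResult:
    counts: ConfusionCounts
    metrics: Metrics
    loss_curve: list[float]
    n_train: int
    n_val: int
    seconds: float


@dataclass
class CVReport:
    per_fold: list[FoldResult]
    aggregate: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "per_fold": [
                {"counts": asdict(f.counts),
                 "metrics": {k: v for k, v in asdict(f.metrics).items()
                             if k != "flags"},
                 "flags": list(f.metrics.flags),
                 "loss_curve": f.loss_curve,
                 "n_train": f.n_train, "n_val": f.n_val}
                for f in self.per_fold
            ],
            "aggregate": self.aggregate,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def _aggregate(folds: list[FoldResult]) -> dict[str, dict[str, float]]:
    out = {}
    for name in ("accuracy", "precision", "recall", "f1"):
        vals = np.array([getattr(f.metrics, name) for f in folds])
        out[name] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=0))}
    return out


def _check_two_classes(samples, context: str) -> None:
    labels = {s.label for s in samples}
    if len(labels) < 2:
        raise ValueError(f"single-class training set in {context}")


def train_fold(train_samples: list[GraphSample],
               val_samples: list[GraphSample],
               model_config: ModelConfig, train_config: TrainConfig,
               montage: MontageLayout, fold_seed: int | None = None,
               fold_name: str = "fold") -> tuple[SpatioTemporalGraphNet,
                                                 list[float], ConfusionCounts]:
    """Train one model on `train_samples`, evaluate on `val_samples`.

    Fixed number of epochs of mini-batch Adam on cross-entropy; dropout is
    active in training only.  Returns the trained network, the per-epoch
    mean training loss, and the validation confusion counts.
    """
    if not train_samples or not val_samples:
        raise ValueError(f"empty train or validation set in {fold_name}")
    _check_two_classes(train_samples, fold_name)
    t0 = time.time()
    seed = train_config.seed if fold_seed is None else fold_seed
    rng = np.random.default_rng(seed)
    net = SpatioTemporalGraphNet(
        model_config, n_channels=len(montage),
        window_samples=train_samples[0].x.shape[1], rng=rng)
    opt = Adam(net.parameters(), lr=train_config.lr,
               betas=train_config.adam_betas, eps=train_config.adam_eps)
    n = len(train_samples)
    bs = train_config.batch_size
    loss_curve = []
    for _epoch in range(train_config.epochs_per_fold):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            batch_samples = [train_samples[i] for i in order[start:start + bs]]
            batch = collate(batch_samples, montage, model_config.patch_len)
            opt.zero_grad()
            logits = net.forward(batch, train=True, rng=rng)
            loss = cross_entropy(logits, batch.labels)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        loss_curve.append(float(np.mean(losses)))

    y_true, y_pred = [], []
    for start in range(0, len(val_samples), bs):
        chunk = val_samples[start:start + bs]
        logits = net.forward_samples(chunk, montage)
        y_pred.extend(np.argmax(logits, axis=1).tolist())
        y_true.extend(s.label for s in chunk)
    counts = confusion_from_predictions(
        np.asarray(y_true), np.asarray(y_pred), train_config.positive_class)
    log.info("%s: %d train / %d val samples, %.1fs, final loss %.4f",
             fold_name, n, len(val_samples), time.time() - t0,
             loss_curve[-1])
    return net, loss_curve, counts


def run_cv(samples: list[GraphSample], model_config: ModelConfig,
           train_config: TrainConfig, montage: MontageLayout,
           out_dir=None) -> CVReport:
    """k-fold cross-validation: each fold trains a fresh seeded model on the
    remaining folds and is evaluated once as the held-out set."""
    if not samples:
        raise ValueError("empty dataset")
    _check_two_classes(samples, "dataset")
    folds = kfold_split(samples, train_config.n_folds, train_config.seed,
                        train_config.group_by)
    results = []
    for f, val_idx in enumerate(folds):
        t0 = time.time()
        val_set = set(val_idx.tolist())
        train_samples = [s for i, s in enumerate(samples) if i not in val_set]
        val_samples = [samples[i] for i in val_idx]
        fold_seed = int(np.random.SeedSequence(
            [train_config.seed, f]).generate_state(1)[0] % (2**31))
        try:
            _net, curve, counts = train_fold(
                train_samples, val_samples, model_config, train_config,
                montage, fold_seed=fold_seed, fold_name=f"fold {f}")
        except ValueError as exc:
            raise ValueError(f"fold {f}: {exc}") from exc
        results.append(FoldResult(
            counts=counts, metrics=compute_metrics(counts),
            loss_curve=curve, n_train=len(train_samples),
            n_val=len(val_samples), seconds=time.time() - t0))
    report = CVReport(per_fold=results, aggregate=_aggregate(results))
    if out_dir is not None:
        _write_report(report, out_dir)
    return report


def _write_report(report: CVReport, out_dir) -> None:
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "cv_report.json").write_text(report.to_json())
    rows = [{"fold": i, **{k: v for k, v in asdict(f.metrics).items()
                           if k != "flags"}}
            for i, f in enumerate(report.per_fold)]
    pd.DataFrame(rows).to_csv(out_dir / "metrics.csv", index=False)
    curves = [{"fold": i, "epoch": e, "loss": l}
              for i, f in enumerate(report.per_fold)
              for e, l in enumerate(f.loss_curve)]
    pd.DataFrame(curves).to_csv(out_dir / "loss_curves.csv", index=False)


def duration_sweep(recordings, durations, model_config: ModelConfig,
                   train_config: TrainConfig, montage: MontageLayout,
                   graph_config: GraphConfig | None = None,
                   out_dir=None) -> pd.DataFrame:
    """Re-window, rebuild graphs and cross-validate per segment duration.

    Returns a tidy table (one row per duration) of aggregate metrics; a
    duration producing zero usable segments is flagged and the sweep
    continues.
    """
    graph_config = graph_config or GraphConfig()
    seen, unique = set(), []
    for d in durations:
        if d <= 0:
            raise ValueError("durations must be positive")
        if d in seen:
            _warnings.warn(f"duplicate duration {d}s dropped", stacklevel=2)
            continue
        seen.add(d)
        unique.append(d)
    rows = []
    for d in unique:
        cfg = GraphConfig(window_s=d, overlap=graph_config.overlap,
                          resample_hz=graph_config.resample_hz,
                          threshold=graph_config.threshold,
                          mode=graph_config.mode,
                          min_nodes=graph_config.min_nodes)
        try:
            samples, _manifest = build_dataset(recordings, montage, cfg)
        except Exception as exc:
            log.warning("duration %ss produced no dataset: %s", d, exc)
            rows.append({"duration_s": d, "n_samples": 0, "failed": True,
                         "accuracy_mean": np.nan, "accuracy_sd": np.nan,
                         "precision_mean": np.nan, "recall_mean": np.nan,
                         "f1_mean": np.nan})
            continue
        report = run_cv(samples, model_config, train_config, montage)
        agg = report.aggregate
        rows.append({
            "duration_s": d, "n_samples": len(samples), "failed": False,
            "accuracy_mean": agg["accuracy"]["mean"],
            "accuracy_sd": agg["accuracy"]["sd"],
            "precision_mean": agg["precision"]["mean"],
            "recall_mean": agg["recall"]["mean"],
            "f1_mean": agg["f1"]["mean"],
        })
    table = pd.DataFrame(rows)
    if out_dir is not None:
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "sweep.csv", index=False)
    return table
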