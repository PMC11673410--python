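"""EEG input, normalization and Hann-windowed segmentation.

A trial enters the pipeline as an :class:`EEGRecording` (channels x samples,
microvolts, one left/right attention label).  It is z-scored per channel,
optionally resampled, and sliced into Hann-tapered :class:`EEGSegment`
windows that become the training-sample precursors.
"""

from __future__ import annotations

import json
import warnings as _warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import get_window, resample_poly

from .montage import MontageLayout, montage_registry

CLASSES: tuple[str, str] = ("left", "right")  # speaker 1, speaker 2


@dataclass
class EEGRecording:
    """One labeled continuous multichannel EEG trial."""

    data: np.ndarray                 # (n_channels, n_samples), microvolts
    channel_names: tuple[str, ...]
    fs: float
    label: str                       # attended side: "left" or "right"
    subject_id: str = ""
    trial_id: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("data must be (n_channels, n_samples) matching channel_names")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}, got {self.label!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EEGSegment:
    """One Hann-tapered window cut from a trial."""

    data: np.ndarray                 # (n_channels, window_samples)
    channel_names: tuple[str, ...]
    fs: float
    window_s: float
    label: str
    source: tuple[str, str, int]     # (subject_id, trial_id, start_sample)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def window_samples(self) -> int:
        return self.data.shape[1]


class FormatError(RuntimeError):
    """Unreadable or structurally invalid input file."""


class ConfigurationError(RuntimeError):
    """Missing or inconsistent configuration (e.g. absent label sidecar)."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_recording(path, format: str | None = None) -> EEGRecording:
    """Read one EEG trial from EDF/BDF or the matrix+JSON fallback format.

    `format` is one of ``edf``, ``bdf``, ``matrix+json`` and is inferred from
    the file suffix when omitted.  Channel labels not resolvable against the
    10-20 montage registry are kept but reported in ``recording.warnings``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format is None:
        suffix = path.suffix.lower()
        format = {".edf": "edf", ".bdf": "bdf"}.get(suffix, "matrix+json")

    if format in ("edf", "bdf"):
        import mne

        reader = mne.io.read_raw_edf if format == "edf" else mne.io.read_raw_bdf
        try:
            raw = reader(path, preload=True, verbose="error")
        except Exception as exc:  # pragma: no cover - mne error text varies
            raise FormatError(f"unreadable {format} file {path}: {exc}") from exc
        data = raw.get_data() * 1e6  # volts -> microvolts
        names = tuple(raw.ch_names)
        fs = float(raw.info["sfreq"])
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ConfigurationError(
                f"missing label sidecar {sidecar} for {format} recording")
        meta = json.loads(sidecar.read_text())
    else:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ConfigurationError(f"missing JSON sidecar {sidecar} for matrix format")
        meta = json.loads(sidecar.read_text())
        try:
            if path.suffix == ".npy":
                data = np.load(path)
            else:
                data = np.loadtxt(path, delimiter=",", ndmin=2)
        except Exception as exc:
            raise FormatError(f"unreadable matrix file {path}: {exc}") from exc
        names = tuple(meta["channel_names"])
        fs = float(meta["fs"])

    registry = montage_registry()
    warn = [f"channel {lab!r} not in 10-20 montage registry"
            for lab in names if lab not in registry]
    return EEGRecording(
        data=data, channel_names=names, fs=fs,
        label=str(meta["label"]),
        subject_id=str(meta.get("subject_id", "")),
        trial_id=str(meta.get("trial_id", "")),
        warnings=warn,
    )


def write_recording(rec: EEGRecording, path, format: str = "npy") -> Path:
    """Write a recording in the matrix+JSON format `read_recording` accepts."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "npy":
        path = path.with_suffix(".npy")
        np.save(path, rec.data)
    elif format == "csv":
        path = path.with_suffix(".csv")
        np.savetxt(path, rec.data, delimiter=",")
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    meta = {
        "channel_names": list(rec.channel_names),
        "fs": rec.fs,
        "label": rec.label,
        "subject_id": rec.subject_id,
        "trial_id": rec.trial_id,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def restrict_to_montage(rec: EEGRecording, montage: MontageLayout) -> EEGRecording:
    """Drop channels absent from `montage` (e.g. ear-canal electrodes)."""
    keep = [i for i, lab in enumerate(rec.channel_names) if lab in montage]
    dropped = [lab for lab in rec.channel_names if lab not in montage]
    warn = rec.warnings + [f"dropped off-montage channel {lab!r}" for lab in dropped]
    return replace(rec, data=rec.data[keep],
                   channel_names=tuple(rec.channel_names[i] for i in keep),
                   warnings=warn)


def normalize(rec: EEGRecording, method: str = "zscore_per_channel") -> EEGRecording:
    """Z-score each channel over the trial (population convention, divisor n).

    Zero-variance channels are mapped to all-zeros and flagged in
    ``warnings`` rather than raising.
    """
    if method != "zscore_per_channel":
        raise ValueError(f"unknown normalization method {method!r}")
    mu = rec.data.mean(axis=1, keepdims=True)
    sd = rec.data.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0.0
    sd[flat] = 1.0
    out = (rec.data - mu) / sd
    out[flat] = 0.0
    warn = rec.warnings + [
        f"zero-variance channel {rec.channel_names[i]!r} set to zeros"
        for i in np.flatnonzero(flat)
    ]
    return replace(rec, data=out, warnings=warn)


def resample_recording(rec: EEGRecording, fs_new: float) -> EEGRecording:
    """Polyphase resampling with built-in anti-alias low-pass filtering."""
    if fs_new == rec.fs:
        return rec
    from fractions import Fraction

    frac = Fraction(fs_new / rec.fs).limit_denominator(1000)
    data = resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return replace(rec, data=data, fs=float(fs_new))


def hann_taper(n: int) -> np.ndarray:
    """Periodic Hann window 0.5 * (1 - cos(2 pi k / n)), k = 0..n-1."""
    return get_window("hann", n, fftbins=True)


def window_segments(rec: EEGRecording, window_s: float,
                    overlap_frac: float = 0.0) -> list[EEGSegment]:
    """Slice a trial into Hann-tapered segments of `window_s` seconds.

    Consecutive starts at stride (1 - overlap_frac) * window; the trailing
    partial window is discarded; every segment inherits the trial label.
    """
    if not 0.0 <= overlap_frac < 1.0:
        raise ValueError("overlap_frac must be in [0, 1)")
    w = int(round(window_s * rec.fs))
    if w < 8:
        raise ValueError(f"window of {w} samples is too short (need >= 8)")
    if w > rec.n_samples:
        _warnings.warn(
            f"window {window_s}s longer than trial "
            f"({rec.duration_s:.1f}s): no segments", stacklevel=2)
        return []
    stride = max(1, int(round((1.0 - overlap_frac) * w)))
    taper = hann_taper(w)
    segments = []
    for start in range(0, rec.n_samples - w + 1, stride):
        segments.append(EEGSegment(
            data=rec.data[:, start:start + w] * taper,
            channel_names=rec.channel_names,
            fs=rec.fs,
            window_s=window_s,
            label=rec.label,
            source=(rec.subject_id, rec.trial_id, start),
        ))
    return segments
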