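"""Synthetic dichotic-listening EEG with class-dependent correlation structure.

The generator emulates the geometry of a selective-attention EEG study
(10-20 labeled channels, ~50 s trials, binary left/right attention labels)
while carrying the class signal purely in second-order spatial structure:
for each trial, the electrodes of the attended side's block share a latent
source so their pairwise correlation is `rho_in`, all other pairs sit at the
background level `rho_out`.  Channel means and variances are identical
across classes, so the only learnable signal is exactly what a
correlation-pruned graph pipeline can detect.

Latent-source mixing: with unit-variance sources s (block), g (global) and
per-channel noise e,

    block channel:  sqrt(rho_in - rho_out) s + sqrt(rho_out) g + sqrt(1 - rho_in) e
    other channel:  sqrt(rho_out) g + sqrt(1 - rho_out) e

giving within-block correlation rho_in and rho_out elsewhere.  All sources
are 1/f-shaped to resemble EEG background activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import standard_montage
from .preprocess import CLASSES, EEGRecording

DEFAULT_BLOCKS = {
    16: {"left": ("T7", "C3", "P7", "P3"), "right": ("T8", "C4", "P8", "P4")},
    64: {"left": ("FT7", "FC5", "T7", "C5", "TP7", "CP5"),
         "right": ("FT8", "FC6", "T8", "C6", "TP8", "CP6")},
}


@dataclass
class SynthConfig:
    """Study-shape and signal-strength parameters of the generator."""

    n_subjects: int = 4
    trials_per_subject: int = 10
    n_channels: int = 16           # 16 (reduced montage) or 64 (BioSemi-64)
    fs: float = 64.0               # Hz
    trial_s: float = 50.0          # seconds per trial
    block_left: tuple[str, ...] | None = None
    block_right: tuple[str, ...] | None = None
    rho_in: float = 0.9            # within-active-block correlation
    rho_out: float = 0.1           # background correlation
    noise_sd: float = 0.5          # white sensor noise, microvolts
    amplitude_uv: float = 10.0     # signal scale, microvolts
    spectral_slope: float = 1.0    # power ~ 1/f**slope for the sources
    seed: int = 0

    def __post_init__(self):
        if self.block_left is None:
            self.block_left = DEFAULT_BLOCKS[self.n_channels]["left"]
        if self.block_right is None:
            self.block_right = DEFAULT_BLOCKS[self.n_channels]["right"]
        labels = set(standard_montage(self.n_channels).labels)
        if not set(self.block_left) <= labels or not set(self.block_right) <= labels:
            raise ValueError("block electrodes must be montage labels")
        if set(self.block_left) & set(self.block_right):
            raise ValueError("left/right blocks must be disjoint")
        if not 0.0 <= self.rho_out < self.rho_in <= 1.0:
            raise ValueError("need 0 <= rho_out < rho_in <= 1")

    def block_for(self, label: str) -> tuple[str, ...]:
        return self.block_left if label == "left" else self.block_right


def pink_noise(rng: np.random.Generator, n: int, slope: float = 1.0,
               fs: float = 64.0, f_corner: float = 1.0) -> np.ndarray:
    """Unit-variance noise with power ~ 1/f**slope above `f_corner` Hz.

    Below the corner the spectrum is flat, mirroring the acquisition
    high-pass of real EEG amplifiers; without it, unbounded low-frequency
    power makes short-window statistics dominated by a handful of slow
    fluctuations.  DC is removed.
    """
    white = rng.standard_normal(n)
    if slope == 0.0:
        x = white
    else:
        spectrum = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, d=1.0 / fs)
        f = np.maximum(f, f_corner)
        spectrum *= f ** (-slope / 2.0)
        spectrum[0] = 0.0
        x = np.fft.irfft(spectrum, n)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_trial(config: SynthConfig, label: str,
                   rng: np.random.Generator) -> EEGRecording:
    """One labeled trial from the latent-source mixing model."""
    if label not in CLASSES:
        raise ValueError(f"label must be one of {CLASSES}")
    montage = standard_montage(config.n_channels)
    n = int(round(config.trial_s * config.fs))
    a = np.sqrt(config.rho_in - config.rho_out)
    b = np.sqrt(config.rho_out)
    c_in = np.sqrt(1.0 - config.rho_in)
    c_out = np.sqrt(1.0 - config.rho_out)

    s = pink_noise(rng, n, config.spectral_slope, config.fs)  # block source
    g = pink_noise(rng, n, config.spectral_slope, config.fs)  # global background
    active = set(config.block_for(label))
    data = np.empty((len(montage), n))
    for i, lab in enumerate(montage.labels):
        e = pink_noise(rng, n, config.spectral_slope, config.fs)
        if lab in active:
            y = a * s + b * g + c_in * e
        else:
            y = b * g + c_out * e
        data[i] = config.amplitude_uv * y
    if config.noise_sd > 0:
        data += config.noise_sd * rng.standard_normal(data.shape)
    return EEGRecording(data=data, channel_names=montage.labels,
                        fs=config.fs, label=label)


def generate_dataset(config: SynthConfig,
                     ) -> tuple[list[EEGRecording], pd.DataFrame]:
    """Balanced labeled trials for all subjects, plus a ground-truth manifest.

    Per subject, labels are balanced to within one trial and shuffled.  Each
    trial gets its own integer seed recorded in the manifest, so any trial is
    bitwise-regenerable via :func:`regenerate_trial`.
    """
    root = np.random.default_rng(config.seed)
    recordings, rows = [], []
    for s in range(config.n_subjects):
        n_t = config.trials_per_subject
        labels = [CLASSES[(t + s) % 2] for t in range(n_t)]
        root.shuffle(labels)
        for t, label in enumerate(labels):
            trial_seed = int(root.integers(0, 2**31))
            rec = generate_trial(config, label, np.random.default_rng(trial_seed))
            rec.subject_id = f"S{s:02d}"
            rec.trial_id = f"T{t:03d}"
            recordings.append(rec)
            rows.append({
                "subject_id": rec.subject_id,
                "trial_id": rec.trial_id,
                "label": label,
                "active_block": "|".join(config.block_for(label)),
                "trial_seed": trial_seed,
            })
    return recordings, pd.DataFrame(rows)


def regenerate_trial(config: SynthConfig, manifest_row) -> EEGRecording:
    """Rebuild one trial bitwise-identically from its manifest row."""
    rec = generate_trial(config, manifest_row["label"],
                         np.random.default_rng(int(manifest_row["trial_seed"])))
    rec.subject_id = manifest_row["subject_id"]
    rec.trial_id = manifest_row["trial_id"]
    return rec


def write_dataset(recordings, manifest: pd.DataFrame, out_dir,
                  format: str = "npy") -> None:
    """Write trials in the matrix+JSON format `preprocess.read_recording` reads."""
    from pathlib import Path

    from .preprocess import write_recording

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_recording(rec, out_dir / f"{rec.subject_id}_{rec.trial_id}", format)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
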