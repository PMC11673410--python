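"""Shared fixtures: small synthetic datasets and minimal EDF/BDF writers.

The EDF/BDF writers produce tiny synthetic files at test time (the package
itself only reads these formats); they implement just enough of the header
layout for a standards-conformant reader.
"""

from __future__ import annotations

import numpy as np
import pytest

import graphaad as g


def _fields(vals, width: int) -> bytes:
    return b"".join(str(v).encode().ljust(width)[:width] for v in vals)


def write_edf(path, data: np.ndarray, ch_names, fs: int) -> None:
    """Minimal synthetic EDF file: 16-bit samples, one record per second."""
    ns, n = len(ch_names), data.shape[1]
    n_rec = n // int(fs)
    pmin, pmax = -3276.8, 3276.7         # 0.1 uV resolution
    dmin, dmax = -32768, 32767
    hdr = _fields(["0"], 8)
    hdr += _fields(["X X X X"], 80) + _fields(["Startdate X X X X"], 80)
    hdr += b"01.01.20" + b"00.00.00"
    hdr += _fields([256 * (ns + 1)], 8) + _fields([""], 44)
    hdr += _fields([n_rec], 8) + _fields([1], 8) + _fields([ns], 4)
    hdr += _fields(ch_names, 16) + _fields(["EEG"] * ns, 80)
    hdr += _fields(["uV"] * ns, 8)
    hdr += _fields([pmin] * ns, 8) + _fields([pmax] * ns, 8)
    hdr += _fields([dmin] * ns, 8) + _fields([dmax] * ns, 8)
    hdr += _fields([""] * ns, 80) + _fields([int(fs)] * ns, 8)
    hdr += _fields([""] * ns, 32)
    scaled = np.clip(np.round(data / 0.1), dmin, dmax).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            for c in range(ns):
                fh.write(scaled[c, r * int(fs):(r + 1) * int(fs)].tobytes())


def write_bdf(path, data: np.ndarray, ch_names, fs: int) -> None:
    """Minimal synthetic BioSemi BDF file: 24-bit samples."""
    ns, n = len(ch_names), data.shape[1]
    n_rec = n // int(fs)
    pmin, pmax = -262144, 262143
    dmin, dmax = -8388608, 8388607
    hdr = b"\xffBIOSEMI"
    hdr += _fields(["X X X X"], 80) + _fields(["Startdate X X X X"], 80)
    hdr += b"01.01.20" + b"00.00.00"
    hdr += _fields([256 * (ns + 1)], 8) + _fields(["24BIT"], 44)
    hdr += _fields([n_rec], 8) + _fields([1], 8) + _fields([ns], 4)
    hdr += _fields(ch_names, 16) + _fields(["EEG"] * ns, 80)
    hdr += _fields(["uV"] * ns, 8)
    hdr += _fields([pmin] * ns, 8) + _fields([pmax] * ns, 8)
    hdr += _fields([dmin] * ns, 8) + _fields([dmax] * ns, 8)
    hdr += _fields([""] * ns, 80) + _fields([int(fs)] * ns, 8)
    hdr += _fields([""] * ns, 32)
    gain = (pmax - pmin) / (dmax - dmin + 1)
    scaled = np.clip(np.round(data / gain), dmin, dmax).astype("<i4")
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            for c in range(ns):
                b = scaled[c, r * int(fs):(r + 1) * int(fs)].tobytes()
                fh.write(b"".join(b[i:i + 3] for i in range(0, len(b), 4)))


@pytest.fixture(scope="session")
def montage16() -> g.MontageLayout:
    return g.standard_montage(16)


@pytest.fixture(scope="session")
def tiny_synth(montage16):
    """12 trials / 60 ten-second graph samples from generator defaults."""
    cfg = g.SynthConfig(n_subjects=2, trials_per_subject=6, seed=3)
    recordings, manifest = g.generate_dataset(cfg)
    samples, graph_manifest = g.build_dataset(
        recordings, montage16, g.GraphConfig(window_s=10.0))
    return {"config": cfg, "recordings": recordings, "manifest": manifest,
            "samples": samples, "graph_manifest": graph_manifest}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
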