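"""Scalp electrode montages (international 10-20 family).

The montage fixes the canonical electrode ordering used throughout the
pipeline: graph nodes are always listed in montage order, and the model's
per-electrode embedding table is indexed by montage position.  Coordinates
come from MNE's standard montage definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

#: Reduced 16-electrode layout used for fast experiments; a symmetric subset
#: of the 10-20 system covering frontal, central, temporal, parietal and
#: occipital sites.
REDUCED_16_LABELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "C3", "C4",
    "T7", "T8", "P3", "P4", "P7", "P8", "O1", "O2",
)


@dataclass(frozen=True)
class MontageLayout:
    """Ordered electrode labels with their 3D scalp coordinates (meters)."""

    labels: tuple[str, ...]
    positions: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate electrode labels in montage")
        for lab in self.labels:
            pos = self.positions[lab]
            if not np.all(np.isfinite(pos)):
                raise ValueError(f"non-finite coordinates for {lab}")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    def __contains__(self, label: str) -> bool:
        return label in self.positions

    def positions_2d(self) -> dict[str, np.ndarray]:
        """Azimuthal-equidistant projection onto the horizontal plane."""
        out = {}
        for lab in self.labels:
            x, y, z = self.positions[lab]
            r = np.hypot(x, y)
            theta = np.arctan2(r, z)  # polar angle from vertex
            phi = np.arctan2(y, x)
            out[lab] = np.array([theta * np.cos(phi), theta * np.sin(phi)])
        return out

    def restrict(self, labels) -> "MontageLayout":
        """Sub-montage containing `labels`, kept in this montage's order."""
        keep = [lab for lab in self.labels if lab in set(labels)]
        return MontageLayout(tuple(keep), {lab: self.positions[lab] for lab in keep})


@lru_cache(maxsize=None)
def _mne_positions(name: str) -> dict[str, np.ndarray]:
    import warnings

    import mne

    with warnings.catch_warnings():
        # montage naming is in flux across MNE releases
        warnings.simplefilter("ignore", FutureWarning)
        mont = mne.channels.make_standard_montage(name)
    return {k: np.asarray(v, dtype=float)
            for k, v in mont.get_positions()["ch_pos"].items()}


def standard_montage(n_channels: int = 64) -> MontageLayout:
    """The two layouts the pipeline ships with.

    64 channels: the BioSemi-64 cap (10-20 naming) used by typical selective
    attention EEG recordings.  16 channels: the reduced symmetric subset.
    """
    if n_channels == 64:
        pos = _mne_positions("biosemi64")
        import mne

        labels = tuple(mne.channels.make_standard_montage("biosemi64").ch_names)
        return MontageLayout(labels, {lab: pos[lab] for lab in labels})
    if n_channels == 16:
        pos = _mne_positions("standard_1020")
        return MontageLayout(REDUCED_16_LABELS,
                             {lab: pos[lab] for lab in REDUCED_16_LABELS})
    raise ValueError(f"no standard montage with {n_channels} channels")


def montage_registry() -> frozenset[str]:
    """All electrode labels resolvable against the 10-20 family."""
    return frozenset(_mne_positions("standard_1020")) | frozenset(_mne_positions("biosemi64"))


def montage_for(channel_names) -> MontageLayout:
    """Best-effort montage for an arbitrary label list (file-driven input).

    Unknown labels are omitted; callers that need to surface them should
    check membership against :func:`montage_registry` first.
    """
    p1020 = _mne_positions("standard_1020")
    pbio = _mne_positions("biosemi64")
    keep, pos = [], {}
    for lab in channel_names:
        if lab in p1020:
            keep.append(lab)
            pos[lab] = p1020[lab]
        elif lab in pbio:
            keep.append(lab)
            pos[lab] = pbio[lab]
    return MontageLayout(tuple(keep), pos)
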