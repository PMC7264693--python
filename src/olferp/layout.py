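"""64-channel 10-20 electrode layout, ROI definitions and sensor adjacency.

Positions come from MNE's standard BioSemi-64 montage, re-centred and
projected onto the unit sphere so that angular distance is well defined.
Two bipolar EOG channels (VEOG below the right eye, HEOG at the right
outer canthus) ride along for artifact handling but take no part in
adjacency, interpolation or referencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

#: Centro-frontal ROI used for the P300 congruence effect (320-580 ms).
CF_ROI = ["AF3", "AFz", "AF4", "F1", "Fz", "F2", "FC1", "FCz", "FC2"]

#: Centro-occipital ROI used for the positive slow wave (600-900 ms); the
#: conventional label includes parietal sites, kept verbatim.
CO_ROI = ["P4", "P2", "Pz", "P1", "P3", "PO8", "PO4", "POz", "PO3", "PO7",
          "O2", "Oz", "O1"]

EOG_NAMES = ["VEOG", "HEOG"]

#: Default angular neighbourhood threshold (radians). On the 64-channel
#: montage this yields a mean sensor degree of ~6 (checked in tests).
DEFAULT_ADJACENCY_RAD = 0.55


@dataclass
class ChannelLayout:
    """Electrode names, unit-sphere positions and EOG bookkeeping."""

    ch_names: list[str]
    positions: np.ndarray  # (n_eeg, 3), unit norm
    eog_names: list[str] = field(default_factory=lambda: list(EOG_NAMES))

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.ch_names), 3):
            raise ValueError("positions must be (n_channels, 3)")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("positions must lie on the unit sphere")

    @property
    def n_eeg(self) -> int:
        return len(self.ch_names)

    @property
    def all_names(self) -> list[str]:
        return list(self.ch_names) + list(self.eog_names)

    def index(self, names: list[str]) -> np.ndarray:
        missing = [n for n in names if n not in self.ch_names]
        if missing:
            raise ValueError(f"channels not in layout: {missing}")
        return np.array([self.ch_names.index(n) for n in names])

    def angular_distances(self) -> np.ndarray:
        """Pairwise great-circle (angular) distances in radians."""
        cosang = np.clip(self.positions @ self.positions.T, -1.0, 1.0)
        return np.arccos(cosang)

    def adjacency(self, angle_threshold: float = DEFAULT_ADJACENCY_RAD) -> np.ndarray:
        """Boolean neighbour matrix: adjacent iff angular distance < threshold.

        Symmetric and irreflexive by construction.
        """
        ang = self.angular_distances()
        adj = ang < angle_threshold
        np.fill_diagonal(adj, False)
        return adj

    def nearest_neighbors(self, k: int = 16) -> np.ndarray:
        """(n, k) indices of each channel's k nearest channels (excluding itself)."""
        ang = self.angular_distances()
        np.fill_diagonal(ang, np.inf)
        return np.argsort(ang, axis=1)[:, :k]


def build_adjacency(layout: ChannelLayout,
                    angle_threshold: float = DEFAULT_ADJACENCY_RAD) -> np.ndarray:
    """Spatial neighbour relation for cluster formation (see layout.adjacency)."""
    return layout.adjacency(angle_threshold)


@lru_cache(maxsize=1)
def _standard_positions() -> tuple[tuple[str, ...], bytes]:
    import mne

    montage = mne.channels.make_standard_montage("biosemi64")
    pos = montage.get_positions()["ch_pos"]
    names = tuple(montage.ch_names)
    arr = np.array([pos[n] for n in names])
    arr = arr - arr.mean(axis=0)
    arr /= np.linalg.norm(arr, axis=1, keepdims=True)
    return names, arr.tobytes()


def standard_layout() -> ChannelLayout:
    """The 64-channel 10-20 layout with two EOG channels."""
    names, raw = _standard_positions()
    arr = np.frombuffer(raw, dtype=float).reshape(len(names), 3).copy()
    return ChannelLayout(list(names), arr)


def layout_from_sfp(path) -> ChannelLayout:
    """Layout from an SFP electrode-coordinate file.

    Channels named like EOG channels are set aside as EOG; the rest are
    re-centred and projected onto the unit sphere.
    """
    import mne

    montage = mne.channels.read_custom_montage(path)
    pos = montage.get_positions()["ch_pos"]
    eog = [n for n in montage.ch_names if n.upper() in
           {e.upper() for e in EOG_NAMES} or "EOG" in n.upper()]
    names = [n for n in montage.ch_names if n not in eog]
    arr = np.array([pos[n] for n in names], dtype=float)
    arr = arr - arr.mean(axis=0)
    arr /= np.linalg.norm(arr, axis=1, keepdims=True)
    return ChannelLayout(names, arr, eog_names=eog or list(EOG_NAMES))
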