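"""In-memory containers shared across the pipeline.

Conventions: samples are 0-based, times are seconds, signal is microvolts.
Epoch time zero sits at the time-locking event; windows are half-open
``[t0, t1)`` unless noted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ContinuousRecording:
    """Multichannel continuous EEG: ``data`` is channels x samples (microvolts).

    ``events`` has one row per marker with columns ``sample`` (0-based index
    into the recording) and ``label``.  ``meta`` carries free-form provenance
    (seeds, corruption logs, processing history).
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    events: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.ch_names)} channel names"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sfreq

    def copy(self) -> "ContinuousRecording":
        return ContinuousRecording(
            self.data.copy(), self.sfreq, list(self.ch_names),
            self.events.copy(), dict(self.meta),
        )

    def pick(self, names: list[str]) -> np.ndarray:
        """View of the rows for the given channel names (in that order)."""
        idx = [self.ch_names.index(n) for n in names]
        return self.data[idx]


@dataclass
class EpochSet:
    """Trials x channels x samples tensor time-locked to an event.

    ``metadata`` is the trial table aligned row-for-row with the first axis.
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    ch_names: list[str]
    metadata: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x samples)")
        if self.data.shape[0] != len(self.metadata):
            raise ValueError("metadata rows must match number of epochs")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel axis must match ch_names")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis must match times")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(), self.times.copy(), self.sfreq,
            list(self.ch_names), self.metadata.copy().reset_index(drop=True),
            dict(self.meta),
        )

    def time_mask(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask for the half-open window [t0, t1)."""
        return (self.times >= t0 - 1e-12) & (self.times < t1 - 1e-12)

    def select(self, rows: np.ndarray) -> "EpochSet":
        rows = np.asarray(rows)
        return EpochSet(
            self.data[rows], self.times.copy(), self.sfreq, list(self.ch_names),
            self.metadata.iloc[rows].reset_index(drop=True), dict(self.meta),
        )
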