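"""File formats: EDF continuous EEG, flat-binary epochs, TSV tables.

Continuous recordings are written as plain 16-bit EDF (physical units
microvolts, one data record per second) with an events TSV sidecar, and
read back through MNE's EDF reader.  Epoch tensors use a documented
raw-binary + JSON-header pair.  All tables are tab-separated text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ContinuousRecording, EpochSet


def write_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: ContinuousRecording, path, events_path=None) -> None:
    """Write a recording as 16-bit EDF (one 1-s data record per second).

    Physical range is taken per channel from the data (symmetric, in
    microvolts); the signal is padded with zeros to a whole number of
    records.  Events go to a TSV sidecar when ``events_path`` is given.
    """
    path = Path(path)
    fs = rec.sfreq
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = len(rec.ch_names)
    n_rec = int(np.ceil(rec.n_samples / fs))
    padded = np.zeros((n_ch, n_rec * fs))
    padded[:, :rec.n_samples] = rec.data

    phys_max = np.maximum(np.abs(padded).max(axis=1), 1.0)
    dig_max, dig_min = 32767, -32768
    scaled = np.round(padded / phys_max[:, None] * dig_max)
    digital = np.clip(scaled, dig_min, dig_max).astype("<i2")

    header = b"".join([
        _edf_field(0, 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate X X X X", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 + 256 * n_ch, 8),
        _edf_field("", 44),
        _edf_field(n_rec, 8),
        _edf_field(1, 8),
        _edf_field(n_ch, 4),
    ])
    sig = b"".join([
        b"".join(_edf_field(n, 16) for n in rec.ch_names),
        b"".join(_edf_field("AgAgCl electrode", 80) for _ in range(n_ch)),
        b"".join(_edf_field("uV", 8) for _ in range(n_ch)),
        b"".join(_edf_field(f"{-m:.6g}"[:8], 8) for m in phys_max),
        b"".join(_edf_field(f"{m:.6g}"[:8], 8) for m in phys_max),
        b"".join(_edf_field(dig_min, 8) for _ in range(n_ch)),
        b"".join(_edf_field(dig_max, 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 80) for _ in range(n_ch)),
        b"".join(_edf_field(fs, 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as fh:
        fh.write(header + sig)
        records = digital.reshape(n_ch, n_rec, fs)
        for r in range(n_rec):
            fh.write(records[:, r, :].tobytes())

    if events_path is not None:
        write_tsv(rec.events, events_path)


def read_edf(path, events_path=None) -> ContinuousRecording:
    """Read an EDF recording (MNE backend) and its optional events TSV."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE uses volts internally
    events = (read_tsv(events_path) if events_path is not None
              else pd.DataFrame(columns=["sample", "label"]))
    return ContinuousRecording(data, raw.info["sfreq"], list(raw.ch_names),
                               events, meta={"source": str(path)})


def write_epochs(epochs: EpochSet, directory) -> None:
    """Flat binary tensor + JSON header + metadata TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(epochs.data, dtype="<f4")
    (directory / "epochs.dat").write_bytes(data.tobytes())
    header = {
        "shape": list(data.shape),
        "dtype": "<f4",
        "order": "C",
        "axes": ["trial", "channel", "time"],
        "sfreq": epochs.sfreq,
        "times": [float(t) for t in epochs.times],
        "ch_names": list(epochs.ch_names),
        "units": "uV",
    }
    (directory / "epochs.json").write_text(json.dumps(header, indent=1))
    write_tsv(epochs.metadata, directory / "metadata.tsv")


def read_epochs(directory) -> EpochSet:
    directory = Path(directory)
    header = json.loads((directory / "epochs.json").read_text())
    data = np.frombuffer((directory / "epochs.dat").read_bytes(),
                         dtype=header["dtype"]).reshape(header["shape"])
    metadata = read_tsv(directory / "metadata.tsv")
    if metadata.empty and header["shape"][0] == 0:
        metadata = pd.DataFrame(index=range(0))
    return EpochSet(np.array(data, dtype=float), np.array(header["times"]),
                    header["sfreq"], list(header["ch_names"]), metadata)


def write_model_fit(fit, path) -> None:
    """ModelFit as JSON mirroring the beta/SE/CI/p table layout."""
    payload = {
        "model_id": fit.model_id,
        "n_obs": fit.n_obs,
        "converged": fit.converged,
        "terms": fit.terms,
        "notes": fit.notes,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
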