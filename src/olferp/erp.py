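"""Single-trial ROI amplitudes and the P300/PSW and amplitude-RT models.

Analysis windows: P300 at 320-580 ms over the centro-frontal ROI; the
positive slow wave split into 600-700, 700-800 and 800-900 ms windows
over the centro-occipital ROI.  Amplitude models mirror the behavioral
models (same covariates, coding and random structure); the amplitude-RT
model regresses single-trial amplitude on per-condition indicators and
per-condition log-RT slopes without a global intercept, so each slope
tests the within-condition amplitude-RT association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .behavior import (build_design_matrix, condition_label,
                       dummy_design_matrix, item_id, standardize_covariate,
                       trial_filter_rt)
from .containers import EpochSet
from .layout import CF_ROI, CO_ROI
from .mixed import ModelFit, fit_lmm

#: Analysis windows in seconds, half-open.
WINDOWS_S = {
    "P300": (0.320, 0.580),
    "PSW1": (0.600, 0.700),
    "PSW2": (0.700, 0.800),
    "PSW3": (0.800, 0.900),
}

ROI_CHANNELS = {"CF": CF_ROI, "CO": CO_ROI}
ROI_FOR_WINDOW = {"P300": "CF", "PSW1": "CO", "PSW2": "CO", "PSW3": "CO"}


@dataclass
class ROISpec:
    name: str
    channels: list[str]
    window_s: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ROI needs at least one channel")
        if self.window_s[0] >= self.window_s[1]:
            raise ValueError("window start must precede its end")


def roi_spec(window_id: str) -> ROISpec:
    """The study's ROI/window pairing for a named analysis window."""
    roi = ROI_FOR_WINDOW[window_id]
    return ROISpec(roi, list(ROI_CHANNELS[roi]), WINDOWS_S[window_id])


def roi_mean_amplitude(epochs: EpochSet, roi: ROISpec,
                       window_id: str | None = None) -> pd.DataFrame:
    """Per-trial mean amplitude over ROI channels and window samples."""
    missing = [c for c in roi.channels if c not in epochs.ch_names]
    if missing:
        raise ValueError(f"ROI channels missing from epochs: {missing}")
    rows = [epochs.ch_names.index(c) for c in roi.channels]
    mask = epochs.time_mask(*roi.window_s)
    if not mask.any():
        raise ValueError("ROI window contains no samples")
    amps = epochs.data[:, rows][:, :, mask].mean(axis=(1, 2))
    out = epochs.metadata.copy().reset_index(drop=True)
    out["window"] = window_id or roi.name
    out["amplitude"] = amps
    return out


def amplitude_table(epochs: EpochSet) -> pd.DataFrame:
    """Stacked single-trial amplitudes for all four analysis windows."""
    return pd.concat(
        [roi_mean_amplitude(epochs, roi_spec(w), w) for w in WINDOWS_S],
        ignore_index=True)


def _window_rows(amps: pd.DataFrame, window_id: str) -> pd.DataFrame:
    rows = amps.loc[amps["window"] == window_id]
    if rows.empty:
        raise ValueError(f"no amplitudes for window {window_id!r}")
    return rows.reset_index(drop=True)


def fit_amplitude_model(amps: pd.DataFrame, window_id: str) -> ModelFit:
    """Mixed model of single-trial amplitude with the full covariate set."""
    data = _window_rows(amps, window_id)
    X = build_design_matrix(data)
    return fit_lmm(
        data["amplitude"].to_numpy(), X,
        participant=data["participant"], item=item_id(data),
        trial_slope=X["trial"].to_numpy(), model_id=f"amp_{window_id}",
    )


def simple_effects_amplitude(amps: pd.DataFrame, window_id: str,
                             within: str) -> ModelFit:
    """Modality contrast within one congruence level (dummy scheme).

    The ``visual-<within>`` coefficient is the contrast of interest.
    """
    data = _window_rows(amps, window_id)
    X = dummy_design_matrix(data, within)
    return fit_lmm(
        data["amplitude"].to_numpy(), X,
        participant=data["participant"], item=item_id(data),
        trial_slope=X["trial"].to_numpy(),
        model_id=f"amp_{window_id}_simple_{within}",
    )


def fit_amplitude_rt_model(amps: pd.DataFrame, window_id: str) -> ModelFit:
    """Per-condition amplitude-RT slopes (no global intercept).

    Amplitude is regressed on the four condition indicators plus four
    condition x standardized-log-RT interaction terms, the control
    covariates, and participant/item random intercepts.  The slope terms
    (``rt:<condition>``) test whether within-condition amplitudes
    covary with response speed.
    """
    data = _window_rows(amps, window_id)
    data = trial_filter_rt(data).reset_index(drop=True)
    X = build_design_matrix(data)
    X = X.drop(columns=["intercept", "congruence", "modality", "interaction"])
    cond = condition_label(data)
    log_rt = standardize_covariate(np.log(data["rt_s"].to_numpy()))
    for cell in sorted(cond.unique()):
        ind = (cond == cell).astype(float).to_numpy()
        X[cell] = ind
        X[f"rt:{cell}"] = ind * log_rt
    return fit_lmm(
        data["amplitude"].to_numpy(), X,
        participant=data["participant"], item=item_id(data),
        trial_slope=X["trial"].to_numpy(), model_id=f"amp_rt_{window_id}",
    )


def subject_condition_averages(epochs: EpochSet, by: list[str]
                               ) -> dict[tuple, np.ndarray]:
    """Per-subject average waveforms for each condition combination.

    Returns {condition key: (n_subjects, n_channels, n_times)} with
    subjects ordered consistently across conditions.
    """
    meta = epochs.metadata
    participants = sorted(meta["participant"].unique())
    out: dict[tuple, np.ndarray] = {}
    for key, rows in meta.groupby(by).groups.items():
        key = key if isinstance(key, tuple) else (key,)
        sub = meta.loc[rows]
        stack = []
        for p in participants:
            sel = np.asarray(sub.index[sub["participant"] == p])
            if len(sel) == 0:
                raise ValueError(f"participant {p} has no trials in {key}")
            stack.append(epochs.data[sel].mean(axis=0))
        out[key] = np.stack(stack)
    return out


def grand_average_peak_latency(diff_wave: np.ndarray, times: np.ndarray,
                               sfreq: float,
                               window_s: tuple[float, float] = (0.6, 0.9),
                               smooth_hz: float = 8.0) -> float:
    """Peak latency (s) of a grand-average difference wave in a window.

    The wave is low-pass smoothed (zero-phase Butterworth) before the
    peak is picked — standard practice for latency estimation on noisy
    averages.
    """
    wave = np.asarray(diff_wave, float)
    if smooth_hz:
        b, a = sps.butter(4, smooth_hz / (sfreq / 2))
        wave = sps.filtfilt(b, a, wave)
    mask = (times >= window_s[0]) & (times <= window_s[1])
    if not mask.any():
        raise ValueError("latency window contains no samples")
    return float(times[mask][np.argmax(wave[mask])])
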