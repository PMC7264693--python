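"""Pipeline orchestration: configuration, staged execution, manifest.

``run_full`` drives simulate -> preprocess -> cluster -> ERP stats ->
behavior stats in the protocol order and writes a reproducibility
manifest (config hash, seeds, file digests, exclusion counts).  Every
numeric threshold is reachable from the config; unset values fall back
to the protocol defaults.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bstats
from . import erp, io, preprocess as pp
from .cluster import cluster_test
from .design import DesignConfig
from .layout import standard_layout
from .simulate import (GeneratorConfig, default_config, generate_behavior,
                       generate_continuous)

logger = logging.getLogger(__name__)

#: Default configuration; thresholds mirror the study protocol.
DEFAULTS: dict = {
    "simulate": {
        "n_participants": 8,
        "n_repetitions": 4,
        "noise_sd_uV": 15.0,
        "blink_rate_per_min": 12.0,
        "n_bad_channels": 2,
    },
    "preprocess": {
        "low_hz": 0.2,
        "high_hz": 40.0,
        "target_hz": 512.0,
        "amplitude_uv": pp.AMPLITUDE_THRESHOLD_UV,
        "correlation": pp.CORRELATION_THRESHOLD,
        "snr_sd": pp.SNR_SD_THRESHOLD,
        "p2p_uv": pp.EPOCH_P2P_UV,
        "chan_sd": pp.EPOCH_CHAN_SD,
        "multi_sd": pp.EPOCH_MULTI_SD,
        "multi_count": pp.EPOCH_MULTI_COUNT,
        "min_accuracy": pp.MIN_ACCURACY,
        "min_epochs": pp.MIN_EPOCHS_PER_CELL,
    },
    "cluster": {
        "alpha": 0.05,
        "threshold": 2.0,
        "n_permutations": 500,
    },
    "erp": {
        "roi": "CF",
        "window": "P300",
    },
}

REQUIRED = [("simulate", "seed"), ("erp", "roi")]


def validate_config(source) -> dict:
    """Load and normalize a pipeline config (YAML path, or dict).

    Missing required keys raise with the key named; unset thresholds are
    filled with the protocol defaults; unknown sections are rejected.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text()) or {}
    else:
        raw = dict(source)
    unknown = set(raw) - set(DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    cfg = {sec: {**vals, **raw.get(sec, {})} for sec, vals in DEFAULTS.items()}
    for sec, key in REQUIRED:
        if key not in cfg.get(sec, {}):
            raise ValueError(f"missing required config key: {sec}.{key}")
    if cfg["erp"]["roi"] not in erp.ROI_CHANNELS:
        raise ValueError(f"unknown ROI {cfg['erp']['roi']!r}; "
                         f"known: {sorted(erp.ROI_CHANNELS)}")
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _generator_config(cfg: dict) -> GeneratorConfig:
    sim = cfg["simulate"]
    gen = default_config(n_participants=sim["n_participants"],
                         seed=sim["seed"])
    return replace(
        gen,
        noise_sd_uV=sim["noise_sd_uV"],
        blink_rate_per_min=sim["blink_rate_per_min"],
        n_bad_channels=sim["n_bad_channels"],
        design=DesignConfig(n_repetitions=sim["n_repetitions"]),
    )


def preprocess_participant(rec, layout, trials, cfg: dict):
    """The full per-participant preprocessing chain, in protocol order."""
    p = cfg["preprocess"]
    rec = pp.bandpass_filter(rec, p["low_hz"], p["high_hz"])
    rec = pp.resample(rec, p["target_hz"])
    bads = pp.detect_bad_channels(rec, layout, p["amplitude_uv"],
                                  p["correlation"], p["snr_sd"])
    bad_names = sorted({b.channel for b in bads})
    if len(bad_names) < layout.n_eeg - 4:
        rec = pp.interpolate_channels(rec, layout, bad_names)
    else:
        logger.warning("too many bad channels to interpolate (%d)",
                       len(bad_names))
    rec = pp.rereference_average(rec, tuple(layout.eog_names))
    rec = pp.correct_ocular(rec, layout.eog_names)
    epochs = pp.epoch(rec, "tone", metadata=trials)
    epochs = pp.baseline_correct(epochs)
    kept, log = pp.reject_epochs(epochs, eeg_names=layout.ch_names,
                                 p2p_uv=p["p2p_uv"], chan_sd=p["chan_sd"],
                                 multi_sd=p["multi_sd"],
                                 multi_count=p["multi_count"])
    return kept, bads, log


def run_full(source, out_dir) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    cfg = validate_config(source)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = standard_layout()
    gen = _generator_config(cfg)

    logger.info("stage=simulate event=start participants=%d",
                gen.n_participants)
    trials = generate_behavior(gen)
    io.write_tsv(trials, out / "behavior.tsv")

    all_epochs = []
    bad_counts, reject_counts = {}, {}
    for name, sub in trials.groupby("participant"):
        sub = sub.reset_index(drop=True)
        rec = generate_continuous(gen, sub, layout)
        kept, bads, log = preprocess_participant(rec, layout, sub, cfg)
        bad_counts[name] = len({b.channel for b in bads})
        reject_counts[name] = int(len(sub) - kept.n_epochs)
        logger.info("stage=preprocess participant=%s bads=%d rejected=%d",
                    name, bad_counts[name], reject_counts[name])
        all_epochs.append(kept)

    eeg_rows = [all_epochs[0].ch_names.index(n) for n in layout.ch_names]
    from .containers import EpochSet
    epochs = EpochSet(
        np.concatenate([e.data[:, eeg_rows] for e in all_epochs]),
        all_epochs[0].times, all_epochs[0].sfreq, list(layout.ch_names),
        pd.concat([e.metadata for e in all_epochs], ignore_index=True))
    io.write_epochs(epochs, out / "epochs")

    # participant exclusion (behavioral + surviving-epoch criteria)
    counts = (epochs.metadata.groupby(["participant", "congruence",
                                       "modality"]).size()
              .rename("n").reset_index())
    kept_p, excluded_p, reasons = pp.exclude_participants(
        trials, counts, cfg["preprocess"]["min_accuracy"],
        cfg["preprocess"]["min_epochs"])
    io.write_tsv(reasons, out / "exclusions.tsv")
    if not kept_p:
        raise RuntimeError("stage=exclude: no participants survive the "
                           "exclusion criteria at this simulation scale")
    analysis = epochs.select(
        np.flatnonzero(epochs.metadata["participant"].isin(kept_p)))
    trials_kept = trials[trials["participant"].isin(kept_p)]

    # cluster permutation: incongruent vs congruent, collapsed over modality
    c = cfg["cluster"]
    avgs = erp.subject_condition_averages(analysis, ["congruence"])
    result = cluster_test(avgs[("incongruent",)], avgs[("congruent",)],
                          layout, alpha=c["alpha"], threshold=c["threshold"],
                          n_permutations=c["n_permutations"],
                          seed=cfg["simulate"]["seed"],
                          times=analysis.times)
    (out / "clusters.json").write_text(result.to_json())

    amps = erp.amplitude_table(analysis)
    io.write_tsv(amps, out / "amplitudes.tsv")
    window = cfg["erp"]["window"]
    amp_fit = erp.fit_amplitude_model(amps, window)
    io.write_model_fit(amp_fit, out / f"amp_{window}.json")

    rt_fit = bstats.fit_rt_model(trials_kept)
    acc_fit = bstats.fit_accuracy_model(trials_kept)
    io.write_model_fit(rt_fit, out / "rt_model.json")
    io.write_model_fit(acc_fit, out / "accuracy_model.json")

    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16],
        "seed": cfg["simulate"]["seed"],
        "package_version": __import__("olferp").__version__,
        "n_participants": gen.n_participants,
        "excluded_participants": excluded_p,
        "bad_channel_counts": bad_counts,
        "rejected_epoch_counts": reject_counts,
        "significant_clusters": len(result.significant),
        "digests": {p.name: _digest(p) for p in sorted(out.iterdir())
                    if p.is_file()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
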