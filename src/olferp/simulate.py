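"""Synthetic behavior and EEG with the study's reported effect structure.

The generator is the ground-truth test bed for every downstream stage.
Behavioral data follow a lognormal RT model and a logistic accuracy
model whose fixed effects default to the published mixed-model
estimates; target-locked epochs carry a common auditory evoked kernel,
a centro-frontal P300 congruence bump (320-580 ms, modality
independent), and a centro-occipital positive slow wave for incongruent
trials whose peak and extent depend on the decision modality (olfactory
652 ms within 600-700 ms; visual 683 ms within 600-900 ms).  A shared
trial-level latent "attention" variable couples P300 gain to faster
responses, more strongly for visual-incongruent trials.  Noise is
spatially correlated 1/f + white; continuous recordings add blinks and
corrupted channels to exercise preprocessing.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavior import FIXED_TERMS, build_design_matrix, condition_label, item_id
from .containers import ContinuousRecording, EpochSet
from .design import DELAY_LEVELS_MS, DesignConfig, build_design
from .layout import CF_ROI, CO_ROI, ChannelLayout, standard_layout

CONDITIONS = ("olfactory-congruent", "visual-congruent",
              "olfactory-incongruent", "visual-incongruent")


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study; defaults via :func:`default_config`."""

    n_participants: int = 35
    # behavioral fixed effects (log-seconds / log-odds, study coding)
    rt_log_effects: dict[str, float] = field(default_factory=dict)
    acc_logit_effects: dict[str, float] = field(default_factory=dict)
    # behavioral random-effect SDs
    rt_sd_participant: float = 0.20
    rt_sd_item: float = 0.05
    rt_sd_trial_slope: float = 0.05
    rt_sd_resid: float = 0.25
    rt_attention_sd: float = 0.10   # latent attention -> -log RT
    acc_sd_participant: float = 1.0
    acc_sd_item: float = 0.20
    acc_sd_trial_slope: float = 0.30
    # ERP effect structure
    p300_effect_uV: float = 0.71     # ROI-window mean difference, incong - cong
    p300_window_ms: tuple[float, float] = (320.0, 580.0)
    psw_effect_uV: float = 1.5       # peak amplitude of the slow-wave bump
    psw_peak_ms: dict[str, float] = field(
        default_factory=lambda: {"olfactory": 652.0, "visual": 683.0})
    psw_extent_ms: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"olfactory": (600.0, 700.0),
                                 "visual": (600.0, 900.0)})
    psw_late_ratio: float = 0.5      # late-bump amplitude relative to the peak bump
    amp_rt_coupling: dict[str, float] = field(
        default_factory=lambda: {"olfactory-congruent": 0.0,
                                 "visual-congruent": 0.0,
                                 "olfactory-incongruent": 1.0,
                                 "visual-incongruent": 2.0})
    # noise and artifacts
    noise_alpha: float = 1.0
    noise_sd_uV: float = 15.0
    noise_white_frac: float = 0.3
    noise_spatial_scale_rad: float = 0.6
    blink_rate_per_min: float = 12.0
    blink_amp_uV: float = 250.0
    n_bad_channels: int = 0
    # timing
    sfreq: float = 512.0
    epoch_window_s: tuple[float, float] = (-0.2, 1.0)
    design: DesignConfig = field(default_factory=DesignConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        t0, t1 = self.epoch_window_s
        for mod, (a, b) in self.psw_extent_ms.items():
            if not (t0 * 1000 <= a < b <= t1 * 1000):
                raise ValueError(f"PSW extent for {mod} outside the epoch span")
        a, b = self.p300_window_ms
        if not (t0 * 1000 <= a < b <= t1 * 1000):
            raise ValueError("P300 window outside the epoch span")
        for name in ("rt_sd_participant", "rt_sd_item", "rt_sd_trial_slope",
                     "rt_sd_resid", "rt_attention_sd", "acc_sd_participant",
                     "acc_sd_item", "acc_sd_trial_slope", "noise_sd_uV"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


#: Published fixed-effect estimates for log RT (intercept is recalibrated,
#: see :func:`calibrated_rt_intercept`).
RT_TABLE_EFFECTS = {
    "congruence": 0.45, "modality": 0.04, "interaction": 0.06,
    "category": 0.02, "sex": 0.14, "trial": -0.35, "delay": 0.02,
    "similarity": 0.01,
}

#: Published fixed-effect estimates for accuracy (log-odds).
ACC_TABLE_EFFECTS = {
    "intercept": 3.68, "congruence": -1.34, "modality": 0.58,
    "interaction": -0.8, "category": 0.19, "sex": -0.31, "trial": 0.54,
    "delay": -0.12, "similarity": -0.26,
}

#: Target mean RT gap, visual-incongruent minus olfactory-incongruent (s).
RT_GAP_TARGET_S = 0.070


def calibrated_rt_intercept(effects: dict[str, float],
                            sd_participant: float, sd_item: float,
                            sd_trial_slope: float, sd_resid: float,
                            attention_sd: float,
                            n_trials: int = 128) -> float:
    """Intercept making the analytic visual-olfactory incongruent RT gap 70 ms.

    Uses lognormal moments: for each independent covariate X with
    coefficient b, the mean RT picks up a factor E[exp(bX)], and each
    Gaussian random term of SD s a factor exp(s^2/2).  The modality gap
    within incongruent trials then factorizes, so the intercept solves in
    closed form.
    """
    bc, bm, bi = effects["congruence"], effects["modality"], effects["interaction"]
    # trial covariate (2-SD standardized positions), with the random slope
    t = np.arange(1, n_trials + 1, dtype=float)
    xt = (t - t.mean()) / (2 * t.std(ddof=1))
    f_trial = np.mean(np.exp(effects["trial"] * xt + 0.5 * (sd_trial_slope * xt) ** 2))
    d = np.array(DELAY_LEVELS_MS, dtype=float)
    xd = (d - d.mean()) / (2 * d.std(ddof=1))
    f_delay = np.mean(np.exp(effects["delay"] * xd))
    f_cat = np.cosh(effects["category"] / 2)
    f_sex = np.cosh(effects["sex"] / 2)
    f_sim = np.exp(0.5 * (effects["similarity"] * 0.5) ** 2)
    var_re = sd_participant**2 + sd_item**2 + sd_resid**2 + attention_sd**2
    factor = f_trial * f_delay * f_cat * f_sex * f_sim * np.exp(var_re / 2)
    gap_unit = np.exp(bc / 2) * 2 * np.sinh((bm + bi / 2) / 2)
    return float(np.log(RT_GAP_TARGET_S) - np.log(factor * gap_unit))


def default_config(n_participants: int = 35, seed: int = 0) -> GeneratorConfig:
    """The study conditions: published coefficients, calibrated intercept."""
    cfg = GeneratorConfig(n_participants=n_participants, seed=seed)
    rt = dict(RT_TABLE_EFFECTS)
    rt["intercept"] = calibrated_rt_intercept(
        rt, cfg.rt_sd_participant, cfg.rt_sd_item, cfg.rt_sd_trial_slope,
        cfg.rt_sd_resid, cfg.rt_attention_sd,
        n_trials=16 * cfg.design.n_repetitions)
    return replace(cfg, rt_log_effects=rt,
                   acc_logit_effects=dict(ACC_TABLE_EFFECTS))


def zero_effect_config(n_participants: int = 8, seed: int = 0,
                       **overrides) -> GeneratorConfig:
    """Null generator: all fixed effects and ERP effects zero (noise kept)."""
    zeros = {k: 0.0 for k in FIXED_TERMS}
    cfg = GeneratorConfig(
        n_participants=n_participants, seed=seed,
        rt_log_effects=dict(zeros), acc_logit_effects=dict(zeros),
        p300_effect_uV=0.0, psw_effect_uV=0.0,
        amp_rt_coupling={c: 0.0 for c in CONDITIONS},
    )
    return replace(cfg, **overrides) if overrides else cfg


def _participant_names(n: int) -> list[str]:
    return [f"P{i + 1:02d}" for i in range(n)]


def _rng_for(seed: int, *tags) -> np.random.Generator:
    parts = [seed] + [zlib.crc32(str(t).encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(parts))


def build_study_design(config: GeneratorConfig) -> pd.DataFrame:
    """Per-participant factorial designs, counterbalanced round-robin."""
    tables = []
    for i, name in enumerate(_participant_names(config.n_participants)):
        dcfg = replace(config.design,
                       counterbalance_id=(i % 4) + 1,
                       seed=int(_rng_for(config.seed, "design", name)
                                .integers(2**31)))
        tables.append(build_design(dcfg, participant=name))
    return pd.concat(tables, ignore_index=True)


def generate_behavior(config: GeneratorConfig,
                      design: pd.DataFrame | None = None) -> pd.DataFrame:
    """Simulate RTs and accuracy on a factorial design.

    RT = exp(fixed effects + participant/item intercepts + participant
    trial slope - attention*z + residual); accuracy ~ Bernoulli on the
    logit scale with its own random effects.  Covariates are coded
    exactly as the fitted models code them, so the models are correctly
    specified, and the latent attention z is stored for the ERP stage.
    """
    trials = (build_study_design(config) if design is None
              else design.copy().reset_index(drop=True))
    required = {"participant", "trial", "congruence", "modality", "category",
                "odor", "picture", "delay_ms"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"design lacks columns: {sorted(missing)}")

    participants = sorted(trials["participant"].unique())
    rng = _rng_for(config.seed, "behavior")
    trials["sex"] = trials["participant"].map(
        {p: ("F" if i % 2 == 0 else "M") for i, p in enumerate(participants)})

    # similarity index ~ N(0,1) per participant x target object x modality
    target = np.where(trials["modality"] == "olfactory",
                      trials["odor"], trials["picture"])
    keys = pd.MultiIndex.from_arrays(
        [trials["participant"], target, trials["modality"]])
    uniq = keys.unique()
    sim_map = dict(zip(uniq, rng.standard_normal(len(uniq))))
    trials["similarity"] = [sim_map[k] for k in keys]

    X = build_design_matrix(trials)
    beta_rt = np.array([config.rt_log_effects.get(k, 0.0) for k in FIXED_TERMS])
    beta_acc = np.array([config.acc_logit_effects.get(k, 0.0) for k in FIXED_TERMS])

    pmap = {p: i for i, p in enumerate(participants)}
    items = item_id(trials)
    imap = {it: i for i, it in enumerate(sorted(items.unique()))}
    pidx = trials["participant"].map(pmap).to_numpy()
    iidx = items.map(imap).to_numpy()

    bp = rng.normal(0, config.rt_sd_participant, len(pmap))
    bi = rng.normal(0, config.rt_sd_item, len(imap))
    bs = rng.normal(0, config.rt_sd_trial_slope, len(pmap))
    ap = rng.normal(0, config.acc_sd_participant, len(pmap))
    ai = rng.normal(0, config.acc_sd_item, len(imap))
    aslope = rng.normal(0, config.acc_sd_trial_slope, len(pmap))

    z = rng.standard_normal(len(trials))
    xt = X["trial"].to_numpy()
    log_rt = (X.to_numpy() @ beta_rt + bp[pidx] + bi[iidx] + bs[pidx] * xt
              - config.rt_attention_sd * z
              + rng.normal(0, config.rt_sd_resid, len(trials)))
    eta = X.to_numpy() @ beta_acc + ap[pidx] + ai[iidx] + aslope[pidx] * xt
    trials["rt_s"] = np.exp(log_rt)
    trials["correct"] = (rng.random(len(trials))
                         < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    trials["latent_attention"] = z
    trials["condition"] = condition_label(trials)
    trials.attrs["seed"] = config.seed
    return trials


# ---------------------------------------------------------------------------
# ERP waveform machinery


def hann_bump(times: np.ndarray, center_s: float, half_width_s: float,
              amp: float = 1.0) -> np.ndarray:
    """Raised-cosine bump: amp/2*(1+cos(pi*(t-c)/hw)) inside |t-c|<hw."""
    y = np.zeros_like(times)
    m = np.abs(times - center_s) < half_width_s
    y[m] = amp * 0.5 * (1.0 + np.cos(np.pi * (times[m] - center_s) / half_width_s))
    return y


def epoch_times(config: GeneratorConfig) -> np.ndarray:
    t0, t1 = config.epoch_window_s
    fs = config.sfreq
    return np.arange(round(t0 * fs), round(t1 * fs) + 1) / fs


def _topo_weight(layout: ChannelLayout, center_ch: str, scale: float) -> np.ndarray:
    ang = layout.angular_distances()
    c = layout.ch_names.index(center_ch)
    return np.exp(-(ang[c] / scale) ** 2 / 2.0)


def auditory_kernel(config: GeneratorConfig, layout: ChannelLayout) -> np.ndarray:
    """Common target-tone evoked response (channels x times, microvolts).

    N1-P2 fronto-central complex plus a modest domain-general centro-
    parietal P3; present in every trial regardless of condition.
    """
    t = epoch_times(config)
    fc = _topo_weight(layout, "FCz", 0.7)
    cp = _topo_weight(layout, "Pz", 0.7)
    wave_fc = (hann_bump(t, 0.100, 0.050, -4.0) + hann_bump(t, 0.200, 0.060, 3.0))
    wave_cp = hann_bump(t, 0.450, 0.150, 2.0)
    return fc[:, None] * wave_fc[None, :] + cp[:, None] * wave_cp[None, :]


def p300_waveform(config: GeneratorConfig) -> np.ndarray:
    """Unit-effect P300 bump whose ROI-window mean equals one microvolt."""
    t = epoch_times(config)
    a, b = (v / 1000.0 for v in config.p300_window_ms)
    c, hw = (a + b) / 2.0, (b - a) / 2.0
    wave = hann_bump(t, c, hw, 1.0)
    mask = (t >= a - 1e-12) & (t < b - 1e-12)
    return wave / wave[mask].mean()


def psw_waveform(config: GeneratorConfig, modality: str) -> np.ndarray:
    """Slow-wave bump for one modality, unit peak amplitude.

    Peak and extent follow the configured latencies: a raised cosine
    peaking at ``psw_peak_ms`` plus, where the configured extent reaches
    beyond the peak bump (the visual case), a second raised cosine at
    ``psw_late_ratio`` amplitude filling the remainder of the extent.
    """
    t = epoch_times(config)
    peak = config.psw_peak_ms[modality] / 1000.0
    lo, hi = (v / 1000.0 for v in config.psw_extent_ms[modality])
    if not lo < peak < hi:
        raise ValueError(f"PSW peak for {modality} outside its extent")
    hw = min(peak - lo, hi - peak)
    wave = hann_bump(t, peak, hw, 1.0)
    if hi - (peak + hw) > 1e-6 and config.psw_late_ratio > 0:
        # extent reaches beyond the peak bump: fill it with a weaker raised
        # cosine from just past the peak to the end of the extent, keeping
        # the wave sustained without moving its maximum
        lo2 = peak + 0.25 * hw
        wave = wave + hann_bump(t, (lo2 + hi) / 2.0, (hi - lo2) / 2.0,
                                config.psw_late_ratio)
    return wave


def onef_noise(rng: np.random.Generator, shape: tuple[int, ...], n_times: int,
               alpha: float) -> np.ndarray:
    """Unit-variance noise with a 1/f^alpha power spectrum along the last axis."""
    freqs = np.fft.rfftfreq(n_times)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-alpha / 2.0)
    spec = (rng.standard_normal(shape + (len(freqs),))
            + 1j * rng.standard_normal(shape + (len(freqs),))) * scale
    x = np.fft.irfft(spec, n=n_times)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _spatial_mixer(config: GeneratorConfig, layout: ChannelLayout) -> np.ndarray:
    """Cholesky factor of a distance kernel with unit channel variances."""
    ang = layout.angular_distances()
    K = np.exp(-(ang / config.noise_spatial_scale_rad) ** 2 / 2.0)
    L = np.linalg.cholesky(K + 1e-9 * np.eye(len(K)))
    return L / np.linalg.norm(L, axis=1, keepdims=True)


def _epoch_noise(config: GeneratorConfig, layout: ChannelLayout,
                 rng: np.random.Generator, n_trials: int,
                 n_times: int) -> np.ndarray:
    if config.noise_sd_uV == 0:
        return np.zeros((n_trials, layout.n_eeg, n_times))
    wf = config.noise_white_frac
    noise = np.sqrt(1 - wf) * onef_noise(
        rng, (n_trials, layout.n_eeg), n_times, config.noise_alpha)
    noise += np.sqrt(wf) * rng.standard_normal((n_trials, layout.n_eeg, n_times))
    L = _spatial_mixer(config, layout)
    return config.noise_sd_uV * np.einsum("ck,tkn->tcn", L, noise)


def generate_epochs(config: GeneratorConfig, behavior: pd.DataFrame,
                    layout: ChannelLayout | None = None) -> EpochSet:
    """Target-locked EEG epochs for each behavioral trial (EEG channels only).

    Deterministic per participant given the config seed, so generating a
    subset of participants reproduces the corresponding epochs exactly.
    """
    layout = layout or standard_layout()
    try:
        cf_idx = layout.index(CF_ROI)
        co_idx = layout.index(CO_ROI)
    except ValueError as err:
        raise ValueError(f"layout lacks ROI electrodes: {err}") from err
    required = {"participant", "condition", "modality", "congruence",
                "latent_attention"}
    missing = required - set(behavior.columns)
    if missing:
        raise ValueError(f"behavior table lacks columns: {sorted(missing)}")

    t = epoch_times(config)
    kernel = auditory_kernel(config, layout)
    p300 = p300_waveform(config)
    psw = {m: psw_waveform(config, m) for m in ("olfactory", "visual")}

    data = np.empty((len(behavior), layout.n_eeg, len(t)))
    behavior = behavior.reset_index(drop=True)
    for name, rows in behavior.groupby("participant").groups.items():
        rows = np.asarray(rows)
        rng = _rng_for(config.seed, "epochs", name)
        block = np.tile(kernel, (len(rows), 1, 1))
        sub = behavior.iloc[rows]
        incong = (sub["congruence"] == "incongruent").to_numpy()
        z = sub["latent_attention"].to_numpy()
        gamma = sub["condition"].map(config.amp_rt_coupling).fillna(0.0).to_numpy()
        p300_amp = incong * config.p300_effect_uV + gamma * z
        block[:, cf_idx, :] += p300_amp[:, None, None] * p300[None, None, :]
        for mod in ("olfactory", "visual"):
            sel = incong & (sub["modality"] == mod).to_numpy()
            if sel.any():
                block[np.flatnonzero(sel)[:, None], co_idx[None, :], :] += (
                    config.psw_effect_uV * psw[mod][None, None, :])
        block += _epoch_noise(config, layout, rng, len(rows), len(t))
        data[rows] = block

    return EpochSet(data, t, config.sfreq, list(layout.ch_names), behavior,
                    meta={"seed": config.seed})


def blink_template(sfreq: float, amp: float) -> np.ndarray:
    """A 300-ms raised-cosine blink deflection."""
    n = int(round(0.3 * sfreq))
    return amp * 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / n))


def generate_continuous(config: GeneratorConfig, behavior: pd.DataFrame,
                        layout: ChannelLayout | None = None
                        ) -> ContinuousRecording:
    """Continuous recording with event markers, blinks and bad channels.

    Trials are laid out sequentially (sniff cue, picture at +400 ms,
    target tone after the stimulus plus its delay, response after the
    trial's RT); the target-locked epoch spans carry exactly the signal
    :func:`generate_epochs` produces, so with blinks and bad channels
    disabled, epoching this recording round-trips the epoch generator.
    """
    layout = layout or standard_layout()
    behavior = behavior.reset_index(drop=True)
    fs = config.sfreq
    epochs = generate_epochs(config, behavior, layout)
    n_ep = epochs.data.shape[2]
    pre = -round(config.epoch_window_s[0] * fs)

    sniff, picture, tone, response = [], [], [], []
    cursor = round(0.5 * fs)
    for _, row in behavior.iterrows():
        s = cursor + round(0.5 * fs)
        p = s + round(0.4 * fs)
        tn = p + round((1.5 + row["delay_ms"] / 1000.0) * fs)
        r = tn + round(float(row["rt_s"]) * fs)
        sniff.append(s); picture.append(p); tone.append(tn); response.append(r)
        cursor = max(r, tn + n_ep - pre) + round(0.5 * fs)
    total = cursor + round(0.5 * fs)

    names = layout.all_names
    data = np.zeros((len(names), total))
    rng = _rng_for(config.seed, "continuous")
    n_eog = len(layout.eog_names)
    data[layout.n_eeg:] = rng.normal(0, 2.0, (n_eog, total))
    for i, tn in enumerate(tone):
        data[:layout.n_eeg, tn - pre:tn - pre + n_ep] += epochs.data[i]

    log: list[dict] = []
    if config.blink_rate_per_min > 0:
        veog = layout.n_eeg + layout.eog_names.index("VEOG")
        prop = 0.45 * _topo_weight(layout, "Fpz", 0.5)
        tmpl = blink_template(fs, config.blink_amp_uV)
        n_blinks = rng.poisson(config.blink_rate_per_min * total / fs / 60.0)
        starts = rng.integers(0, total - len(tmpl), n_blinks)
        for s in starts:
            data[veog, s:s + len(tmpl)] += tmpl
            data[:layout.n_eeg, s:s + len(tmpl)] += prop[:, None] * tmpl[None, :]

    if config.n_bad_channels > 0:
        kinds = ["flat", "noisy", "disconnected"]
        bad = rng.choice(layout.n_eeg, size=config.n_bad_channels, replace=False)
        for j, ch in enumerate(bad):
            kind = kinds[j % len(kinds)]
            if kind == "flat":
                data[ch] = 0.0
            elif kind == "noisy":
                data[ch] += rng.normal(0, 200.0, total)
            else:  # slow large drift, as from a detached electrode
                drift = np.cumsum(rng.normal(0, 30.0, total))
                drift -= np.linspace(drift[0], drift[-1], total)
                data[ch] = drift + rng.normal(0, 5.0, total)
            log.append({"channel": names[ch], "kind": kind})

    events = pd.DataFrame({
        "sample": sniff + picture + tone + response,
        "label": (["sniff"] * len(sniff) + ["picture"] * len(picture)
                  + ["tone"] * len(tone) + ["response"] * len(response)),
        "trial": list(behavior["trial"]) * 4,
    }).sort_values("sample", kind="stable").reset_index(drop=True)
    return ContinuousRecording(
        data, fs, names, events,
        meta={"seed": config.seed, "bad_channel_log": log},
    )
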