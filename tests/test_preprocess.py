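"""Filtering, channel QC, interpolation, referencing, epoching, rejection."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from olferp.containers import ContinuousRecording, EpochSet
from olferp.preprocess import (bandpass_filter, baseline_correct,
                               correct_ocular, detect_bad_channels, epoch,
                               exclude_participants, interpolate_channels,
                               reject_epochs, rereference_average, resample)

from conftest import make_recording

FS = 512.0


def empty_events():
    return pd.DataFrame({"sample": [], "label": []})


class TestBandpass:
    def test_passband_stopband_and_dc(self, layout):
        n = int(30 * FS)
        t = np.arange(n) / FS
        data = np.zeros((66, n))
        data[0] = np.sin(2 * np.pi * 10 * t)
        data[1] = np.sin(2 * np.pi * 100 * t)
        data[2] = 50.0
        out = bandpass_filter(make_recording(layout, data))
        mid = slice(n // 4, 3 * n // 4)
        assert out.data[0, mid].std() == pytest.approx(data[0, mid].std(),
                                                       rel=0.01)
        atten = 20 * np.log10(out.data[1, mid].std() / data[1, mid].std())
        assert atten < -20
        assert np.abs(out.data[2]).max() < 1e-6

    def test_upper_edge_above_nyquist_rejected(self, layout):
        rec = make_recording(layout, np.zeros((66, 1024)), sfreq=64.0)
        with pytest.raises(ValueError):
            bandpass_filter(rec, high_hz=40.0)


class TestResample:
    def test_downsample_preserves_sine_and_rescales_events(self):
        n = 4 * 2048
        t = np.arange(n) / 2048.0
        rec = ContinuousRecording(
            np.sin(2 * np.pi * 5 * t)[None, :], 2048.0, ["a"],
            pd.DataFrame({"sample": [2048], "label": ["e"]}))
        out = resample(rec, 512.0)
        assert out.data.shape[1] == n // 4
        assert out.events["sample"].iloc[0] == 512
        t2 = np.arange(out.data.shape[1]) / 512.0
        mid = slice(100, -100)
        assert np.allclose(out.data[0, mid],
                           np.sin(2 * np.pi * 5 * t2)[mid], atol=1e-3)

    def test_identity_when_rate_matches(self):
        rec = ContinuousRecording(np.random.default_rng(0).normal(size=(1, 512)),
                                  512.0, ["a"], empty_events())
        out = resample(rec, 512.0)
        assert np.array_equal(out.data, rec.data)


class TestBadChannels:
    def test_flat_channel_flagged_by_correlation(self, layout,
                                                 correlated_background):
        data = correlated_background.copy()
        data[5] = 0.0
        reports = detect_bad_channels(make_recording(layout, data), layout)
        flagged = {(r.channel, r.criterion) for r in reports}
        assert (layout.all_names[5], "correlation") in flagged

    def test_large_square_wave_flagged_by_amplitude(self, layout,
                                                    correlated_background):
        data = correlated_background.copy()
        t = np.arange(data.shape[1]) / FS
        # 600 uV square wave with transitions inside most 1-s windows
        data[7] = 300.0 * np.sign(np.sin(2 * np.pi * 1.3 * t))
        reports = detect_bad_channels(make_recording(layout, data), layout)
        flagged = {(r.channel, r.criterion) for r in reports}
        assert (layout.all_names[7], "amplitude") in flagged
        # brute-force window count confirms the fraction criterion
        win = int(FS)
        n_win = data.shape[1] // win
        w = data[7, :n_win * win].reshape(n_win, win)
        frac = ((w.max(axis=1) - w.min(axis=1)) > 500).mean()
        assert frac > 0.5

    def test_identical_channels_are_clean(self, layout):
        sig = np.tile(np.random.default_rng(1).normal(0, 10, int(5 * FS)),
                      (66, 1))
        assert detect_bad_channels(make_recording(layout, sig), layout) == []

    def test_recording_shorter_than_window_rejected(self, layout):
        rec = make_recording(layout, np.zeros((66, 100)))
        with pytest.raises(ValueError):
            detect_bad_channels(rec, layout)

    def test_injected_bad_channels_detected_on_generator_output(self, layout):
        """Recall 1.0 for flat and high-amplitude corrupted channels."""
        from olferp.simulate import (default_config, generate_behavior,
                                     generate_continuous)

        cfg = dataclasses.replace(default_config(n_participants=1, seed=21),
                                  n_bad_channels=3)
        beh = generate_behavior(cfg).head(10).reset_index(drop=True)
        rec = generate_continuous(cfg, beh, layout)
        injected = {e["channel"] for e in rec.meta["bad_channel_log"]}
        reports = detect_bad_channels(rec, layout)
        assert injected <= {r.channel for r in reports}


class TestInterpolation:
    def test_constant_field_reproduced(self, layout):
        data = np.full((66, 256), 7.5)
        out = interpolate_channels(make_recording(layout, data), layout, ["Cz"])
        assert np.allclose(out.data[layout.all_names.index("Cz")], 7.5)

    def test_leave_one_out_on_smooth_topography(self, layout):
        n = 256
        wave = np.sin(2 * np.pi * 3 * np.arange(n) / FS)
        topo = np.exp(-2 * (1 - layout.positions @ layout.positions[10]) ** 2)
        data = np.zeros((66, n))
        data[:64] = topo[:, None] * wave[None, :]
        truth = data[layout.all_names.index("C3")].copy()
        out = interpolate_channels(make_recording(layout, data), layout, ["C3"])
        r = np.corrcoef(out.data[layout.all_names.index("C3")], truth)[0, 1]
        assert r > 0.9

    def test_zero_signal_stays_zero(self, layout):
        out = interpolate_channels(
            make_recording(layout, np.zeros((66, 64))), layout, ["Pz"])
        assert np.allclose(out.data, 0.0)

    def test_too_few_good_channels_rejected(self, layout):
        rec = make_recording(layout, np.zeros((66, 64)))
        with pytest.raises(ValueError):
            interpolate_channels(rec, layout, list(layout.ch_names[:62]))


class TestAverageReference:
    def test_channel_mean_zero_and_idempotent(self, layout,
                                              correlated_background):
        rec = make_recording(layout, correlated_background)
        out = rereference_average(rec)
        eeg = [i for i, n in enumerate(out.ch_names)
               if n not in ("VEOG", "HEOG")]
        assert np.allclose(out.data[eeg].mean(axis=0), 0.0, atol=1e-10)
        again = rereference_average(out)
        assert np.allclose(again.data, out.data, atol=1e-10)

    def test_single_channel_becomes_zero(self):
        rec = ContinuousRecording(np.random.default_rng(0).normal(size=(1, 64)),
                                  FS, ["Cz"], empty_events())
        assert np.allclose(rereference_average(rec).data, 0.0)


class TestOcularCorrection:
    def test_exact_linear_contamination_removed(self, layout):
        n = int(30 * FS)
        t = np.arange(n) / FS
        eog = np.zeros(n)
        blink = (t > 5) & (t < 6)
        eog[blink] = 200 * np.sin(np.pi * (t[blink] - 5)) ** 2
        clean = 5 * np.sin(2 * np.pi * 7 * t)
        clean[blink] = 0.0
        data = np.zeros((66, n))
        data[0] = clean + 0.3 * eog
        data[layout.all_names.index("VEOG")] = eog
        out = correct_ocular(make_recording(layout, data), ["VEOG"])
        assert np.abs(out.data[0] - clean).max() < 1e-6 * np.abs(clean).max()

    def test_zero_eog_is_identity(self, layout, correlated_background):
        data = correlated_background.copy()
        data[64:] = 0.0
        rec = make_recording(layout, data)
        out = correct_ocular(rec, ["VEOG", "HEOG"])
        assert np.array_equal(out.data, rec.data)

    def test_generator_blinks_suppressed_in_frontal_channels(self, layout):
        from olferp.simulate import (default_config, generate_behavior,
                                     generate_continuous)

        cfg = dataclasses.replace(default_config(n_participants=1, seed=31),
                                  blink_rate_per_min=30.0, n_bad_channels=0)
        beh = generate_behavior(cfg).head(10).reset_index(drop=True)
        rec = generate_continuous(cfg, beh, layout)
        veog = rec.pick(["VEOG"])[0]
        blink_samples = veog > 50.0
        assert blink_samples.any()
        fp = rec.ch_names.index("Fpz")
        out = correct_ocular(rec, ["VEOG", "HEOG"])
        var_before = rec.data[fp, blink_samples].var()
        var_after = out.data[fp, blink_samples].var()
        assert var_after < 0.2 * var_before


class TestEpoching:
    def test_one_epoch_per_event_with_expected_length(self, layout):
        n = int(20 * FS)
        events = pd.DataFrame({"sample": [2000, 4000, 6000],
                               "label": ["tone"] * 3})
        rec = make_recording(layout, np.zeros((66, n)), events=events)
        eps = epoch(rec, "tone", -0.2, 1.0)
        assert eps.n_epochs == 3
        assert eps.data.shape[2] == round(1.2 * FS) + 1

    def test_boundary_event_dropped_and_logged(self, layout):
        events = pd.DataFrame({"sample": [10, 3000], "label": ["tone"] * 2})
        rec = make_recording(layout, np.zeros((66, 4000)), events=events)
        eps = epoch(rec, "tone")
        assert eps.n_epochs == 1
        assert eps.meta["dropped_events"] == [10]

    def test_time_zero_at_event(self, layout):
        n = 4000
        data = np.zeros((66, n))
        data[:, 2000] = 9.0
        events = pd.DataFrame({"sample": [2000], "label": ["tone"]})
        eps = epoch(make_recording(layout, data, events=events), "tone")
        i0 = np.argmin(np.abs(eps.times))
        assert eps.times[i0] == 0.0
        assert eps.data[0, 0, i0] == 9.0


class TestBaseline:
    def _epochs(self, data):
        n_t = data.shape[2]
        times = (np.arange(n_t) - round(0.2 * FS)) / FS
        return EpochSet(data, times, FS, [f"c{i}" for i in range(data.shape[1])],
                        pd.DataFrame(index=range(data.shape[0])))

    def test_constant_epoch_zeroed(self):
        eps = self._epochs(np.full((2, 3, 615), 4.2))
        assert np.allclose(baseline_correct(eps).data, 0.0)

    def test_baseline_mean_zero_after(self):
        rng = np.random.default_rng(3)
        eps = self._epochs(rng.normal(size=(4, 3, 615)))
        out = baseline_correct(eps)
        mask = out.time_mask(-0.2, 0.0)
        assert np.allclose(out.data[:, :, mask].mean(axis=2), 0.0, atol=1e-12)

    def test_ramp_crossing_window_midpoint_unchanged(self):
        eps = self._epochs(np.zeros((1, 1, 615)))
        mask = eps.time_mask(-0.2, 0.0)
        midpoint = eps.times[mask].mean()
        eps.data[0, 0] = 3.0 * (eps.times - midpoint)
        out = baseline_correct(eps)
        assert np.allclose(out.data, eps.data, atol=1e-12)


class TestRejection:
    def _clean_epochs(self, n=20, rng=None):
        rng = rng or np.random.default_rng(5)
        data = rng.normal(0, 5, (n, 4, 615))
        times = (np.arange(615) - round(0.2 * FS)) / FS
        meta = pd.DataFrame({"rt_s": np.full(n, 0.8)})
        return EpochSet(data, times, FS, list("abcd"), meta)

    def test_absolute_peak_to_peak_violation(self):
        eps = self._clean_epochs()
        eps.data[3, 1, 300] = 130.0
        kept, log = reject_epochs(eps)
        assert 3 not in kept.metadata.index.to_list() or kept.n_epochs == 19
        assert ("p2p_120" in set(log.loc[log["epoch_id"] == 3, "reason"]))

    def test_rt_bounds_violation(self):
        eps = self._clean_epochs()
        eps.metadata.loc[7, "rt_s"] = 0.150
        eps.metadata.loc[9, "rt_s"] = 6.0
        kept, log = reject_epochs(eps)
        assert kept.n_epochs == 18
        assert set(log["reason"]) == {"rt_bounds"}

    def test_identical_clean_epochs_survive(self):
        data = np.tile(np.random.default_rng(1).normal(0, 5, (1, 4, 615)),
                       (10, 1, 1))
        times = (np.arange(615) - round(0.2 * FS)) / FS
        eps = EpochSet(data, times, FS, list("abcd"),
                       pd.DataFrame({"rt_s": np.full(10, 1.0)}))
        kept, log = reject_epochs(eps)
        assert kept.n_epochs == 10 and len(log) == 0

    def test_every_removal_is_logged_and_counts_conserve(self):
        rng = np.random.default_rng(11)
        eps = self._clean_epochs(40, rng)
        eps.data[2, 0, :] += np.linspace(0, 200, 615)
        eps.metadata.loc[5, "rt_s"] = 0.05
        kept, log = reject_epochs(eps)
        assert kept.n_epochs + len(set(log["epoch_id"])) == 40


class TestParticipantExclusion:
    def _trials(self, acc_by_participant):
        rows = []
        for p, (acc_c, acc_i) in acc_by_participant.items():
            for cong, acc in (("congruent", acc_c), ("incongruent", acc_i)):
                n_ok = int(round(acc * 100))
                rows += [{"participant": p, "congruence": cong, "correct": 1}] * n_ok
                rows += [{"participant": p, "congruence": cong, "correct": 0}] * (100 - n_ok)
        return pd.DataFrame(rows)

    def test_behavioral_exclusion_below_75(self):
        trials = self._trials({"P01": (0.74, 0.95), "P02": (0.90, 0.90)})
        kept, excluded, reasons = exclude_participants(trials)
        assert excluded == ["P01"] and kept == ["P02"]
        assert reasons["criterion"].tolist() == ["behavioral"]

    def test_epoch_boundary_inclusive_of_fifteen(self):
        trials = self._trials({"P01": (0.9, 0.9)})
        counts = pd.DataFrame(
            [{"participant": "P01", "congruence": c, "modality": m, "n": 15}
             for c in ("congruent", "incongruent")
             for m in ("olfactory", "visual")])
        kept, excluded, _ = exclude_participants(trials, counts)
        assert kept == ["P01"] and excluded == []

    def test_fourteen_in_one_cell_excludes(self):
        trials = self._trials({"P01": (0.9, 0.9)})
        counts = pd.DataFrame(
            [{"participant": "P01", "congruence": c, "modality": m, "n": 20}
             for c in ("congruent", "incongruent")
             for m in ("olfactory", "visual")])
        counts.loc[0, "n"] = 14
        kept, excluded, reasons = exclude_participants(trials, counts)
        assert excluded == ["P01"]
        assert reasons["criterion"].tolist() == ["erp"]
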