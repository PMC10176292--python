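"""Pruning, OD conversion, motion correction, filtering, epoching rules."""

import numpy as np
import pytest

from nirsav import (
    Event, RawRecording, bandpass, correct_motion, default_montage,
    epoch_and_reject, prune_channels, window_means,
)
from nirsav import preprocess as pp
from nirsav.optics import intensity_to_od as od_from_intensity
from nirsav.preprocess import PreprocessParams
from nirsav.simulate import simulate_cohort
from .conftest import clean_config

FS = 10.0


def _recording(intensity, events=None, looking=None, fs=FS):
    n_stim = len([e for e in (events or []) if e.condition != "baseline"])
    return RawRecording(
        participant_id="p1", age_group="younger", sampling_rate=fs,
        intensity=intensity, events=events or [],
        looking=np.asarray(looking if looking is not None else [0.9] * n_stim),
    )


class TestPrune:
    def test_low_intensity_channel_unusable(self):
        I = np.ones((46, 2, 100))
        I[4] = 0.0005
        rec = _recording(I)
        mask = prune_channels(rec, PreprocessParams())
        assert not mask[4]
        assert mask.sum() == 45

    def test_all_nominal_channels_usable(self):
        rec = _recording(np.ones((46, 2, 100)))
        assert prune_channels(rec, PreprocessParams()).all()

    def test_high_intensity_channel_unusable(self):
        I = np.ones((46, 2, 100))
        I[0] = 11.0
        assert not prune_channels(_recording(I), PreprocessParams())[0]


class TestOpticalDensity:
    def test_constant_intensity_gives_zero_od(self):
        od = od_from_intensity(np.full((3, 2, 50), 2.0))
        assert np.allclose(od, 0.0)

    def test_log10_identity(self):
        I = np.ones(1000)
        I[500] = I.mean() / 10  # approximately Ibar/10
        od = od_from_intensity(I[None, None, :])
        assert od[0, 0, 500] == pytest.approx(1.0, abs=5e-3)

    def test_exp_mean_property(self):
        rng = np.random.default_rng(0)
        I = rng.lognormal(0, 0.3, size=(4, 2, 512))
        od = od_from_intensity(I)
        assert np.allclose((10.0 ** (-od)).mean(axis=-1), 1.0, atol=1e-12)

    def test_nonpositive_sample_raises(self):
        I = np.ones((2, 2, 50))
        I[1, 0, 3] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            od_from_intensity(I)


class TestMotionCorrection:
    def test_noop_on_smooth_signal(self):
        t = np.arange(0, 120, 1 / FS)
        x = 0.1 * np.sin(2 * np.pi * 0.08 * t)
        od = np.tile(x, (46, 2, 1))
        out, segs = correct_motion(od, FS, PreprocessParams())
        assert segs == []
        rms = np.sqrt((x**2).mean())
        change = np.sqrt(((out[0, 0] - x) ** 2).mean())
        assert change < 0.01 * rms

    def test_spike_removed_and_reported(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 120, 1 / FS)
        base = 0.05 * np.sin(2 * np.pi * 0.08 * t)
        od = np.tile(base, (46, 2, 1)) + rng.normal(0, 0.005, (46, 2, len(t)))
        spike = 0.8 * np.exp(-0.5 * ((t - 60.0) / 0.15) ** 2)
        od[7] += spike
        out, segs = correct_motion(od, FS, PreprocessParams())
        assert any(ch == 7 and t0 <= 60.0 <= t1 for ch, t0, t1 in segs)
        win = (t > 58) & (t < 62)
        peak_before = np.abs(od[7, 0, win] - base[win]).max()
        peak_after = np.abs(out[7, 0, win] - base[win]).max()
        assert peak_after < 0.2 * peak_before

    def test_zero_series_unchanged(self):
        od = np.zeros((46, 2, 600))
        out, segs = correct_motion(od, FS, PreprocessParams())
        assert segs == []
        np.testing.assert_allclose(out, od)


class TestBandpass:
    params = PreprocessParams()

    def _gain(self, freq):
        t = np.arange(0, 600, 1 / FS)
        x = np.sin(2 * np.pi * freq * t)
        y = bandpass(x, FS, self.params)
        core = slice(len(t) // 4, 3 * len(t) // 4)  # avoid edge transients
        return np.abs(y[core]).max()

    def test_passband_gain(self):
        assert self._gain(0.12) >= 0.9

    def test_cardiac_attenuated(self):
        assert self._gain(2.0) <= 0.1

    def test_slow_drift_attenuated(self):
        assert self._gain(0.005) <= 0.1

    def test_zero_in_zero_out(self):
        assert np.allclose(bandpass(np.zeros(500), FS, self.params), 0.0)

    def test_band_above_nyquist_rejected(self):
        bad = PreprocessParams(band_hz=(0.03, 6.0))
        with pytest.raises(ValueError):
            bandpass(np.zeros(500), FS, bad)


def _simple_session(n_trials=8, gap=30.0, fs=FS):
    """Alternating bimodal/alternating trials every `gap` s, 46-ch flat data."""
    events = []
    t = 10.0
    for k in range(n_trials):
        cond = "bimodal" if k % 2 == 0 else "alternating"
        events.append(Event(cond, t, 8.0))
        t += gap
    n = int((t + 25) * fs)
    conc = np.ones((46, 2, n))
    rec = _recording(np.ones((46, 2, n)), events)
    return conc, rec


class TestExclusionRules:
    params = PreprocessParams()

    def test_artifact_in_pre_trial_guard_rejects_trial(self):
        conc, rec = _simple_session()
        onset = rec.stim_events()[2].onset_s
        usable = np.ones(46, bool)
        # artifact ending 3 s before onset: inside the 5 s guard
        arts = [(None, onset - 4.0, onset - 3.0)]
        epochs, _ = epoch_and_reject(conc, rec, arts, usable, self.params)
        assert epochs.motion_rejected[2].all()
        assert not epochs.motion_rejected[1].any()

    def test_looking_rule_boundary(self):
        conc, rec = _simple_session()
        rec.looking[0] = 0.35  # away 65% -> rejected
        rec.looking[1] = 0.40  # exactly at the boundary -> kept
        epochs, _ = epoch_and_reject(conc, rec, [], np.ones(46, bool),
                                     self.params)
        assert epochs.looking_rejected[0]
        assert not epochs.looking_rejected[1]

    def test_channel_excluded_after_four_artifact_trials(self):
        conc, rec = _simple_session()
        onsets = [e.onset_s for e in rec.stim_events()]
        arts = [(5, o + 1.0, o + 1.5) for o in onsets[:4]]
        epochs, _ = epoch_and_reject(conc, rec, arts, np.ones(46, bool),
                                     self.params)
        assert epochs.channel_excluded[5]
        assert not epochs.channel_excluded[6]
        arts3 = arts[:3]
        epochs3, _ = epoch_and_reject(conc, rec, arts3, np.ones(46, bool),
                                      self.params)
        assert not epochs3.channel_excluded[5]

    def test_too_few_trials_excludes_participant(self):
        conc, rec = _simple_session()
        # reject all but 2 bimodal trials via looking
        conds = [e.condition for e in rec.stim_events()]
        k = 0
        for i, c in enumerate(conds):
            if c == "bimodal" and k < 2:
                k += 1
            elif c == "bimodal":
                rec.looking[i] = 0.1
        _, verdict = epoch_and_reject(conc, rec, [], np.ones(46, bool),
                                      self.params)
        assert not verdict.included
        assert any("bimodal=2" in r for r in verdict.reasons)

    def test_channel_count_rule(self):
        conc, rec = _simple_session()
        usable = np.ones(46, bool)
        usable[:16] = False  # 30 usable < 31
        _, verdict = epoch_and_reject(conc, rec, [], usable, self.params)
        assert not verdict.included
        usable = np.ones(46, bool)
        usable[:15] = False  # exactly 31 usable -> included
        _, verdict31 = epoch_and_reject(conc, rec, [], usable, self.params)
        assert verdict31.included

    def test_epoch_past_recording_end_dropped(self):
        conc, rec = _simple_session()
        rec.events.append(Event("bimodal", rec.duration_s - 10.0, 8.0))
        rec.looking = np.append(rec.looking, 0.9)
        with pytest.warns(UserWarning, match="extends past"):
            epochs, _ = epoch_and_reject(conc, rec, [], np.ones(46, bool),
                                         self.params)
        assert len(epochs.conditions) == 8


class TestWindowMeans:
    def test_constant_epochs_give_unit_means(self):
        conc, rec = _simple_session()
        epochs, _ = epoch_and_reject(conc, rec, [], np.ones(46, bool),
                                     PreprocessParams())
        table = window_means(epochs, PreprocessParams())
        assert np.allclose(table["mean"], 1.0)
        assert set(table.n_trials) == {4}

    def test_rejected_trials_contribute_nothing(self):
        conc, rec = _simple_session()
        conc = conc.copy()
        onset = rec.stim_events()[0].onset_s
        i0 = int((onset - 5) * FS)
        conc[:, :, i0:i0 + 250] = 100.0  # poisoned trial
        arts = [(None, onset, onset + 1.0)]
        epochs, _ = epoch_and_reject(conc, rec, arts, np.ones(46, bool),
                                     PreprocessParams())
        table = window_means(epochs, PreprocessParams())
        assert np.allclose(table["mean"], 1.0)


class TestPipelineOrder:
    def test_filter_before_motion_changes_output(self):
        """Guard: on artifact-bearing data, band-passing before motion
        correction is not equivalent to the pipeline order."""
        rng = np.random.default_rng(4)
        t = np.arange(0, 120, 1 / FS)
        od = np.tile(0.05 * np.sin(2 * np.pi * 0.08 * t), (46, 2, 1))
        od += rng.normal(0, 0.01, od.shape)
        od[3] += 1.0 * np.exp(-0.5 * ((t - 50.0) / 0.2) ** 2)
        params = PreprocessParams()
        a, _ = correct_motion(od, FS, params)
        a = bandpass(a, FS, params)
        b, _ = correct_motion(bandpass(od, FS, params), FS, params)
        assert not np.allclose(a, b, atol=1e-6)

    def test_attrition_reasons_match_ground_truth(self):
        """Seeded cohort: participant verdicts derived from the simulator's
        planted truth agree with the pipeline's own accounting."""
        from nirsav.preprocess import preprocess_cohort
        from nirsav.simulate import AttritionConfig

        cfg = clean_config(seed=77, n=8)
        cfg.attrition = AttritionConfig(p_channel_missing=0.3,
                                        looking_alpha=2.0, looking_beta=1.5)
        recs, gt = simulate_cohort(cfg)
        _, verdicts = preprocess_cohort(
            recs, artifact_lists=gt.artifact_segments)
        for rec, v in zip(recs, verdicts):
            n_dropped = len(gt.dropped_channels[rec.participant_id])
            assert v.n_usable_channels == 46 - n_dropped
            expect_channel_fail = (46 - n_dropped) < 31
            if expect_channel_fail:
                assert not v.included
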