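"""Filtering, flatline rules, spherical-spline interpolation, QC formulas."""

import numpy as np
import pytest
from scipy import signal as sps

from conftest import make_recording, sine
from fceeg.errors import InputError, InterpolationError, ParameterError
from fceeg.io import Recording
from fceeg.preprocess import (
    bandpass_filter,
    crop_resting,
    design_bandpass,
    detect_bad_channels,
    detect_bad_segments,
    interpolate_channels,
    per_channel_flat_duration,
    preprocess_recording,
    qc_report,
    qc_summary,
    remove_artifact_components,
    split_good_chunks,
)
from fceeg.simulate import blink_reference, blink_template, generate_recording
from fceeg.spectral import relative_power, welch_psd


class TestBandpassFilter:
    def test_passband_tone_preserved(self):
        rec = make_recording(sine(10, 30))
        out = bandpass_filter(rec)
        mid = out.data[0, 2000:-2000]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_slow_drift_strongly_attenuated(self):
        # transfer-function oracle: designed response at 0.1 Hz
        sos = design_bandpass(0.5, 45, 250)
        _w, h = sps.sosfreqz(sos, worN=[0.1], fs=250)
        expected_gain = np.abs(h[0]) ** 2  # zero-phase doubles attenuation
        rec = make_recording(sine(0.1, 60))
        out = bandpass_filter(rec)
        mid = np.abs(out.data[0, 5000:-5000]).max()
        assert mid <= 0.1  # >= 90% attenuation
        assert mid == pytest.approx(expected_gain, rel=0.5)

    def test_dc_removed(self):
        rec = make_recording(np.full(5000, 7.0))
        out = bandpass_filter(rec)
        assert np.abs(out.data).max() < 1e-6

    def test_stopband_attenuation_of_design(self):
        sos = design_bandpass(0.5, 45, 250)
        _w, h = sps.sosfreqz(sos, worN=[0.25, 67.5], fs=250)
        att_db = -20 * np.log10(np.abs(h) ** 2)  # forward-backward
        assert np.all(att_db >= 40.0)

    def test_above_nyquist_rejected(self):
        rec = make_recording(np.zeros(1000))
        with pytest.raises(ParameterError):
            bandpass_filter(rec, 0.5, 130.0)

    def test_passband_idempotence(self, rng):
        rec = make_recording(rng.standard_normal(250 * 40))
        once = bandpass_filter(rec)
        twice = bandpass_filter(once)
        ps1 = welch_psd(once)
        ps2 = welch_psd(twice)
        sel = (ps1.frequencies >= 1) & (ps1.frequencies <= 40)
        p1 = ps1.power[0, sel].sum()
        p2 = ps2.power[0, sel].sum()
        assert abs(p2 - p1) / p1 < 0.10


class TestFlatlineRules:
    def test_all_zero_channel_flagged(self, rng):
        data = rng.standard_normal((3, 1000))
        data[1] = 0.0
        rec = make_recording(data)
        assert detect_bad_channels(rec) == {"ch1"}

    @pytest.mark.parametrize(
        "n_zero,expected", [(600, False), (610, True), (601, True)]
    )
    def test_sixty_percent_boundary_is_strict(self, rng, n_zero, expected):
        data = rng.standard_normal((1, 1000)) + 5.0
        data[0, :n_zero] = 0.0
        rec = make_recording(data)
        assert (("ch0" in detect_bad_channels(rec)) is expected)

    def test_empty_recording_rejected(self):
        rec = make_recording(np.zeros((2, 0)))
        with pytest.raises(InputError):
            detect_bad_channels(rec)

    def test_single_zeroed_window_detected(self, rng):
        data = rng.standard_normal((2, 2500)) + 2.0
        data[1, 500:750] = 0.0  # 1 s at 250 Hz
        rec = make_recording(data)
        segs = detect_bad_segments(rec)
        assert len(segs) == 1
        onset, dur = segs[0]
        assert onset == pytest.approx(2.0, abs=1 / 250)
        assert dur == pytest.approx(1.0, abs=1 / 250)

    def test_clean_recording_yields_no_segments(self, rng):
        rec = make_recording(rng.standard_normal((2, 1000)) + 2.0)
        assert detect_bad_segments(rec) == []

    def test_overlapping_windows_merge_to_interval_union(self, rng):
        data = rng.standard_normal((2, 5000)) + 2.0
        data[0, 1000:1250] = 0.0  # [4, 5] s
        data[1, 1125:1375] = 0.0  # [4.5, 5.5] s
        rec = make_recording(data)
        segs = detect_bad_segments(rec)
        assert len(segs) == 1
        onset, dur = segs[0]
        assert onset == pytest.approx(4.0, abs=1 / 250)
        assert dur == pytest.approx(1.5, abs=2 / 250)

    def test_runs_shorter_than_min_run_ignored(self, rng):
        data = rng.standard_normal((1, 1000)) + 2.0
        data[0, 100:130] = 0.0  # 0.12 s < 0.2 s
        rec = make_recording(data)
        assert detect_bad_segments(rec) == []

    def test_split_good_chunks_never_bridges_gaps(self, rng):
        rec = make_recording(rng.standard_normal((2, 2500)),
                             bad_segments=[(2.0, 1.0)])
        chunks = split_good_chunks(rec)
        assert [c.n_samples for c in chunks] == [500, 1750]


class TestInterpolation:
    def test_constant_field_reproduced(self, montage64):
        rec = make_recording(np.full((64, 50), 3.7), names=montage64.names)
        out = interpolate_channels(rec, {"Cz", "P3"}, montage64)
        i = rec.index_of("Cz")
        assert out.data[i] == pytest.approx(3.7, rel=1e-6)

    def test_first_order_harmonic_within_five_percent(self, montage64):
        xfield = montage64.positions[:, 0]
        rec = make_recording(
            np.tile(xfield[:, None], (1, 10)), names=montage64.names
        )
        bad = {"P3", "F4", "C6"}
        out = interpolate_channels(rec, bad, montage64)
        for name in bad:
            i = rec.index_of(name)
            expected = xfield[i]
            assert out.data[i, 0] == pytest.approx(expected, rel=0.05)

    def test_no_bad_channels_is_identity(self, montage64, rng):
        rec = make_recording(rng.standard_normal((64, 100)),
                             names=montage64.names)
        out = interpolate_channels(rec, set(), montage64)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_good_channels_bit_exact(self, montage64, rng):
        rec = make_recording(rng.standard_normal((64, 100)),
                             names=montage64.names)
        out = interpolate_channels(rec, {"Oz"}, montage64)
        for i, name in enumerate(rec.channel_names):
            if name != "Oz":
                np.testing.assert_array_equal(out.data[i], rec.data[i])

    def test_too_few_good_channels(self, montage64, rng):
        names = ["Fp1", "Fp2", "Cz", "Pz", "Oz"]
        rec = make_recording(rng.standard_normal((5, 10)), names=names)
        with pytest.raises(InterpolationError):
            interpolate_channels(rec, {"Fp1", "Fp2"}, montage64)

    def test_matches_reference_spherical_spline(self, montage64, rng):
        """Independent oracle: MNE's spherical-spline bad-channel repair."""
        import mne

        data = rng.standard_normal((64, 500))
        # smooth spatial structure so interpolation is meaningful
        smooth = np.exp(-2 * (1 - montage64.positions @ montage64.positions.T))
        data = smooth @ data
        rec = make_recording(data, names=montage64.names)
        bad = {"Cz", "P3"}
        ours = interpolate_channels(rec, bad, montage64)

        info = mne.create_info(list(montage64.names), 250.0, "eeg")
        raw = mne.io.RawArray(data * 1e-6, info, verbose="error")
        raw.set_montage(mne.channels.make_dig_montage(
            ch_pos={n: p * 0.095 for n, p in
                    zip(montage64.names, montage64.positions)},
            coord_frame="head"), verbose="error")
        raw.info["bads"] = sorted(bad)
        raw.interpolate_bads(verbose="error")
        theirs = raw.get_data() * 1e6
        for name in bad:
            i = rec.index_of(name)
            rho = np.corrcoef(ours.data[i], theirs[i])[0, 1]
            assert rho > 0.99


class TestArtifactRemoval:
    @pytest.fixture()
    def blinky_recording(self, montage64):
        from fceeg.simulate import ArtifactRates, SimulationConfig

        cfg = SimulationConfig(
            n_patients=2, n_controls=2, seed=2,
            task_schedule=(("resting", 20.0),),
            artifact_rates=ArtifactRates(0.0, 0.0, 12.0),
        )
        rng = np.random.default_rng(42)
        return generate_recording(cfg, "control", "resting", 20.0, rng)

    def test_blink_variance_reduced_at_frontal_channels(self, blinky_recording):
        rec = blinky_recording
        ref = blink_reference(rec)
        assert np.any(ref)
        cleaned, frac = remove_artifact_components(rec, ref, seed=1)
        i = rec.index_of("Fp1")
        # oracle: variance of the known injected blink signal at Fp1
        resid_before = rec.data[i] - (rec.data[i] - ref)  # = ref at Fp1 weight 1
        blink_var_before = np.var(resid_before)
        leftover = cleaned.data[i] - (rec.data[i] - ref)
        assert np.var(leftover) < 0.3 * blink_var_before
        assert 0 < frac <= 1

    def test_uncorrelated_reference_removes_nothing(self, blinky_recording, rng):
        ref = rng.standard_normal(blinky_recording.n_samples)
        cleaned, frac = remove_artifact_components(blinky_recording, ref, seed=1)
        assert frac == 0.0
        np.testing.assert_array_equal(cleaned.data, blinky_recording.data)

    def test_threshold_bound(self, blinky_recording):
        ref = blink_reference(blinky_recording)
        with pytest.raises(ParameterError):
            remove_artifact_components(blinky_recording, ref, threshold=1.0 + 1e-9)

    def test_reference_length_mismatch(self, blinky_recording):
        with pytest.raises(InputError):
            remove_artifact_components(blinky_recording, np.zeros(10))


class TestQC:
    def test_bad_channel_percentage(self, rng):
        rec = make_recording(rng.standard_normal((64, 1000)))
        rep = qc_report(rec, n_bad_channels=4, flat_channel_seconds=0.0,
                        artifact_fraction=0.0)
        assert rep.pct_bad_channels == pytest.approx(6.25)

    def test_bad_segment_per_channel_time_convention(self, rng):
        # one 6 s flat window in one of 64 channels of a 600 s recording
        fs = 50.0
        data = rng.standard_normal((64, int(600 * fs))) + 2.0
        data[10, 1000:1000 + int(6 * fs)] = 0.0
        rec = make_recording(data, fs=fs)
        flat = per_channel_flat_duration(rec)
        rep = qc_report(rec, n_bad_channels=0, flat_channel_seconds=flat,
                        artifact_fraction=0.0)
        assert rep.pct_bad_segments == pytest.approx(0.015625, rel=1e-6)

    def test_zero_artifacts_is_zero_percent(self, rng):
        rec = make_recording(rng.standard_normal((4, 100)))
        rep = qc_report(rec, n_bad_channels=0, flat_channel_seconds=0.0,
                        artifact_fraction=0.0)
        assert rep.pct_artifacts_removed == 0.0

    def test_summary_aggregates_mean_and_sd(self, rng):
        rec = make_recording(rng.standard_normal((64, 1000)))
        reps = [
            qc_report(rec, n_bad_channels=k, flat_channel_seconds=0.0,
                      artifact_fraction=0.0, subject_id=f"S{k}")
            for k in (0, 4, 8)
        ]
        table, agg = qc_summary(reps)
        mean, sd = agg["pct_bad_channels"]
        assert mean == pytest.approx(100 * 4 / 64)
        assert sd == pytest.approx(np.std([0, 6.25, 12.5], ddof=1))

    def test_percentages_invariant_to_channel_order(self, rng):
        data = rng.standard_normal((4, 1000)) + 2.0
        data[2, :300] = 0.0
        rec1 = make_recording(data)
        perm = [3, 1, 0, 2]
        rec2 = make_recording(data[perm], names=[f"ch{i}" for i in perm])
        assert (per_channel_flat_duration(rec1)
                == per_channel_flat_duration(rec2))
        assert detect_bad_channels(rec1) == detect_bad_channels(rec2)


class TestCropResting:
    def test_long_recording_cropped_to_two_minutes(self, rng):
        rec = make_recording(rng.standard_normal((2, 250 * 420)))
        out = crop_resting(rec)
        assert out.n_samples == 250 * 120

    def test_exact_length_unchanged(self, rng):
        rec = make_recording(rng.standard_normal((2, 250 * 120)))
        assert crop_resting(rec).n_samples == rec.n_samples

    def test_short_recording_warns_and_keeps_all(self, rng):
        rec = make_recording(rng.standard_normal((2, 250 * 90)))
        with pytest.warns(UserWarning, match="shorter"):
            out = crop_resting(rec)
        assert out.n_samples == 250 * 90


def test_full_preprocess_flags_and_repairs(montage64, rng):
    data = rng.standard_normal((64, 250 * 20)) * 10
    data[5] = 0.0  # flat channel
    data[20, 1000:1500] = 0.0  # 2 s flat segment
    rec = Recording(data=data, sampling_rate=250.0,
                    channel_names=list(montage64.names))
    out, report = preprocess_recording(rec, montage64)
    flat_name = montage64.names[5]
    assert flat_name in out.bad_channels
    assert not np.allclose(out.data[5], 0.0)  # interpolated
    assert len(out.bad_segments) == 1
    assert report.pct_bad_channels == pytest.approx(100 / 64)
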