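import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import semgkit as sk
from semgkit.errors import ConfigError, NoOnsetError, SegmentError


class TestDenoise:
    def test_power_line_tone_suppressed(self):
        # oracle: RMS of a pure 50 Hz tone before/after the notch chain
        fs = 2000.0
        t = np.arange(20000) / fs
        rec = sk.Recording(np.sin(2 * np.pi * 50 * t)[None, :], fs=fs)
        out = sk.denoise(rec)
        rms_in = np.sqrt(np.mean(rec.data**2))
        rms_out = np.sqrt(np.mean(out.data**2))
        assert rms_out <= 0.05 * rms_in

    def test_zero_signal_stays_zero(self):
        rec = sk.Recording(np.zeros((2, 4000)), fs=2000.0)
        assert np.abs(sk.denoise(rec).data).max() == 0.0

    def test_dc_offset_removed(self, rng):
        x = 1e-3 * rng.standard_normal((3, 8000)) + 1.0
        out = sk.denoise(sk.Recording(x, fs=2000.0))
        assert np.abs(out.data.mean(axis=1)).max() <= 0.01

    def test_sampling_rate_too_low_for_corners(self):
        rec = sk.Recording(np.zeros((1, 1000)), fs=15.0)
        with pytest.raises(ConfigError):
            sk.denoise(rec)


class TestFraming:
    @pytest.mark.parametrize(
        "N,L,I,M",
        [
            (20000, 64, 32, 624),  # the protocol trial length
            (64, 64, 32, 1),
            (95, 64, 32, 1),  # samples 65-95 dropped
            (4000, 64, 32, 124),
        ],
    )
    def test_frame_counts(self, N, L, I, M):
        spec = sk.FrameSpec(L=L, I=I)
        frames = sk.frame_signal(np.arange(N, dtype=float), spec)
        assert frames.shape == (M, L)

    def test_frame_contents_match_manual_slices(self, rng):
        x = rng.standard_normal(500)
        spec = sk.FrameSpec(L=64, I=32)
        frames = sk.frame_signal(x, spec)
        for i, frame in enumerate(frames):
            np.testing.assert_array_equal(frame, x[i * 32 : i * 32 + 64])

    def test_signal_shorter_than_frame_rejected(self):
        with pytest.raises(SegmentError):
            sk.frame_signal(np.zeros(10), sk.FrameSpec(L=64, I=32))

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.data())
    def test_frame_count_brackets_signal_length(self, data):
        # (M-1)*I + L <= N < M*I + L for every valid geometry
        L = data.draw(st.integers(1, 256))
        I = data.draw(st.integers(1, L))
        N = data.draw(st.integers(L, 5000))
        M = sk.FrameSpec(L=L, I=I).frame_count(N)
        assert (M - 1) * I + L <= N < M * I + L


class TestFrameEnergy:
    def test_hand_examples(self):
        assert sk.frame_energy(np.full((1, 64), 2.0))[0] == pytest.approx(256.0)
        assert sk.frame_energy(np.zeros((1, 64)))[0] == 0.0
        assert sk.frame_energy(np.array([[1.0, 2.0, 3.0]]))[0] == pytest.approx(14.0)

    def test_matches_bruteforce_loop(self, rng):
        frames = rng.standard_normal((50, 64))
        expected = np.array([sum(v * v for v in frame) for frame in frames])
        np.testing.assert_allclose(sk.frame_energy(frames), expected, rtol=0, atol=1e-12)


class TestAdaptiveThreshold:
    def test_mean_of_rest_energies(self, rng):
        assert sk.adaptive_threshold(np.array([1.0, 2.0, 3.0])) == pytest.approx(2.0)
        e = 5 + rng.standard_normal(1000)
        assert sk.adaptive_threshold(e) == pytest.approx(e.sum() / len(e), abs=1e-12)

    def test_empty_series_rejected(self):
        with pytest.raises(SegmentError):
            sk.adaptive_threshold(np.array([]))


class TestDetectOnset:
    def test_first_qualifying_run(self):
        p = sk.EnergyProfile(np.array([0, 0, 5, 5, 5, 5, 5.0]), threshold=1.0)
        assert sk.detect_onset(p) == 3

    def test_short_run_does_not_qualify(self):
        p = sk.EnergyProfile(np.array([0, 5, 5, 0, 5, 5, 5, 5.0]), threshold=1.0)
        assert sk.detect_onset(p) == 5

    def test_three_in_a_row_variant(self):
        p = sk.EnergyProfile(np.array([0, 5, 5, 5, 0, 0, 0, 0.0]), threshold=1.0)
        assert sk.detect_onset(p, onset_run_length=3) == 2
        with pytest.raises(NoOnsetError):
            sk.detect_onset(p, onset_run_length=4)

    def test_no_onset_signalled_distinctly(self):
        p = sk.EnergyProfile(np.full(10, 0.5), threshold=1.0)
        with pytest.raises(NoOnsetError):
            sk.detect_onset(p)


class TestMainSegment:
    def test_bounds_formula(self):
        rec = sk.Recording(np.arange(8 * 20000, dtype=float).reshape(8, 20000), fs=2000.0)
        seg, b = sk.extract_main_segment(rec, FS=1, spec=sk.FrameSpec())
        assert (b.SN, b.MSN, b.MEN) == (1, 1001, 5001)
        assert seg.n_samples == 4000
        # 1-based samples MSN..MEN-1 == 0-based MSN-1..MEN-2
        np.testing.assert_array_equal(seg.data, rec.data[:, 1000:5000])

    def test_boundary_segment_ending_at_trial_end(self):
        # MEN == N succeeds; one sample shorter fails
        seg, b = sk.extract_main_segment(
            sk.Recording(np.zeros((1, 5001)), fs=2000.0), FS=1, spec=sk.FrameSpec()
        )
        assert b.MEN == 5001 and seg.n_samples == 4000
        with pytest.raises(SegmentError):
            sk.extract_main_segment(
                sk.Recording(np.zeros((1, 5000)), fs=2000.0), FS=1, spec=sk.FrameSpec()
            )

    def test_segment_length_always_two_seconds(self):
        fs = 2000.0
        for FS in (1, 10, 100):
            rec = sk.Recording(np.zeros((2, 20000)), fs=fs)
            seg, _ = sk.extract_main_segment(rec, FS=FS, spec=sk.FrameSpec())
            assert seg.n_samples == int(2 * fs)

    def test_recording_too_short_after_onset(self):
        rec = sk.Recording(np.zeros((1, 6000)), fs=2000.0)
        with pytest.raises(SegmentError):
            sk.extract_main_segment(rec, FS=100, spec=sk.FrameSpec())


def test_onset_recovery_on_synthetic_trials(short_sim):
    # scaled-down version of the recovery property (full scale in acceptance)
    profile = short_sim["profiles"]["y1"]
    config = sk.SimConfig(duration=4.0)
    hits = 0
    for seed in range(20):
        rec, true_onset = sk.generate_recording(profile, config, seed)
        _, b = sk.segment_recording(sk.denoise(rec))
        hits += abs(b.SN - true_onset) <= 3 * 32
    assert hits >= 19
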