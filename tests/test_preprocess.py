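import numpy as np
import pytest

from scgdtw import (
    BeatSpec,
    Channel,
    SignalClip,
    condition_signal,
    detect_q_point,
    detect_r_peaks,
    generate_beat_pair,
    generate_recording,
    section_beat,
)
from scgdtw.preprocess import DetectionError


def make_clip(samples, fs=500.0, channel=Channel.ECG):
    return SignalClip("c", "s", channel, fs, np.asarray(samples, dtype=float))


class TestConditionSignal:
    def test_constant_becomes_zero(self):
        out = condition_signal(make_clip(np.full(2000, 3.7)))
        assert np.allclose(out.samples, 0.0, atol=1e-9)

    def test_output_zero_mean_same_shape(self):
        rng = np.random.default_rng(1)
        clip = make_clip(rng.normal(size=3000) + 5.0)
        out = condition_signal(clip)
        assert out.n_samples == clip.n_samples
        assert out.sampling_rate == clip.sampling_rate
        assert abs(out.samples.mean()) < 1e-9 * out.samples.std() + 1e-12

    def test_passband_sinusoid_barely_attenuated(self):
        # 5 Hz sits well inside the 0.5-40 Hz band; analytic |H(5)| ~ 1
        fs = 500.0
        t = np.arange(0, 8, 1 / fs)
        clip = make_clip(np.sin(2 * np.pi * 5 * t), fs)
        out = condition_signal(clip, 0.5, 40.0, level=0)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        ratio = out.samples[mid].std() / clip.samples[mid].std()
        assert abs(ratio - 1.0) < 0.05

    def test_wavelet_stage_removes_noise_energy(self):
        rng = np.random.default_rng(2)
        clip = make_clip(rng.normal(size=4000))
        var_on = condition_signal(clip, level=4).samples.var()
        var_off = condition_signal(clip, level=0).samples.var()
        assert var_on < var_off

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            condition_signal(make_clip(np.zeros(100), fs=100.0), 1.0, 60.0)

    def test_conditioning_roughly_idempotent(self):
        # The 0.5 Hz high-pass edge transient spans beat-length clips, so
        # a second pass changes the signal by a few percent, not less.
        ecg, _, _, _ = generate_beat_pair(BeatSpec())
        c1 = condition_signal(ecg)
        c2 = condition_signal(c1)
        rel = np.linalg.norm(c2.samples - c1.samples) / np.linalg.norm(c1.samples)
        assert rel < 0.08


class TestRPeakDetection:
    def test_peaks_within_5ms_of_truth(self):
        ecg, _, ann, _ = generate_beat_pair(BeatSpec(rr_ms=966.0))
        det = detect_r_peaks(ecg)
        assert len(det.r_peaks) == len(ann.r_peaks)
        for got, want in zip(det.r_peaks, ann.r_peaks):
            assert abs(got - want) / ecg.sampling_rate * 1000.0 <= 5.0

    def test_two_beat_rr_interval_966(self):
        ecg, _, _, _ = generate_beat_pair(BeatSpec(rr_ms=966.0))
        det = detect_r_peaks(ecg)
        assert det.rr_interval_ms == pytest.approx(966.0, abs=2.0)

    def test_flat_signal_fails(self):
        with pytest.raises(DetectionError):
            detect_r_peaks(make_clip(np.zeros(1000)))

    def test_perfect_sensitivity_and_precision_at_10db(self):
        """Every true R found and nothing spurious, over 50 seeded noisy trials."""
        rng = np.random.default_rng(99)
        for trial in range(50):
            rrs = list(rng.uniform(800.0, 1100.0, size=3))
            base = BeatSpec(noise_snr_db=10.0, seed=int(rng.integers(2**31)))
            ecg, _, ann, _ = generate_recording(rrs, base=base, seed=base.seed)
            det = detect_r_peaks(ecg)
            truth = np.asarray(ann.r_peaks)
            got = np.asarray(det.r_peaks)
            tol = int(0.05 * ecg.sampling_rate)  # 50 ms matching window
            matched = sum(np.any(np.abs(truth - g) <= tol) for g in got)
            assert matched == len(truth) == len(got), f"trial {trial}"


class TestQPointDetection:
    def test_within_5ms_of_generator_truth(self, clean_beat):
        ecg, _, ann, truth = clean_beat
        q = detect_q_point(ecg, ann.r_peaks[0])
        assert abs(ecg.index_to_ms(q) - truth.times["Q"]) <= 5.0

    def test_monotone_ramp_gives_window_start(self):
        fs = 1000.0
        clip = make_clip(np.linspace(0, 1, 500), fs)
        assert detect_q_point(clip, 400) == 400 - 80

    def test_window_beyond_clip_start(self):
        clip = make_clip(np.zeros(100), fs=1000.0)
        with pytest.raises(IndexError):
            detect_q_point(clip, 3)


class TestSectionBeat:
    @pytest.fixture
    def recording(self):
        return generate_recording([900.0, 966.0, 1003.0, 950.0, 1000.0], seed=11)

    def test_central_beat_window_duration(self, recording):
        ecg, scg, ann, _ = recording
        e, s = section_beat(ecg, scg, ann, 2)
        expect = 1003.0 + 2 * 300.0  # central RR plus both margins
        assert e.duration_ms == pytest.approx(expect, abs=1.0)

    def test_outputs_cover_identical_window(self, recording):
        ecg, scg, ann, _ = recording
        e, s = section_beat(ecg, scg, ann, 1)
        assert e.n_samples == s.n_samples
        assert e.t0_offset == s.t0_offset
        assert e.sampling_rate == s.sampling_rate

    def test_edge_beat_without_margin_fails(self):
        ecg, scg, ann, _ = generate_recording([966.0, 966.0], seed=1)
        # strip the lead-in so beat 0 has no room for its left margin
        cut = slice(ann.r_peaks[0] - 10, None)
        ecg2 = SignalClip("e", "s", Channel.ECG, ecg.sampling_rate, ecg.samples[cut])
        scg2 = SignalClip("g", "s", Channel.SCG, scg.sampling_rate, scg.samples[cut])
        from scgdtw import BeatAnnotation

        ann2 = BeatAnnotation("e", [p - (ann.r_peaks[0] - 10) for p in ann.r_peaks])
        with pytest.raises(IndexError):
            section_beat(ecg2, scg2, ann2, 0)
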