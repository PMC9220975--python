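import numpy as np
import pytest

from scgdtw import (
    BeatAnnotation,
    BeatSpec,
    EchoAnnotation,
    FiducialSet,
    Provenance,
    conventional_align,
    detection_error,
    generate_beat_pair,
    map_echo_to_reference,
    project_fiducials,
    select_reference,
)
from scgdtw.align import RRMismatchError
from scgdtw.experiments import run_method_comparison, run_projection_recovery
from scgdtw.types import Modality


def beat_with_rr(rr):
    ecg, scg, ann, truth = generate_beat_pair(BeatSpec(rr_ms=rr))
    return ecg, scg, ann


class TestSelectReference:
    def test_closest_rr_wins_with_zero_residual(self):
        clips = [beat_with_rr(rr) for rr in (950.0, 966.0, 1003.0)]
        (_, _, ann), idx, residual = select_reference(clips, 966.0)
        assert idx == 1
        assert ann.rr_interval_ms == pytest.approx(966.0)
        assert residual == 0.0

    def test_single_candidate_always_selected(self):
        clips = [beat_with_rr(850.0)]
        _, idx, residual = select_reference(clips, 1100.0)
        assert idx == 0
        assert residual == pytest.approx(250.0)

    def test_tie_resolves_to_earliest(self):
        clips = [beat_with_rr(950.0), beat_with_rr(982.0)]
        _, idx, _ = select_reference(clips, 966.0)
        assert idx == 0

    def test_empty_candidate_set(self):
        with pytest.raises(ValueError):
            select_reference([], 966.0)


def make_ref_annotation(rr=966.0, r0=300, fs=1000.0):
    return BeatAnnotation(
        "ref", r_peaks=[r0, r0 + int(rr)], rr_interval_ms=rr, sampling_rate=fs
    )


def make_echo(rr=966.0, r1=100.0, **events):
    return EchoAnnotation(
        "img", "s", Modality.COLOR_DOPPLER, r1, r1 + rr, events=events
    )


class TestMapEchoToReference:
    def test_pure_shift(self):
        echo = make_echo(AC=500.0)  # 400 ms after R1
        fid = map_echo_to_reference(echo, make_ref_annotation())
        assert fid.times["AC"] == pytest.approx(300.0 + 400.0)
        assert fid.provenance == Provenance.ECHO_MAPPED

    def test_event_at_r1_maps_to_r_peak(self):
        echo = make_echo(MC=100.0)
        fid = map_echo_to_reference(echo, make_ref_annotation())
        assert fid.times["MC"] == pytest.approx(300.0)

    def test_rr_mismatch_beyond_tolerance_refused(self):
        echo = make_echo(rr=966.0, AC=500.0)
        with pytest.raises(RRMismatchError) as exc:
            map_echo_to_reference(echo, make_ref_annotation(rr=1003.0))
        assert exc.value.mismatch_fraction == pytest.approx(37.0 / 966.0, abs=1e-6)


class TestConventionalAlign:
    @pytest.fixture
    def clip_and_fid(self):
        _, scg, _, truth = generate_beat_pair(BeatSpec(rr_ms=1003.0))
        return scg, truth

    def test_squeeze_ratio_1003_to_966(self, clip_and_fid):
        scg, truth = clip_and_fid
        _, mapped = conventional_align(scg, 1003.0, 966.0, truth, r_peak_ms=300.0)
        # fiducial 600 ms after the R peak moves to 600 * 966/1003 = 577.9 ms
        fid600 = FiducialSet("c", {"MO": 900.0}, Provenance.GROUND_TRUTH)
        _, m600 = conventional_align(scg, 1003.0, 966.0, fid600, r_peak_ms=300.0)
        assert m600.times["MO"] - 300.0 == pytest.approx(577.9, abs=0.05)

    def test_unit_ratio_is_identity(self, clip_and_fid):
        scg, truth = clip_and_fid
        rescaled, mapped = conventional_align(scg, 966.0, 966.0, truth, r_peak_ms=300.0)
        assert mapped.times == truth.times
        assert np.allclose(rescaled.samples, scg.samples, atol=1e-9)

    def test_rescale_round_trip_restores_times(self, clip_and_fid):
        scg, truth = clip_and_fid
        down, mapped = conventional_align(scg, 1003.0, 966.0, truth, r_peak_ms=300.0)
        _, back = conventional_align(down, 966.0, 1003.0, mapped, r_peak_ms=300.0)
        for lab, t in truth.times.items():
            assert back.times[lab] == pytest.approx(t, abs=1e-9)

    def test_nonpositive_rr_rejected(self, clip_and_fid):
        scg, truth = clip_and_fid
        with pytest.raises(ValueError):
            conventional_align(scg, 0.0, 966.0, truth)


class TestDetectionError:
    def test_identical_sets_zero(self):
        f = FiducialSet("c", {"AO": 100.0, "AC": 400.0}, Provenance.GROUND_TRUTH)
        res = detection_error(f, f)
        assert all(v == 0.0 for v in res.errors_ms.values())
        assert res.mean_abs_ms == 0.0

    def test_disjoint_sets_warn_empty(self):
        a = FiducialSet("c", {"AO": 100.0}, Provenance.GROUND_TRUTH)
        b = FiducialSet("c", {"MC": 50.0}, Provenance.GROUND_TRUTH)
        with pytest.warns(UserWarning):
            res = detection_error(a, b)
        assert res.errors_ms == {}

    def test_uniform_rescale_drifts_late_events_more(self):
        # diastole-lengthened pair: conventional AC error exceeds MC error
        res = run_method_comparison(n_pairs=5, seed=7)
        assert res.mean_abs("conventional", "AC") > res.mean_abs("conventional", "MC")


class TestProjection:
    def test_identity_projection_within_half_sample(self, clean_beat):
        _, scg, _, truth = clean_beat
        fid, _ = project_fiducials(scg, truth, scg)
        for lab, t in truth.times.items():
            # half a sample at the 500 Hz projection rate is 1 ms
            assert abs(fid.times[lab] - t) <= 1.0 + 1e-9

    def test_fiducial_outside_reference_rejected(self, clean_beat):
        _, scg, _, _ = clean_beat
        bad = FiducialSet("c", {"AO": scg.duration_ms + 100.0}, Provenance.ECHO_MAPPED)
        with pytest.raises(ValueError):
            project_fiducials(scg, bad, scg)

    def test_warped_noisy_recovery_within_10ms(self):
        res = run_projection_recovery(n_trials=25, snr_db=20.0, seed=5)
        assert res.fraction_within >= 0.95

    def test_dtw_beats_conventional_on_diastolic_variation(self):
        res = run_method_comparison(n_pairs=25, seed=3)
        assert res.mean_abs("dtw") < res.mean_abs("conventional")
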