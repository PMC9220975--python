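"""Quasi-synchronous alignment: reference selection, echo mapping, and
fiducial projection.

The protocol avoids the uniform-rescale distortion of conventional
quasi-synchronous alignment in two steps:

1. pick, from the beat library, the **reference** ECG/SCG pair whose RR
   interval best matches the RR selected on the echocardiogram, so the echo
   events transfer by a pure time shift (no rescaling);
2. **project** the reference fiducials onto every other (non-reference) SCG
   beat along a DTW warping path, which absorbs beat-length differences
   where they occur instead of smearing them over the whole cycle.

The conventional shift-plus-uniform-rescale alignment is implemented as the
baseline, together with a signed detection-error comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dtw import DtwConfig, WarpPath, dtw_align
from .preprocess import detect_q_point
from .types import (
    BeatAnnotation,
    EchoAnnotation,
    FiducialSet,
    Provenance,
    SignalClip,
)

__all__ = [
    "RRMismatchError",
    "ErrorSummary",
    "select_reference",
    "map_echo_to_reference",
    "project_fiducials",
    "add_q_from_ecg",
    "conventional_align",
    "detection_error",
]

#: Common sampling rate (Hz) both clips are resampled to before DTW; bounds
#: the cost-matrix size while keeping 2 ms resolution.
DEFAULT_COMMON_RATE = 500.0


class RRMismatchError(ValueError):
    """Reference RR differs from the echo RR beyond the shift-only tolerance."""

    def __init__(self, mismatch_fraction: float, tolerance: float):
        self.mismatch_fraction = mismatch_fraction
        self.tolerance = tolerance
        super().__init__(
            f"RR mismatch {mismatch_fraction:.1%} exceeds the {tolerance:.1%} "
            "tolerance for shift-only alignment; pick a closer reference beat"
        )


def select_reference(
    clips: Sequence[tuple[SignalClip, SignalClip, BeatAnnotation]],
    target_rr_ms: float,
) -> tuple[tuple[SignalClip, SignalClip, BeatAnnotation], int, float]:
    """The candidate beat whose RR interval is closest to ``target_rr_ms``.

    Returns ``(candidate, index, residual_ms)``; ties resolve to the
    earliest candidate in input order.
    """
    if not clips:
        raise ValueError("empty candidate set")
    residuals = []
    for _, _, ann in clips:
        if ann.rr_interval_ms is None:
            raise ValueError(f"candidate {ann.clip_id} lacks rr_interval_ms")
        residuals.append(abs(ann.rr_interval_ms - target_rr_ms))
    idx = int(np.argmin(residuals))  # argmin takes the first of equal minima
    return clips[idx], idx, float(residuals[idx])


def map_echo_to_reference(
    echo: EchoAnnotation,
    ref_annotation: BeatAnnotation,
    rr_tolerance: float = 0.02,
) -> FiducialSet:
    """Shift (never rescale) echo valve events onto the reference clip.

    The echo's R1 is identified with the left R peak of the reference
    clip's central beat; each event time ``t`` maps to
    ``r_peak_time + (t - r1)``.  Refuses when the RR intervals disagree by
    more than ``rr_tolerance`` (fractional), since the shift-only premise
    rests on matching cycle lengths.
    """
    if ref_annotation.sampling_rate is None or ref_annotation.rr_interval_ms is None:
        raise ValueError("reference annotation needs sampling_rate and rr_interval_ms")
    mismatch = abs(ref_annotation.rr_interval_ms - echo.rr_interval_ms) / echo.rr_interval_ms
    if mismatch > rr_tolerance:
        raise RRMismatchError(mismatch, rr_tolerance)
    i = ref_annotation.central_beat_index()
    r_ms = ref_annotation.r_peaks[i] / ref_annotation.sampling_rate * 1000.0
    times = {lab: r_ms + (t - echo.r1_ms) for lab, t in echo.events.items()}
    return FiducialSet(
        clip_id=ref_annotation.clip_id,
        times=times,
        provenance=Provenance.ECHO_MAPPED,
    )


def _resample_linear(clip: SignalClip, rate: float) -> np.ndarray:
    t = clip.times_ms()
    n = int(np.floor(t[-1] * rate / 1000.0)) + 1
    t_new = np.arange(n) / rate * 1000.0
    return np.interp(t_new, t, clip.samples)


def project_fiducials(
    ref_scg: SignalClip,
    ref_fiducials: FiducialSet,
    target_scg: SignalClip,
    config: DtwConfig | None = None,
    common_rate: float = DEFAULT_COMMON_RATE,
) -> tuple[FiducialSet, WarpPath]:
    """Carry reference fiducials onto a non-reference SCG beat via DTW.

    Both clips are resampled to ``common_rate``; the warping path is
    computed under the hybrid cost; each event's reference sample index is
    looked up on the path and the **median** matched target index (a
    one-to-many match is possible) becomes the event time on the target.

    Returns the projected fiducial set and the warp path.  A projection
    that breaks the physiological ordering is returned with a warning, so
    the caller can reject the beat.
    """
    # Derivatives enter the cost in per-sample units (config.sampling_rate
    # stays 1): per-second units at 500 Hz would scale the slope and
    # concavity terms by fs^2 and fs^4, drowning the value term and
    # amplifying high-frequency noise.
    config = config or DtwConfig()
    x = _resample_linear(ref_scg, common_rate)
    y = _resample_linear(target_scg, common_rate)
    path = dtw_align(x, y, config)
    times = {}
    for lab, t_ms in ref_fiducials.times.items():
        a_star = int(round(t_ms * common_rate / 1000.0))
        if not 0 <= a_star < len(x):
            raise ValueError(
                f"fiducial {lab} at {t_ms} ms lies outside the reference clip"
            )
        matched = path.target_indices(a_star)
        b = float(np.median(matched))
        times[lab] = b / common_rate * 1000.0
    out = FiducialSet(
        clip_id=target_scg.clip_id,
        times=times,
        provenance=Provenance.DTW_PROJECTED,
    )
    if not out.is_ordered():
        warnings.warn(
            f"projected fiducials on {target_scg.clip_id} violate the "
            f"physiological ordering: {out.ordering_violations()}",
            stacklevel=2,
        )
    return out, path


def add_q_from_ecg(
    fiducials: FiducialSet,
    ecg: SignalClip,
    annotation: BeatAnnotation,
) -> FiducialSet:
    """Attach the ECG-derived Q time to a valve-event fiducial set.

    Q is not an echo event; it comes from the simultaneously measured ECG of
    the same beat (the central beat's R peak).
    """
    i = annotation.central_beat_index()
    q_idx = detect_q_point(ecg, annotation.r_peaks[i])
    times = dict(fiducials.times)
    times["Q"] = ecg.index_to_ms(q_idx)
    return FiducialSet(fiducials.clip_id, times, fiducials.provenance)


def conventional_align(
    signal: SignalClip,
    source_rr_ms: float,
    target_rr_ms: float,
    fiducials: FiducialSet,
    r_peak_ms: float = 0.0,
) -> tuple[SignalClip, FiducialSet]:
    """Baseline shift-plus-uniform-rescale alignment.

    The time axis is scaled by ``target_rr / source_rr`` about the left R
    peak (``r_peak_ms``, clip-relative); every fiducial time moves to
    ``r + (t - r) * ratio`` and the samples are linearly re-interpolated on
    the rescaled grid.  This is the operation whose distortion the DTW
    protocol eliminates.
    """
    if source_rr_ms <= 0 or target_rr_ms <= 0:
        raise ValueError("RR intervals must be positive")
    ratio = target_rr_ms / source_rr_ms
    fs = signal.sampling_rate
    t_old = signal.times_ms()
    dur_new = r_peak_ms + (t_old[-1] - r_peak_ms) * ratio
    n_new = int(round(dur_new * fs / 1000.0)) + 1
    t_new = np.arange(n_new) / fs * 1000.0
    samples = np.interp(r_peak_ms + (t_new - r_peak_ms) / ratio, t_old, signal.samples)
    rescaled = SignalClip(
        clip_id=f"{signal.clip_id}/rescaled",
        subject_id=signal.subject_id,
        channel=signal.channel,
        sampling_rate=fs,
        samples=samples,
        t0_offset=signal.t0_offset,
    )
    mapped = FiducialSet(
        clip_id=rescaled.clip_id,
        times={lab: r_peak_ms + (t - r_peak_ms) * ratio for lab, t in fiducials.times.items()},
        provenance=Provenance.CONVENTIONAL,
    )
    return rescaled, mapped


@dataclass(frozen=True)
class ErrorSummary:
    """Signed per-event detection errors (candidate minus truth), ms."""

    errors_ms: Mapping[str, float]
    mean_abs_ms: float
    max_abs_ms: float


def detection_error(candidate: FiducialSet, truth: FiducialSet) -> ErrorSummary:
    """Per-event signed timing error of ``candidate`` against ``truth``."""
    shared = [e for e in truth.times if e in candidate.times]
    if not shared:
        warnings.warn("candidate and truth share no events", stacklevel=2)
        return ErrorSummary(errors_ms={}, mean_abs_ms=float("nan"), max_abs_ms=float("nan"))
    errors = {e: candidate.times[e] - truth.times[e] for e in shared}
    abs_vals = [abs(v) for v in errors.values()]
    return ErrorSummary(
        errors_ms=errors,
        mean_abs_ms=float(np.mean(abs_vals)),
        max_abs_ms=float(max(abs_vals)),
    )
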