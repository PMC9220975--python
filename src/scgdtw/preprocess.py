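"""Signal conditioning and beat segmentation.

The conditioning chain is linear detrend -> zero-phase Butterworth band-pass
-> wavelet shrinkage (Daubechies-4, soft universal threshold), the standard
recipe for ECG/SCG denoising.  R peaks are found Pan-Tompkins style
(band-pass, differentiate, square, moving-window integrate, adaptive
threshold) and refined to the local signal maximum.  Beat sectioning cuts a
window around the central RR interval with fixed margins standing in for the
T-wave bounds T0/T2, since T-wave delineation is outside this package's
scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .types import BeatAnnotation, Channel, SignalClip

__all__ = [
    "PreprocessConfig",
    "DetectionError",
    "condition_signal",
    "detect_r_peaks",
    "detect_q_point",
    "section_beat",
]


class DetectionError(RuntimeError):
    """No landmark satisfied the detector's criteria."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Conditioning and detection parameters.

    Band edges in Hz; ``wavelet_level = 0`` disables the shrinkage stage.
    ``refractory_ms`` is the minimum R-R separation enforced by the peak
    detector; ``q_window_ms`` bounds the Q search before each R peak
    (physiological QR duration); ``margin_ms`` is the sectioning margin
    either side of the central RR interval.
    """

    ecg_band: tuple[float, float] = (0.5, 40.0)
    scg_band: tuple[float, float] = (1.0, 45.0)
    filter_order: int = 4
    wavelet: str = "db4"
    wavelet_level: int = 4
    refractory_ms: float = 250.0
    q_window_ms: float = 80.0
    margin_ms: float = 300.0


def condition_signal(
    clip: SignalClip,
    band_low: float | None = None,
    band_high: float | None = None,
    wavelet_name: str = "db4",
    level: int = 4,
    order: int = 4,
) -> SignalClip:
    """Detrend, band-pass filter, and wavelet-denoise a clip.

    Band defaults depend on the channel (ECG 0.5-40 Hz, SCG 1-45 Hz).
    Output has the same length and rate as the input and zero mean.
    """
    if band_low is None or band_high is None:
        lo, hi = (0.5, 40.0) if clip.channel == Channel.ECG else (1.0, 45.0)
        band_low = lo if band_low is None else band_low
        band_high = hi if band_high is None else band_high
    nyq = clip.sampling_rate / 2.0
    if not (0 <= band_low < band_high < nyq):
        raise ValueError(
            f"band ({band_low}, {band_high}) Hz invalid for Nyquist {nyq} Hz"
        )
    x = sps.detrend(clip.samples, type="linear")
    if band_low > 0:
        sos = sps.butter(order, [band_low, band_high], btype="bandpass", fs=clip.sampling_rate, output="sos")
    else:
        sos = sps.butter(order, band_high, btype="lowpass", fs=clip.sampling_rate, output="sos")
    x = sps.sosfiltfilt(sos, x)
    if level > 0:
        x = _wavelet_shrink(x, wavelet_name, level)
    x = x - x.mean()
    return SignalClip(
        clip_id=clip.clip_id,
        subject_id=clip.subject_id,
        channel=clip.channel,
        sampling_rate=clip.sampling_rate,
        samples=x,
        t0_offset=clip.t0_offset,
    )


def _wavelet_shrink(x: np.ndarray, wavelet: str, level: int) -> np.ndarray:
    """Soft universal-threshold shrinkage of the detail coefficients."""
    level = min(level, pywt.dwt_max_level(len(x), pywt.Wavelet(wavelet).dec_len))
    if level < 1:
        return x
    coeffs = pywt.wavedec(x, wavelet, level=level)
    # noise scale from the finest details (robust MAD estimate)
    sigma = np.median(np.abs(coeffs[-1])) / 0.6745 if len(coeffs[-1]) else 0.0
    thr = sigma * np.sqrt(2.0 * np.log(max(len(x), 2)))
    coeffs = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]]
    return pywt.waverec(coeffs, wavelet)[: len(x)]


def detect_r_peaks(ecg: SignalClip, config: PreprocessConfig | None = None) -> BeatAnnotation:
    """Locate ECG R peaks with a Pan-Tompkins-style energy detector.

    Returns a :class:`BeatAnnotation` whose ``rr_interval_ms`` describes the
    central beat when at least two peaks are found.

    Raises
    ------
    DetectionError
        If no sample crosses the adaptive threshold.
    """
    config = config or PreprocessConfig()
    fs = ecg.sampling_rate
    x = np.asarray(ecg.samples, dtype=float)
    if np.ptp(x) == 0:
        raise DetectionError("flat signal: no R peaks")
    # QRS emphasis band
    sos = sps.butter(2, [5.0, min(15.0, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
    e = sps.sosfiltfilt(sos, x)
    e = np.gradient(e) ** 2
    win = max(1, int(round(0.150 * fs)))
    e = np.convolve(e, np.ones(win) / win, mode="same")
    threshold = 0.3 * e.max()
    if threshold <= 0:
        raise DetectionError("no energy above adaptive threshold")
    distance = max(1, int(round(config.refractory_ms * fs / 1000.0)))
    peaks, _ = sps.find_peaks(e, height=threshold, distance=distance)
    if peaks.size == 0:
        raise DetectionError("no peak above adaptive threshold")
    # refine each detection to the local maximum of the raw ECG
    half = max(1, int(round(0.05 * fs)))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    r_peaks = sorted(set(refined))
    rr = None
    if len(r_peaks) >= 2:
        ann_tmp = BeatAnnotation(clip_id=ecg.clip_id, r_peaks=r_peaks)
        i = ann_tmp.central_beat_index()
        rr = (r_peaks[i + 1] - r_peaks[i]) / fs * 1000.0
    return BeatAnnotation(
        clip_id=ecg.clip_id,
        r_peaks=r_peaks,
        rr_interval_ms=rr,
        sampling_rate=fs,
    )


def detect_q_point(
    ecg: SignalClip, r_index: int, config: PreprocessConfig | None = None
) -> int:
    """Index of the Q point: the minimum in the window before an R peak.

    Searches ``[r_index - q_window_ms, r_index)``; raises if the window
    extends past the start of the clip.
    """
    config = config or PreprocessConfig()
    w = int(round(config.q_window_ms * ecg.sampling_rate / 1000.0))
    lo = r_index - w
    if lo < 0:
        raise IndexError(
            f"Q search window ({w} samples before index {r_index}) exceeds clip start"
        )
    if r_index <= lo:
        raise IndexError("empty Q search window")
    seg = ecg.samples[lo:r_index]
    return lo + int(np.argmin(seg))


def section_beat(
    ecg: SignalClip,
    scg: SignalClip,
    annotation: BeatAnnotation,
    beat_index: int,
    config: PreprocessConfig | None = None,
) -> tuple[SignalClip, SignalClip]:
    """Cut the ECG/SCG pair around one beat's central RR interval.

    The window is ``[R_i - margin, R_{i+1} + margin]``, a fixed-margin
    stand-in for T-wave bounds.  Both output clips cover the identical
    sample window; a beat whose margins run past the data raises IndexError.
    """
    config = config or PreprocessConfig()
    if ecg.sampling_rate != scg.sampling_rate:
        raise ValueError("ECG and SCG clips must share a sampling rate")
    if len(ecg.samples) != len(scg.samples):
        raise ValueError("ECG and SCG clips must have equal length")
    peaks = list(annotation.r_peaks)
    if not 0 <= beat_index < len(peaks) - 1:
        raise IndexError(f"beat_index {beat_index} out of range for {len(peaks)} R peaks")
    margin = int(round(config.margin_ms * ecg.sampling_rate / 1000.0))
    lo = peaks[beat_index] - margin
    hi = peaks[beat_index + 1] + margin + 1
    if lo < 0 or hi > len(ecg.samples):
        raise IndexError(
            f"beat {beat_index} with {config.margin_ms} ms margins exceeds the clip"
        )

    def cut(clip: SignalClip) -> SignalClip:
        return SignalClip(
            clip_id=f"{clip.clip_id}/beat{beat_index}",
            subject_id=clip.subject_id,
            channel=clip.channel,
            sampling_rate=clip.sampling_rate,
            samples=clip.samples[lo:hi].copy(),
            t0_offset=clip.t0_offset + clip.index_to_ms(lo),
        )

    return cut(ecg), cut(scg)
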