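"""Synthetic ECG/SCG generation with exact ground truth.

The generator emulates the features the alignment protocol depends on:

* ECG beats as sums of Gaussian P-QRS-T components with known Q and R times;
* SCG beats as Gaussian-windowed 20 Hz bursts centered at the valve events
  (MC, AO, AC, MO), with per-event amplitudes giving the characteristic
  peak/valley structure;
* beat-length variability confined to the diastolic (late) portion of the
  cycle — the early, systolic portion keeps a fixed pace, so RR differences
  between beats move late events little and early events not at all;
* smooth monotone piecewise-linear time warps with exact fiducial mapping;
* additive white Gaussian noise at a prescribed SNR;
* cohort tables generated under a known linear LVEF-index law.

All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .types import (
    BeatAnnotation,
    Channel,
    Disease,
    FiducialSet,
    InvariantError,
    Provenance,
    SignalClip,
    SubjectRecord,
)

__all__ = [
    "BeatSpec",
    "WarpSpec",
    "DEFAULT_EVENT_TIMES",
    "generate_beat_pair",
    "generate_recording",
    "vary_diastole",
    "apply_warp",
    "random_warp",
    "generate_cohort",
]

#: Default event times, ms from the R peak.  Q precedes R (ECG); the valve
#: events sit at physiologically plausible offsets: isovolumic contraction
#: MC->AO ~ 60 ms, ejection AO->AC ~ 300 ms, isovolumic relaxation
#: AC->MO ~ 70 ms.
DEFAULT_EVENT_TIMES: dict[str, float] = {
    "Q": -30.0, "MC": 25.0, "AO": 85.0, "AC": 385.0, "MO": 455.0,
}

# ECG morphology: (center ms from R, amplitude, Gaussian sigma ms)
_ECG_COMPONENTS = (
    (-160.0, 0.12, 22.0),   # P
    (-30.0, -0.15, 6.0),    # Q
    (0.0, 1.00, 9.0),       # R
    (25.0, -0.20, 7.0),     # S
    (240.0, 0.30, 45.0),    # T
)

# SCG bursts: event -> (amplitude, envelope sigma ms)
_SCG_BURSTS = {"MC": (0.6, 12.0), "AO": (1.0, 12.0), "AC": (0.8, 12.0), "MO": (0.5, 12.0)}
_SCG_CARRIER_HZ = 20.0


@dataclass(frozen=True)
class BeatSpec:
    """Parameters of one synthetic heartbeat.

    ``systole_ms`` is the boundary of the fixed-pace early portion; RR
    changes applied with :func:`vary_diastole` act only after it.
    """

    rr_ms: float = 966.0
    systole_ms: float = 600.0
    event_times: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EVENT_TIMES))
    noise_snr_db: float = math.inf
    seed: int = 0
    sampling_rate: float = 1000.0
    margin_ms: float = 300.0

    def __post_init__(self) -> None:
        t = self.event_times
        order = ["Q", "MC", "AO", "AC", "MO"]
        if not all(t[a] < t[b] for a, b in zip(order, order[1:])):
            raise InvariantError("event times must satisfy Q < MC < AO < AC < MO")
        if not t["MO"] < self.rr_ms:
            raise InvariantError("MO must precede the next R peak")
        if not self.systole_ms < self.rr_ms:
            raise InvariantError("systole_ms must be shorter than rr_ms")


@dataclass(frozen=True)
class WarpSpec:
    """Strictly increasing piecewise-linear time map src_ms -> dst_ms."""

    knots_src_ms: tuple[float, ...]
    knots_dst_ms: tuple[float, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        s, d = np.asarray(self.knots_src_ms), np.asarray(self.knots_dst_ms)
        if s.size != d.size or s.size < 2:
            raise InvariantError("warp needs matching knot arrays of length >= 2")
        if np.any(np.diff(s) <= 0) or np.any(np.diff(d) <= 0):
            raise InvariantError("warp knots must be strictly increasing")

    def __call__(self, t_ms):
        return np.interp(t_ms, self.knots_src_ms, self.knots_dst_ms)

    def inverse(self) -> "WarpSpec":
        return WarpSpec(self.knots_dst_ms, self.knots_src_ms, self.seed)


def _ecg_trace(t_ms: np.ndarray, r_times_ms: np.ndarray) -> np.ndarray:
    x = np.zeros_like(t_ms)
    for r in r_times_ms:
        for center, amp, sigma in _ECG_COMPONENTS:
            x += amp * np.exp(-0.5 * ((t_ms - r - center) / sigma) ** 2)
    return x


def _scg_trace(
    t_ms: np.ndarray, r_times_ms: np.ndarray, event_times: dict[str, float]
) -> np.ndarray:
    x = np.zeros_like(t_ms)
    for r in r_times_ms:
        for label, (amp, sigma) in _SCG_BURSTS.items():
            c = r + event_times[label]
            env = np.exp(-0.5 * ((t_ms - c) / sigma) ** 2)
            x += amp * env * np.cos(2 * np.pi * _SCG_CARRIER_HZ * (t_ms - c) / 1000.0)
    return x


def _add_noise(x: np.ndarray, snr_db: float, rng: np.random.Generator) -> np.ndarray:
    if not math.isfinite(snr_db):
        return x
    p_signal = float(np.mean(x**2))
    p_noise = p_signal / 10.0 ** (snr_db / 10.0)
    return x + rng.normal(0.0, math.sqrt(p_noise), size=x.shape)


def generate_beat_pair(
    spec: BeatSpec,
) -> tuple[SignalClip, SignalClip, BeatAnnotation, FiducialSet]:
    """One beat window: ECG + SCG clips, R/Q annotation, and exact fiducials.

    The window spans ``margin + RR + margin`` with R peaks at both ends of
    the central RR interval; fiducial times are clip-relative ms.
    """
    fs = spec.sampling_rate
    rng = np.random.default_rng(spec.seed)
    n = int(round((spec.rr_ms + 2 * spec.margin_ms) * fs / 1000.0)) + 1
    t = np.arange(n) / fs * 1000.0
    r_times = np.array([spec.margin_ms, spec.margin_ms + spec.rr_ms])
    ecg = _add_noise(_ecg_trace(t, r_times), spec.noise_snr_db, rng)
    scg = _add_noise(_scg_trace(t, r_times, spec.event_times), spec.noise_snr_db, rng)
    cid = f"synth-rr{spec.rr_ms:g}-s{spec.seed}"
    ecg_clip = SignalClip(f"{cid}-ecg", "synth", Channel.ECG, fs, ecg)
    scg_clip = SignalClip(f"{cid}-scg", "synth", Channel.SCG, fs, scg)
    r_idx = [int(round(r * fs / 1000.0)) for r in r_times]
    q_idx = [int(round((r + spec.event_times["Q"]) * fs / 1000.0)) for r in r_times]
    ann = BeatAnnotation(
        clip_id=ecg_clip.clip_id,
        r_peaks=r_idx,
        q_points=q_idx,
        # RR from the rounded peak indices so the annotation invariant holds
        rr_interval_ms=(r_idx[1] - r_idx[0]) / fs * 1000.0,
        sampling_rate=fs,
    )
    truth = FiducialSet(
        clip_id=scg_clip.clip_id,
        times={k: spec.margin_ms + v for k, v in spec.event_times.items()},
        provenance=Provenance.GROUND_TRUTH,
    )
    return ecg_clip, scg_clip, ann, truth


def generate_recording(
    rr_ms_list: list[float],
    base: BeatSpec | None = None,
    seed: int = 0,
) -> tuple[SignalClip, SignalClip, BeatAnnotation, list[FiducialSet]]:
    """A multi-beat recording with per-beat RR values.

    RR variation is applied diastolically (via :func:`vary_diastole`), so
    early-cycle events keep their offsets from each R peak.  Returns the
    ECG and SCG clips, the full R/Q annotation, and one ground-truth
    fiducial set per complete beat.
    """
    base = base or BeatSpec()
    fs = base.sampling_rate
    rng = np.random.default_rng(seed)
    r_times = [base.margin_ms]
    for rr in rr_ms_list:
        r_times.append(r_times[-1] + rr)
    r_times = np.array(r_times)
    total_ms = r_times[-1] + base.margin_ms
    n = int(round(total_ms * fs / 1000.0)) + 1
    t = np.arange(n) / fs * 1000.0
    ecg = _ecg_trace(t, r_times)
    scg = np.zeros_like(t)
    truths: list[FiducialSet] = []
    cid = f"synthrec-s{seed}"
    for k, rr in enumerate(rr_ms_list):
        spec_k = vary_diastole(base, rr - base.rr_ms)
        scg += _scg_trace(t, r_times[[k]], spec_k.event_times)
        truths.append(
            FiducialSet(
                clip_id=f"{cid}-scg",
                times={lab: r_times[k] + v for lab, v in spec_k.event_times.items()},
                provenance=Provenance.GROUND_TRUTH,
            )
        )
    ecg = _add_noise(ecg, base.noise_snr_db, rng)
    scg = _add_noise(scg, base.noise_snr_db, rng)
    ecg_clip = SignalClip(f"{cid}-ecg", "synth", Channel.ECG, fs, ecg)
    scg_clip = SignalClip(f"{cid}-scg", "synth", Channel.SCG, fs, scg)
    r_idx = [int(round(r * fs / 1000.0)) for r in r_times]
    c = min((len(r_idx) - 1) // 2, len(r_idx) - 2)
    ann = BeatAnnotation(
        clip_id=ecg_clip.clip_id,
        r_peaks=r_idx,
        q_points=[int(round((r + base.event_times["Q"]) * fs / 1000.0)) for r in r_times],
        rr_interval_ms=(r_idx[c + 1] - r_idx[c]) / fs * 1000.0,
        sampling_rate=fs,
    )
    return ecg_clip, scg_clip, ann, truths


def vary_diastole(spec: BeatSpec, delta_ms: float) -> BeatSpec:
    """Lengthen (or shorten) the beat in the diastolic portion only.

    Events at or before ``systole_ms`` are untouched; later events are
    scaled proportionally within the diastolic span.  This reproduces the
    observation that hearts beat at a comparable pace early in the cycle and
    absorb period differences late.
    """
    new_rr = spec.rr_ms + delta_ms
    if new_rr <= spec.systole_ms:
        raise InvariantError("diastolic shortening would erase the diastole")
    old_span = spec.rr_ms - spec.systole_ms
    new_span = new_rr - spec.systole_ms
    events = {
        lab: (t if t <= spec.systole_ms else spec.systole_ms + (t - spec.systole_ms) * new_span / old_span)
        for lab, t in spec.event_times.items()
    }
    return replace(spec, rr_ms=new_rr, event_times=events)


def apply_warp(
    clip: SignalClip, fiducials: FiducialSet, warp: WarpSpec
) -> tuple[SignalClip, FiducialSet]:
    """Resample a clip onto a warped time grid and map fiducials exactly.

    The warp maps clip-relative source time to destination time; samples are
    linearly interpolated at the warped grid, fiducial times pass through
    the warp in closed form.
    """
    fs = clip.sampling_rate
    t_src = clip.times_ms()
    dst_end = float(warp(t_src[-1]))
    n_dst = int(round(dst_end * fs / 1000.0)) + 1
    t_dst = np.arange(n_dst) / fs * 1000.0
    inv = warp.inverse()
    samples = np.interp(inv(t_dst), t_src, clip.samples)
    warped_clip = SignalClip(
        clip_id=f"{clip.clip_id}/warped",
        subject_id=clip.subject_id,
        channel=clip.channel,
        sampling_rate=fs,
        samples=samples,
        t0_offset=clip.t0_offset,
    )
    warped_fid = FiducialSet(
        clip_id=warped_clip.clip_id,
        times={lab: float(warp(t)) for lab, t in fiducials.times.items()},
        provenance=fiducials.provenance,
    )
    return warped_clip, warped_fid


def random_warp(
    duration_src_ms: float,
    duration_dst_ms: float,
    n_interior: int = 4,
    jitter_ms: float = 15.0,
    seed: int = 0,
) -> WarpSpec:
    """A smooth random monotone warp between two clip durations.

    Interior knots start on the proportional map and are jittered by up to
    ``jitter_ms`` while strict monotonicity is preserved.
    """
    rng = np.random.default_rng(seed)
    src = np.linspace(0.0, duration_src_ms, n_interior + 2)
    dst = src * duration_dst_ms / duration_src_ms
    j = rng.uniform(-jitter_ms, jitter_ms, size=n_interior)
    dst[1:-1] = dst[1:-1] + j
    # enforce strict monotonicity with a minimum gap
    for k in range(1, len(dst)):
        dst[k] = max(dst[k], dst[k - 1] + 1.0)
    dst[-1] = duration_dst_ms
    if dst[-2] >= dst[-1]:
        dst[-2] = (dst[-3] + dst[-1]) / 2.0
    return WarpSpec(tuple(src), tuple(dst), seed)


def generate_cohort(
    n_subjects: int,
    law_slope: float = -1.614,
    law_intercept: float = 0.998,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Cohort records under a known linear LVEF-index law.

    Per-subject PEP/LVET is drawn uniformly over a realistic range, LVEF
    follows ``intercept + slope * index`` plus Gaussian noise (clipped to an
    open unit interval), the Tei index tracks PEP/LVET with a fixed offset,
    and the disease label is HFrEF below the 40% ejection-fraction bound.
    """
    rng = np.random.default_rng(seed)
    records = []
    for k in range(n_subjects):
        pep_lvet = float(rng.uniform(0.15, 0.55))
        lvef = law_intercept + law_slope * pep_lvet
        if noise_sd > 0:
            lvef += float(rng.normal(0.0, noise_sd))
        lvef = float(np.clip(lvef, 1e-3, 1 - 1e-3))
        tei = pep_lvet + 0.12 + (float(rng.normal(0.0, noise_sd / 2)) if noise_sd > 0 else 0.0)
        tei = max(tei, 1e-3)
        if lvef < 0.40:
            disease = Disease.HFREF
        elif lvef < 0.50:
            disease = Disease.HFMREF
        else:
            disease = Disease.NORMAL
        records.append(
            SubjectRecord(
                subject_id=f"Synth-{k + 1:02d}",
                sex="M" if k % 2 else "F",
                age=float(rng.integers(20, 91)),
                lvef=lvef,
                disease=disease,
                cycles=int(rng.integers(34, 107)),
                pep_lvet_avg=pep_lvet,
                pep_lvet_sd=float(rng.uniform(0.01, 0.05)),
                tei_avg=tei,
                tei_sd=float(rng.uniform(0.02, 0.08)),
            )
        )
    return records
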