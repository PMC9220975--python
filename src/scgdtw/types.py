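"""Domain types for quasi-synchronous ECG/SCG alignment.

Conventions used throughout the package:

* every time is expressed in **milliseconds on the owning clip's timeline**
  (``t0_offset`` anchors a clip to its recording);
* sample indices are 0-based; ``index / sampling_rate * 1000`` converts an
  index to milliseconds;
* left-ventricular ejection fraction (LVEF) is stored as a fraction in
  ``(0, 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Channel",
    "Modality",
    "Provenance",
    "Disease",
    "EVENT_ORDER",
    "SignalClip",
    "BeatAnnotation",
    "EchoAnnotation",
    "FiducialSet",
    "SubjectRecord",
    "InvariantError",
]

#: Physiological ordering of the annotated events within one beat: the ECG Q
#: wave precedes mitral closure, which precedes aortic opening; aortic
#: closure and mitral opening end systole and isovolumic relaxation.
EVENT_ORDER = ("Q", "MC", "AO", "AC", "MO")

#: Valve events identifiable on an echocardiogram (Q comes from the ECG).
VALVE_EVENTS = ("MO", "MC", "AO", "AC")


class InvariantError(ValueError):
    """A domain-type invariant was violated."""


class Channel(str, Enum):
    ECG = "ECG"
    SCG = "SCG"


class Modality(str, Enum):
    M_MODE = "M_MODE"
    COLOR_DOPPLER = "COLOR_DOPPLER"
    TISSUE_DOPPLER = "TISSUE_DOPPLER"


class Provenance(str, Enum):
    ECHO_MAPPED = "ECHO_MAPPED"
    DTW_PROJECTED = "DTW_PROJECTED"
    CONVENTIONAL = "CONVENTIONAL"
    GROUND_TRUTH = "GROUND_TRUTH"


class Disease(str, Enum):
    NORMAL = "Normal"
    HFREF = "HFrEF"
    HFMREF = "HFmrEF"
    HFPEF = "HFpEF"
    MI = "MI"


@dataclass
class SignalClip:
    """One uniformly sampled ECG or SCG window.

    Parameters
    ----------
    clip_id, subject_id : str
        Identifiers carried through the pipeline.
    channel : Channel
        Whether the samples are an electrocardiogram or a seismocardiogram.
    sampling_rate : float
        Samples per second, > 0.
    samples : ndarray
        The signal values; finite, non-empty.
    t0_offset : float
        Time of the first sample relative to the recording start, ms.
    """

    clip_id: str
    subject_id: str
    channel: Channel
    sampling_rate: float
    samples: np.ndarray
    t0_offset: float = 0.0

    def __post_init__(self) -> None:
        self.channel = Channel(self.channel)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise InvariantError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise InvariantError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise InvariantError("samples must all be finite")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_ms(self) -> float:
        """Span from first to last sample, ms."""
        return (self.n_samples - 1) / self.sampling_rate * 1000.0

    def index_to_ms(self, index: float) -> float:
        """Clip-relative time of a (possibly fractional) sample index."""
        return float(index) / self.sampling_rate * 1000.0

    def ms_to_index(self, t_ms: float) -> int:
        """Nearest sample index for a clip-relative time."""
        return int(round(t_ms * self.sampling_rate / 1000.0))

    def times_ms(self) -> np.ndarray:
        """Clip-relative time axis, ms."""
        return np.arange(self.n_samples) / self.sampling_rate * 1000.0


@dataclass
class BeatAnnotation:
    """ECG landmarks for a clip: R peaks, optional Q points and T bounds.

    ``rr_interval_ms`` describes the central beat; when two or more R peaks
    are present it must equal the index difference of the central pair
    within half a sample.
    """

    clip_id: str
    r_peaks: Sequence[int]
    q_points: Sequence[int] | None = None
    t_bounds: tuple[int, int] | None = None
    rr_interval_ms: float | None = None
    sampling_rate: float | None = None

    def __post_init__(self) -> None:
        self.r_peaks = [int(i) for i in self.r_peaks]
        if len(self.r_peaks) < 1:
            raise InvariantError("at least one R peak required")
        if any(b <= a for a, b in zip(self.r_peaks, self.r_peaks[1:])):
            raise InvariantError("r_peaks must be strictly increasing")
        if self.q_points is not None:
            self.q_points = [int(i) for i in self.q_points]
            if len(self.q_points) != len(self.r_peaks):
                raise InvariantError("one q_point per r_peak expected")
        if self.rr_interval_ms is not None and self.rr_interval_ms <= 0:
            raise InvariantError("rr_interval_ms must be positive")
        if (
            self.rr_interval_ms is not None
            and self.sampling_rate is not None
            and len(self.r_peaks) >= 2
        ):
            i = self.central_beat_index()
            implied = (self.r_peaks[i + 1] - self.r_peaks[i]) / self.sampling_rate * 1000.0
            half_sample = 0.5 / self.sampling_rate * 1000.0
            if abs(implied - self.rr_interval_ms) > half_sample + 1e-9:
                raise InvariantError(
                    f"rr_interval_ms {self.rr_interval_ms} inconsistent with "
                    f"central R-R index difference ({implied:.3f} ms)"
                )

    def central_beat_index(self) -> int:
        """Index into ``r_peaks`` of the left R of the central beat."""
        n = len(self.r_peaks)
        if n < 2:
            return 0
        return min((n - 1) // 2, n - 2)


@dataclass
class EchoAnnotation:
    """Valve events read off one echocardiogram image.

    ``r1_ms``/``r2_ms`` are the two ECG R peaks delimiting the selected RR
    interval on the image timeline; ``events`` maps valve-event labels
    (MO, MC, AO, AC) to times on that same timeline.
    """

    image_id: str
    subject_id: str
    modality: Modality
    r1_ms: float
    r2_ms: float
    events: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        if not self.r1_ms < self.r2_ms:
            raise InvariantError(f"r1_ms ({self.r1_ms}) must precede r2_ms ({self.r2_ms})")
        self.events = dict(self.events)
        for label, t in self.events.items():
            if label not in VALVE_EVENTS:
                raise InvariantError(f"unknown event label {label!r}")
            if not (self.r1_ms <= t <= self.r2_ms):
                raise InvariantError(
                    f"event {label} at {t} ms outside [R1, R2] = "
                    f"[{self.r1_ms}, {self.r2_ms}] ms"
                )

    @property
    def rr_interval_ms(self) -> float:
        return self.r2_ms - self.r1_ms


@dataclass
class FiducialSet:
    """Event → time (ms, clip timeline) mapping on a specific SCG beat."""

    clip_id: str
    times: Mapping[str, float]
    provenance: Provenance

    def __post_init__(self) -> None:
        self.provenance = Provenance(self.provenance)
        self.times = dict(self.times)
        for label in self.times:
            if label not in EVENT_ORDER:
                raise InvariantError(f"unknown fiducial label {label!r}")

    def ordering_violations(self) -> list[tuple[str, str]]:
        """Pairs of present events that break Q ≤ MC ≤ AO ≤ AC ≤ MO."""
        present = [e for e in EVENT_ORDER if e in self.times]
        return [
            (a, b)
            for a, b in zip(present, present[1:])
            if self.times[a] > self.times[b]
        ]

    def is_ordered(self) -> bool:
        return not self.ordering_violations()

    def shifted(self, delta_ms: float) -> "FiducialSet":
        return FiducialSet(
            self.clip_id,
            {k: v + delta_ms for k, v in self.times.items()},
            self.provenance,
        )


@dataclass
class SubjectRecord:
    """One cohort-table row: clinical assessment plus per-subject index stats."""

    subject_id: str
    sex: str
    age: float
    lvef: float
    disease: Disease
    cycles: int
    pep_lvet_avg: float
    pep_lvet_sd: float
    tei_avg: float
    tei_sd: float

    def __post_init__(self) -> None:
        self.disease = Disease(self.disease)
        if self.sex not in ("M", "F"):
            raise InvariantError(f"sex must be M or F, got {self.sex!r}")
        if not 0.0 < self.lvef < 1.0:
            raise InvariantError(f"lvef must be a fraction in (0, 1), got {self.lvef}")
        if self.cycles < 1:
            raise InvariantError("cycles must be >= 1")
        if self.pep_lvet_sd < 0 or self.tei_sd < 0:
            raise InvariantError("SDs must be >= 0")
        if self.pep_lvet_avg <= 0 or self.tei_avg <= 0:
            raise InvariantError("indexes must be > 0")
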