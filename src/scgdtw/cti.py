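"""Cardiac time intervals and diagnostic indexes.

From the five per-beat fiducials (Q, MC, AO, AC, MO):

    PEP  = AO - Q      pre-ejection period
    LVET = AC - AO     left ventricular ejection time
    IVCT = AO - MC     isovolumic contraction time
    IVRT = MO - AC     isovolumic relaxation time

and the two heart-rate-independent indexes

    PEP/LVET           contractility coefficient
    Tei  = (IVCT + IVRT) / LVET    myocardial performance index.

Both indexes are ratios of intervals, so a common rescaling of all fiducial
times cancels; a common shift cancels already in the intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .types import EVENT_ORDER, FiducialSet

__all__ = [
    "CtiSet",
    "IndexPair",
    "SubjectStatistics",
    "OrderingError",
    "compute_ctis",
    "compute_indexes",
    "subject_statistics",
]


class OrderingError(ValueError):
    """Fiducials are missing or violate the physiological ordering."""


@dataclass(frozen=True)
class CtiSet:
    pep_ms: float
    lvet_ms: float
    ivct_ms: float
    ivrt_ms: float


@dataclass(frozen=True)
class IndexPair:
    pep_over_lvet: float
    tei: float


@dataclass(frozen=True)
class SubjectStatistics:
    """Per-subject mean and sample SD of the two indexes over n beats."""

    pep_lvet_avg: float
    pep_lvet_sd: float
    tei_avg: float
    tei_sd: float
    n: int


def compute_ctis(f: FiducialSet) -> CtiSet:
    """Intervals from a complete, ordered fiducial set.

    Raises
    ------
    OrderingError
        If any of Q, MC, AO, AC, MO is missing or an interval is
        non-positive; the message names the offending events.
    """
    missing = [e for e in EVENT_ORDER if e not in f.times]
    if missing:
        raise OrderingError(f"missing fiducial event(s): {', '.join(missing)}")
    t = f.times
    intervals = {
        "PEP": ("Q", "AO", t["AO"] - t["Q"]),
        "LVET": ("AO", "AC", t["AC"] - t["AO"]),
        "IVCT": ("MC", "AO", t["AO"] - t["MC"]),
        "IVRT": ("AC", "MO", t["MO"] - t["AC"]),
    }
    bad = [
        f"{name} = {b} - {a} = {v:.3f} ms"
        for name, (a, b, v) in intervals.items()
        if v <= 0
    ]
    if bad:
        raise OrderingError("non-positive interval(s): " + "; ".join(bad))
    return CtiSet(
        pep_ms=intervals["PEP"][2],
        lvet_ms=intervals["LVET"][2],
        ivct_ms=intervals["IVCT"][2],
        ivrt_ms=intervals["IVRT"][2],
    )


def compute_indexes(c: CtiSet) -> IndexPair:
    """PEP/LVET and Tei index from one beat's intervals."""
    return IndexPair(
        pep_over_lvet=c.pep_ms / c.lvet_ms,
        tei=(c.ivct_ms + c.ivrt_ms) / c.lvet_ms,
    )


def subject_statistics(per_beat: Sequence[IndexPair] | Iterable[IndexPair]) -> SubjectStatistics:
    """Mean and sample SD (n-1 denominator; 0 when n = 1) per index."""
    pairs = list(per_beat)
    if not pairs:
        raise ValueError("need at least one per-beat index pair")
    p = np.array([ip.pep_over_lvet for ip in pairs])
    t = np.array([ip.tei for ip in pairs])
    n = len(pairs)
    sd = (lambda v: float(np.std(v, ddof=1))) if n > 1 else (lambda v: 0.0)
    return SubjectStatistics(
        pep_lvet_avg=float(p.mean()),
        pep_lvet_sd=sd(p),
        tei_avg=float(t.mean()),
        tei_sd=sd(t),
        n=n,
    )
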