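"""Readers and writers for signal clips, annotations, and the cohort table.

Clip files are UTF-8 delimited text: ``#key=value`` header lines followed by
one sample per line.  Annotations travel as JSON.  The 56-subject cohort
table ships with the package as a TSV fixture.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    BeatAnnotation,
    Channel,
    EchoAnnotation,
    FiducialSet,
    InvariantError,
    Modality,
    Provenance,
    SignalClip,
    SubjectRecord,
)

__all__ = [
    "read_clip",
    "write_clip",
    "read_annotation",
    "write_annotation",
    "load_table1",
    "records_to_frame",
    "ClipParseError",
]

_HEADER_FIELDS = ("clip_id", "subject_id", "channel", "sampling_rate")


class ClipParseError(ValueError):
    """A clip file could not be parsed; the message names the offending line."""


def write_clip(clip: SignalClip, path: str | Path) -> Path:
    """Write ``clip`` as delimited text readable by :func:`read_clip`.

    Samples are written with 17 significant digits, which round-trips IEEE
    doubles bit-exactly; two writes of the same clip are byte-identical.
    """
    path = Path(path)
    lines = [
        f"#clip_id={clip.clip_id}",
        f"#subject_id={clip.subject_id}",
        f"#channel={clip.channel.value}",
        f"#sampling_rate={clip.sampling_rate!r}",
        f"#t0_offset={clip.t0_offset!r}",
    ]
    lines.extend(f"{x:.17g}" for x in clip.samples)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_clip(path: str | Path) -> SignalClip:
    """Parse a delimited-text clip file written by :func:`write_clip`."""
    path = Path(path)
    header: dict[str, str] = {}
    samples: list[float] = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" not in line:
                raise ClipParseError(f"{path}:{lineno}: malformed header line {raw!r}")
            key, _, value = line[1:].partition("=")
            header[key.strip()] = value.strip()
        else:
            try:
                samples.append(float(line))
            except ValueError:
                raise ClipParseError(
                    f"{path}:{lineno}: non-numeric sample {raw!r}"
                ) from None
    for f in _HEADER_FIELDS:
        if f not in header:
            raise ClipParseError(f"{path}: missing header field {f!r}")
    if not samples:
        raise ClipParseError(f"{path}: no sample lines")
    try:
        return SignalClip(
            clip_id=header["clip_id"],
            subject_id=header["subject_id"],
            channel=Channel(header["channel"]),
            sampling_rate=float(header["sampling_rate"]),
            samples=np.asarray(samples),
            t0_offset=float(header.get("t0_offset", 0.0)),
        )
    except (InvariantError, ValueError) as exc:
        raise ClipParseError(f"{path}: invalid clip: {exc}") from exc


# --- annotation JSON ------------------------------------------------------

def _annotation_payload(obj) -> dict:
    if isinstance(obj, BeatAnnotation):
        return {
            "kind": "beat",
            "clip_id": obj.clip_id,
            "r_peaks": list(obj.r_peaks),
            "q_points": list(obj.q_points) if obj.q_points is not None else None,
            "t_bounds": list(obj.t_bounds) if obj.t_bounds is not None else None,
            "rr_interval_ms": obj.rr_interval_ms,
            "sampling_rate": obj.sampling_rate,
        }
    if isinstance(obj, EchoAnnotation):
        return {
            "kind": "echo",
            "image_id": obj.image_id,
            "subject_id": obj.subject_id,
            "modality": obj.modality.value,
            "r1_ms": obj.r1_ms,
            "r2_ms": obj.r2_ms,
            "events": dict(obj.events),
        }
    if isinstance(obj, FiducialSet):
        return {
            "kind": "fiducials",
            "clip_id": obj.clip_id,
            "times": dict(obj.times),
            "provenance": obj.provenance.value,
        }
    raise TypeError(f"not an annotation type: {type(obj).__name__}")


def write_annotation(obj, path: str | Path) -> Path:
    """Serialize a Beat/Echo/Fiducial annotation to JSON."""
    path = Path(path)
    path.write_text(json.dumps(_annotation_payload(obj), indent=2, sort_keys=True) + "\n")
    return path


def read_annotation(path: str | Path):
    """Load an annotation JSON; the ``kind`` field selects the type."""
    payload = json.loads(Path(path).read_text())
    kind = payload.pop("kind", None)
    if kind == "beat":
        return BeatAnnotation(
            clip_id=payload["clip_id"],
            r_peaks=payload["r_peaks"],
            q_points=payload["q_points"],
            t_bounds=tuple(payload["t_bounds"]) if payload["t_bounds"] else None,
            rr_interval_ms=payload["rr_interval_ms"],
            sampling_rate=payload["sampling_rate"],
        )
    if kind == "echo":
        return EchoAnnotation(
            image_id=payload["image_id"],
            subject_id=payload["subject_id"],
            modality=Modality(payload["modality"]),
            r1_ms=payload["r1_ms"],
            r2_ms=payload["r2_ms"],
            events=payload["events"],
        )
    if kind == "fiducials":
        return FiducialSet(
            clip_id=payload["clip_id"],
            times=payload["times"],
            provenance=Provenance(payload["provenance"]),
        )
    raise ValueError(f"unknown annotation kind {kind!r}")


# --- cohort table ---------------------------------------------------------

def load_table1() -> list[SubjectRecord]:
    """Load the packaged 56-subject cohort table.

    LVEF is converted from the printed percentage to a fraction.
    """
    ref = resources.files("scgdtw.data").joinpath("table1.tsv")
    try:
        with resources.as_file(ref) as p:
            frame = pd.read_csv(p, sep="\t")
    except FileNotFoundError as exc:
        raise FileNotFoundError("packaged cohort table fixture is missing") from exc
    required = {
        "subject_id", "sex", "age", "lvef_pct", "disease", "cycles",
        "pep_lvet_avg", "pep_lvet_sd", "tei_avg", "tei_sd",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"cohort table fixture corrupt; missing columns {sorted(missing)}")
    records = [
        SubjectRecord(
            subject_id=row.subject_id,
            sex=row.sex,
            age=float(row.age),
            lvef=float(row.lvef_pct) / 100.0,
            disease=row.disease,
            cycles=int(row.cycles),
            pep_lvet_avg=float(row.pep_lvet_avg),
            pep_lvet_sd=float(row.pep_lvet_sd),
            tei_avg=float(row.tei_avg),
            tei_sd=float(row.tei_sd),
        )
        for row in frame.itertuples(index=False)
    ]
    return records


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Tabulate subject records as a DataFrame (LVEF as a fraction)."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "sex": [r.sex for r in records],
            "age": [r.age for r in records],
            "lvef": [r.lvef for r in records],
            "disease": [r.disease.value for r in records],
            "cycles": [r.cycles for r in records],
            "pep_lvet_avg": [r.pep_lvet_avg for r in records],
            "pep_lvet_sd": [r.pep_lvet_sd for r in records],
            "tei_avg": [r.tei_avg for r in records],
            "tei_sd": [r.tei_sd for r in records],
        }
    )
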