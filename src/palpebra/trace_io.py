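"""Readers/writers and data model for interpalpebral-fissure (IPF) recordings.

The pipeline's core signal is an IPF trace: the vertical eyelid aperture of one
eye sampled frame-by-frame from video (nominally 30 frames/s), in millimetres
after iris-diameter calibration, or in pixels before it.  A *recording* is one
such trace together with the study metadata (participant, eye, device
condition, comfort rating) that the crossover analysis needs.

File formats are deliberately plain: one CSV per trace
(``frame,time_s,ipf_mm`` or ``ipf_px``), a manifest CSV with one row per
recording, and a JSON annotation file for blink-event labels.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "ANGLE_CONDITIONS",
    "EYES",
    "LID_MAGNETS",
    "FRAME_STYLES",
    "EVENT_TYPES",
    "TraceFormatError",
    "ValidationError",
    "Recording",
    "IPFTrace",
    "BlinkAnnotation",
    "AnnotationSet",
    "read_trace",
    "write_trace",
    "read_manifest",
    "write_manifest",
    "read_annotations",
    "write_annotations",
    "write_results",
]

#: Study conditions: no device (baseline), the five spectacle-magnet angular
#: positions, and the fellow unaffected eye of unilateral participants.
CONDITIONS = (
    "baseline",
    "angle_0",
    "angle_30",
    "angle_60",
    "angle_90",
    "angle_180",
    "unaffected",
)
#: The five device angular positions, in rotation order.
ANGLE_CONDITIONS = ("angle_0", "angle_30", "angle_60", "angle_90", "angle_180")

EYES = ("left", "right")
LID_MAGNETS = ("type1", "type2", "none")
FRAME_STYLES = ("standard", "custom", "none")
EVENT_TYPES = ("spontaneous", "volitional")
ANNOTATION_SOURCES = ("ground_truth", "detected")


class TraceFormatError(ValueError):
    """A file does not have the expected columns/structure."""


class ValidationError(ValueError):
    """Well-formed data violating a domain invariant."""


@dataclass(frozen=True)
class Recording:
    """Metadata for one one-minute video recording of one eye.

    ``volitional_start`` marks the protocol point (seconds from trace start)
    at which the participant was asked to blink volitionally; everything
    before it is the spontaneous-blink segment.
    """

    recording_id: str
    participant_id: str
    eye: str
    condition: str
    lid_magnet: str = "none"
    frame_style: str = "none"
    comfort: Optional[int] = None
    frame_rate: float = 30.0
    volitional_start: Optional[float] = None

    def __post_init__(self) -> None:
        if self.eye not in EYES:
            raise ValidationError(f"unknown eye {self.eye!r}")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.lid_magnet not in LID_MAGNETS:
            raise ValidationError(f"unknown lid_magnet {self.lid_magnet!r}")
        if self.frame_style not in FRAME_STYLES:
            raise ValidationError(f"unknown frame_style {self.frame_style!r}")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")
        if self.comfort is not None and not (1 <= self.comfort <= 10):
            raise ValidationError(f"comfort {self.comfort} outside [1, 10]")
        if self.condition == "baseline" and self.lid_magnet != "none":
            raise ValidationError("baseline recordings carry no lid magnet")
        if self.volitional_start is not None and self.volitional_start < 0:
            raise ValidationError("volitional_start must be >= 0")


@dataclass
class IPFTrace:
    """A timestamped IPF series for one recording.

    Exactly one unit applies: ``unit='mm'`` (calibrated) or ``unit='px'``
    (raw pixel measurements awaiting calibration).
    """

    frame_index: np.ndarray
    time_s: np.ndarray
    values: np.ndarray
    unit: str = "mm"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.unit not in ("mm", "px"):
            raise ValidationError(f"unknown unit {self.unit!r}")

    # -- accessors ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    @property
    def ipf_mm(self) -> np.ndarray:
        if self.unit != "mm":
            raise ValidationError("trace is in pixels; calibrate it first")
        return self.values

    @property
    def ipf_px(self) -> np.ndarray:
        if self.unit != "px":
            raise ValidationError("trace is already calibrated to mm")
        return self.values

    def validate(self, frame_rate: Optional[float] = None) -> "IPFTrace":
        """Check the trace invariants, raising :class:`ValidationError`.

        Rows are reported 1-based (first data row = row 1).
        """
        if not (len(self.frame_index) == len(self.time_s) == len(self.values)):
            raise ValidationError("frame/time/value columns differ in length")
        if self.n < 2:
            raise ValidationError("trace must hold at least 2 samples")
        dt = np.diff(self.time_s)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            raise ValidationError(
                f"time not strictly increasing at row {bad[0] + 2}"
            )
        neg = np.nonzero(self.values < 0)[0]
        if neg.size:
            raise ValidationError(f"negative IPF value at row {neg[0] + 1}")
        if frame_rate is not None:
            nominal = 1.0 / frame_rate
            off = np.nonzero(np.abs(dt - nominal) > 0.1 * nominal)[0]
            if off.size:
                raise ValidationError(
                    f"frame spacing at row {off[0] + 2} deviates more than "
                    f"10% from nominal {nominal:.4f} s"
                )
        return self


@dataclass(frozen=True)
class BlinkAnnotation:
    """One labelled blink period on a trace."""

    start_s: float
    end_s: float
    type: str
    true_min_ipf_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {self.type!r}")
        if not self.start_s < self.end_s:
            raise ValidationError("event must satisfy start_s < end_s")


@dataclass
class AnnotationSet:
    """Ordered, non-overlapping blink-period labels for one recording."""

    events: list
    source: str = "ground_truth"

    def __post_init__(self) -> None:
        if self.source not in ANNOTATION_SOURCES:
            raise ValidationError(f"unknown annotation source {self.source!r}")
        ev = sorted(self.events, key=lambda e: e.start_s)
        for a, b in zip(ev, ev[1:]):
            if b.start_s < a.end_s:
                raise ValidationError(
                    f"events overlap: [{a.start_s}, {a.end_s}] and "
                    f"[{b.start_s}, {b.end_s}]"
                )
        self.events = ev


# ---------------------------------------------------------------------------
# trace CSV
# ---------------------------------------------------------------------------

def read_trace(path, frame_rate: float = 30.0) -> IPFTrace:
    """Read a trace CSV (``frame,time_s,ipf_mm`` or ``ipf_px``).

    ``time_s`` may be omitted, in which case it is derived as
    ``frame / frame_rate``.  The returned trace is validated against the
    trace invariants (monotone time, non-negative IPF, nominal spacing).
    """
    df = pd.read_csv(path)
    if "frame" not in df.columns:
        raise TraceFormatError(f"{path}: missing required column 'frame'")
    has_mm = "ipf_mm" in df.columns
    has_px = "ipf_px" in df.columns
    if has_mm == has_px:
        raise TraceFormatError(
            f"{path}: exactly one of 'ipf_mm'/'ipf_px' must be present"
        )
    unit = "mm" if has_mm else "px"
    frame = df["frame"].to_numpy()
    if "time_s" in df.columns:
        time_s = df["time_s"].to_numpy(dtype=float)
    else:
        time_s = frame / frame_rate
    trace = IPFTrace(frame, time_s, df["ipf_mm" if has_mm else "ipf_px"].to_numpy(),
                     unit=unit)
    trace.validate(frame_rate=frame_rate)
    return trace


def write_trace(trace: IPFTrace, path) -> None:
    col = "ipf_mm" if trace.unit == "mm" else "ipf_px"
    df = pd.DataFrame(
        {"frame": trace.frame_index, "time_s": trace.time_s, col: trace.values}
    )
    df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# manifest CSV
# ---------------------------------------------------------------------------

_MANIFEST_COLS = [
    "recording_id",
    "participant_id",
    "eye",
    "condition",
    "lid_magnet",
    "frame_style",
    "comfort",
    "frame_rate",
    "volitional_start",
]


def read_manifest(path) -> list[Recording]:
    """Read a study manifest CSV into validated :class:`Recording` rows."""
    df = pd.read_csv(path)
    missing = {"recording_id", "participant_id", "eye", "condition"} - set(df.columns)
    if missing:
        raise TraceFormatError(f"{path}: missing columns {sorted(missing)}")
    recordings = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        def _opt(name, default):
            v = row.get(name, default)
            return default if v is None or (isinstance(v, float) and np.isnan(v)) else v
        try:
            rec = Recording(
                recording_id=str(row["recording_id"]),
                participant_id=str(row["participant_id"]),
                eye=str(row["eye"]),
                condition=str(row["condition"]),
                lid_magnet=str(_opt("lid_magnet", "none")),
                frame_style=str(_opt("frame_style", "none")),
                comfort=None if _opt("comfort", None) is None else int(_opt("comfort", 0)),
                frame_rate=float(_opt("frame_rate", 30.0)),
                volitional_start=(None if _opt("volitional_start", None) is None
                                  else float(_opt("volitional_start", 0.0))),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
        recordings.append(rec)
    return recordings


def write_manifest(recordings: Sequence[Recording], path) -> None:
    rows = []
    for r in recordings:
        d = dataclasses.asdict(r)
        rows.append({c: d[c] for c in _MANIFEST_COLS})
    pd.DataFrame(rows, columns=_MANIFEST_COLS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# annotation JSON
# ---------------------------------------------------------------------------

def write_annotations(annotations: Mapping[str, AnnotationSet], path) -> None:
    """Write per-recording annotation sets to one JSON file."""
    payload = {
        rid: {
            "source": ann.source,
            "events": [
                {
                    "start_s": e.start_s,
                    "end_s": e.end_s,
                    "type": e.type,
                    "true_min_ipf_mm": e.true_min_ipf_mm,
                }
                for e in ann.events
            ],
        }
        for rid, ann in annotations.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotations(path) -> dict[str, AnnotationSet]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for rid, d in payload.items():
        events = [
            BlinkAnnotation(
                start_s=e["start_s"],
                end_s=e["end_s"],
                type=e["type"],
                true_min_ipf_mm=e.get("true_min_ipf_mm"),
            )
            for e in d["events"]
        ]
        out[rid] = AnnotationSet(events=events, source=d["source"])
    return out


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_results(tables: Mapping[str, object], out_dir) -> dict[str, str]:
    """Write result tables to ``out_dir``; returns name -> written path.

    DataFrames become CSV; mappings/lists become JSON.  Re-reading the CSVs
    with pandas reproduces the tabular content.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, obj in tables.items():
        if isinstance(obj, pd.DataFrame):
            path = out / f"{name}.csv"
            obj.to_csv(path, index=False, float_format="%.9g")
        else:
            path = out / f"{name}.json"
            path.write_text(json.dumps(obj, indent=1, default=_jsonable))
        manifest[name] = str(path)
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"cannot serialise {type(obj)!r}")
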