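"""Per-recording eyelid metrics: o-IPF, spontaneous and volitional m-IPF.

Three extractors turn a segmented trace into the study's outcome measures:

* **resting-open IPF (o-IPF)** — pool every between-blink frame and keep the
  values inside the 40th–60th percentile band; their mean is the resting
  opening, robust to residual slope frames at blink edges;
* **spontaneous minimum IPF (m-IPF)** — the mean of the three smallest values
  within a spontaneous blink period (three points, not one, to damp
  frame-level measurement error; at 30 frames/s three is the most that is
  consistently available around a spontaneous-blink minimum);
* **volitional minimum IPF** — the mean of the values inside the 40th–60th
  percentile band of the within-period distribution, which lands on the
  square-wave plateau and excludes the fast closing/opening slopes.

Percentiles use linear interpolation between order statistics and the band
is inclusive, ``[P40, P60]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .detection import BlinkEvent, SegmentationResult
from .trace_io import IPFTrace, Recording, ValidationError

__all__ = [
    "RecordingSummary",
    "percentile_band_values",
    "three_smallest_values",
    "resting_open_points",
    "resting_open_value",
    "spontaneous_min_points",
    "spontaneous_min_value",
    "volitional_min_points",
    "volitional_min_value",
    "summarize_recording",
]

MIN_OPEN_FRAMES = 5
MIN_VOLITIONAL_SAMPLES = 5


@dataclass
class RecordingSummary:
    """One recording's extracted metrics.

    Absent metrics (no events of a type, too few open frames) are ``None``
    and flagged — never silently zero.
    """

    recording_id: str
    o_ipf_mm: Optional[float]
    o_ipf_n: int
    spont_m_ipf_mm: Optional[float]
    vol_m_ipf_mm: Optional[float]
    spont_count: int
    vol_count: int
    blink_rate_per_min: Optional[float]
    flags: tuple = ()


# ---------------------------------------------------------------------------
# selectors
# ---------------------------------------------------------------------------

def percentile_band_values(values: np.ndarray, lo: float = 40.0,
                           hi: float = 60.0) -> np.ndarray:
    """Values v with ``P_lo <= v <= P_hi`` (linear-interpolation percentiles).

    Ties at the band edges are included.
    """
    values = np.asarray(values, dtype=float)
    p_lo, p_hi = np.percentile(values, [lo, hi])
    return values[(values >= p_lo) & (values <= p_hi)]


def three_smallest_values(values: np.ndarray) -> np.ndarray:
    """The three smallest values (all of them if fewer than three)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("empty blink period")
    k = min(3, values.size)
    return np.partition(values, k - 1)[:k]


# ---------------------------------------------------------------------------
# extractors
# ---------------------------------------------------------------------------

def resting_open_points(trace: IPFTrace, seg: SegmentationResult) -> np.ndarray:
    """The selected open-band IPF values (40th–60th percentile of open frames)."""
    open_values = trace.ipf_mm[seg.open_mask]
    if open_values.size < MIN_OPEN_FRAMES:
        return np.empty(0)
    return percentile_band_values(open_values)


def resting_open_value(trace: IPFTrace, seg: SegmentationResult):
    """Mean o-IPF and selected count; ``(None, n_open)`` if under 5 open frames."""
    open_values = trace.ipf_mm[seg.open_mask]
    if open_values.size < MIN_OPEN_FRAMES:
        return None, int(open_values.size)
    sel = percentile_band_values(open_values)
    return float(sel.mean()), int(sel.size)


def spontaneous_min_points(event: BlinkEvent) -> np.ndarray:
    if event.type != "spontaneous":
        raise ValidationError("event is not spontaneous")
    return three_smallest_values(event.within_period_values)


def spontaneous_min_value(event: BlinkEvent) -> float:
    """Mean of the three smallest within-period values."""
    return float(spontaneous_min_points(event).mean())


def volitional_min_points(event: BlinkEvent) -> np.ndarray:
    """Selected plateau values of a volitional blink period.

    Falls back to the three-smallest rule for degenerate periods shorter
    than 5 samples (flagged by the caller).
    """
    if event.type != "volitional":
        raise ValidationError("event is not volitional")
    v = event.within_period_values
    if v.size < MIN_VOLITIONAL_SAMPLES:
        return three_smallest_values(v)
    return percentile_band_values(v)


def volitional_min_value(event: BlinkEvent) -> float:
    return float(volitional_min_points(event).mean())


# ---------------------------------------------------------------------------
# per-recording summary
# ---------------------------------------------------------------------------

def summarize_recording(trace: IPFTrace, seg: SegmentationResult,
                        recording: Recording) -> RecordingSummary:
    """Aggregate the three extractors into one :class:`RecordingSummary`.

    The blink rate is the spontaneous count divided by the duration of the
    spontaneous segment (up to ``volitional_start`` when marked, else the
    whole trace) in minutes.
    """
    flags = []
    o_ipf, o_n = resting_open_value(trace, seg)
    if o_ipf is None:
        flags.append("insufficient_open_frames")

    spont = [e for e in seg.events if e.type == "spontaneous"]
    vol = [e for e in seg.events if e.type == "volitional"]

    spont_vals = [spontaneous_min_value(e) for e in spont]
    if any(e.within_period_values.size < 3 for e in spont):
        flags.append("short_spontaneous_period")
    vol_vals = [volitional_min_value(e) for e in vol]
    if any(e.within_period_values.size < MIN_VOLITIONAL_SAMPLES for e in vol):
        flags.append("short_volitional_period")

    spont_m = float(np.mean(spont_vals)) if spont_vals else None
    vol_m = float(np.mean(vol_vals)) if vol_vals else None
    if spont_m is None:
        flags.append("no_spontaneous_events")
    if vol_m is None:
        flags.append("no_volitional_events")

    spont_minutes = (
        recording.volitional_start if recording.volitional_start is not None
        else trace.duration_s
    ) / 60.0
    rate = len(spont) / spont_minutes if spont_minutes > 0 else None

    return RecordingSummary(
        recording_id=recording.recording_id,
        o_ipf_mm=o_ipf,
        o_ipf_n=o_n,
        spont_m_ipf_mm=spont_m,
        vol_m_ipf_mm=vol_m,
        spont_count=len(spont),
        vol_count=len(vol),
        blink_rate_per_min=rate,
        flags=tuple(flags),
    )
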