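"""Pixel-to-millimetre calibration via the horizontal visible iris diameter.

Video-derived IPF measurements start in pixels.  The in-image ruler is the
horizontal visible iris diameter (HVID), whose adult population mean of
11.67 mm is highly consistent across gender and race, so

    mm_per_px = 11.67 / HVID_in_pixels.

Frames here are the synthetic high-contrast renderings from
:mod:`palpebra.synthetic`; segmentation is a fixed intensity threshold
(iris < 128 < sclera/lids), which is all the schematic frames require.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import LID_INTENSITY, SCLERA_INTENSITY, SyntheticFrame
from .trace_io import IPFTrace, ValidationError

__all__ = [
    "HVID_MM",
    "IRIS_THRESHOLD",
    "Calibration",
    "MeasurementError",
    "measure_hvid_px",
    "measure_ipf_px",
    "make_calibration",
    "calibrate_trace",
    "uncalibrate_trace",
]

#: Adult population mean horizontal visible iris diameter, mm.
HVID_MM = 11.67

#: Fixed intensity threshold separating iris from sclera/lids.
IRIS_THRESHOLD = 128

#: Threshold separating the aperture (sclera/iris) from the lids.
_APERTURE_THRESHOLD = (LID_INTENSITY + SCLERA_INTENSITY) // 2


class MeasurementError(ValueError):
    """The frame does not contain the structure being measured."""


@dataclass(frozen=True)
class Calibration:
    """Pixel scale derived from a measured HVID."""

    hvid_px: float
    hvid_mm: float = HVID_MM

    def __post_init__(self) -> None:
        if self.hvid_px <= 0:
            raise ValidationError("hvid_px must be positive")

    @property
    def mm_per_px(self) -> float:
        return self.hvid_mm / self.hvid_px


def _longest_run(mask_row: np.ndarray) -> int:
    """Length of the longest run of True in a boolean vector."""
    if not mask_row.any():
        return 0
    padded = np.concatenate(([False], mask_row, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return int((ends - starts).max())


def measure_hvid_px(frame: SyntheticFrame) -> int:
    """Widest horizontal run of iris-class pixels (intensity < 128)."""
    iris = frame.intensity < IRIS_THRESHOLD
    if not iris.any():
        raise MeasurementError("no iris pixels visible (lid closed?)")
    return max(_longest_run(row) for row in iris)


def measure_ipf_px(frame: SyntheticFrame) -> int:
    """Greatest vertical extent of the lid aperture, in pixels (0 if closed)."""
    aperture = frame.intensity < _APERTURE_THRESHOLD
    if not aperture.any():
        return 0
    return int(aperture.sum(axis=0).max())


def make_calibration(hvid_px: float, hvid_mm: float = HVID_MM) -> Calibration:
    if hvid_px <= 0:
        raise ValidationError("hvid_px must be positive")
    return Calibration(hvid_px=float(hvid_px), hvid_mm=hvid_mm)


def calibrate_trace(trace: IPFTrace, cal: Calibration) -> IPFTrace:
    """Convert a pixel trace to millimetres; records the calibration used."""
    if trace.unit != "px":
        raise ValidationError("trace is already in mm")
    meta = dict(trace.meta)
    meta["calibration"] = {"hvid_px": cal.hvid_px, "hvid_mm": cal.hvid_mm,
                           "mm_per_px": cal.mm_per_px}
    return IPFTrace(
        frame_index=trace.frame_index.copy(),
        time_s=trace.time_s.copy(),
        values=trace.values * cal.mm_per_px,
        unit="mm",
        meta=meta,
    )


def uncalibrate_trace(trace: IPFTrace, cal: Calibration) -> IPFTrace:
    """Inverse of :func:`calibrate_trace` (mm back to pixels)."""
    if trace.unit != "mm":
        raise ValidationError("trace is already in px")
    return IPFTrace(
        frame_index=trace.frame_index.copy(),
        time_s=trace.time_s.copy(),
        values=trace.values / cal.mm_per_px,
        unit="px",
        meta=dict(trace.meta),
    )
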