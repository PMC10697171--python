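"""Synthetic IPF traces and studies with known ground truth.

The generator emulates the crossover study design: for each participant, a
one-minute spontaneous-blink recording per condition (no-device baseline plus
five spectacle-magnet angular positions, and the fellow unaffected eye of
unilateral participants), followed by three requested volitional blinks.

The signal model is deliberately simple and fully annotated:

* resting-open IPF is a per-recording constant — the population baseline
  (4.5 mm) plus a per-condition device effect plus a per-participant random
  intercept (severity), all in mm;
* each blink is a piecewise-linear dip: a linear fall over ``close_dur_s`` to
  the blink minimum, a constant hold, and a linear rise back to the open
  level.  Spontaneous blinks are sub-second and usually incomplete
  (minimum ≈ 2–4 mm under the device); volitional blinks hold over a second
  and close nearly completely (≈ 0.4 mm), the square-wave pattern seen in
  the study traces;
* i.i.d. Gaussian measurement noise per frame, clamped at zero.

Every generated event is recorded exactly in a ground-truth annotation set,
so detection and extraction can be scored without any manual labels.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .trace_io import (
    ANGLE_CONDITIONS,
    AnnotationSet,
    BlinkAnnotation,
    IPFTrace,
    Recording,
    ValidationError,
)

__all__ = [
    "BlinkSpec",
    "SimulationConfig",
    "GroundTruth",
    "SyntheticFrame",
    "GenerationError",
    "GeometryError",
    "blink_waveform",
    "simulate_recording",
    "simulate_study",
    "render_eye_frame",
]

STATES = ("open", "spont_blink", "vol_blink")


class GenerationError(RuntimeError):
    """Event layout could not be generated under the constraints."""


class GeometryError(ValueError):
    """Requested eye geometry does not fit the pixel grid."""


@dataclass(frozen=True)
class BlinkSpec:
    """Timing and depth of one blink dip."""

    onset_s: float
    close_dur_s: float
    hold_dur_s: float
    open_dur_s: float
    min_ipf_mm: float
    type: str = "spontaneous"

    def __post_init__(self) -> None:
        if min(self.close_dur_s, self.hold_dur_s, self.open_dur_s) <= 0:
            raise ValidationError("all blink durations must be positive")
        if self.min_ipf_mm < 0:
            raise ValidationError("min_ipf_mm must be >= 0")
        if self.type == "spontaneous" and self.total_dur_s >= 1.0:
            raise ValidationError("spontaneous blinks must last under 1 s")
        if self.type == "volitional" and self.hold_dur_s < 1.0:
            raise ValidationError("volitional blinks must hold >= 1 s")

    @property
    def total_dur_s(self) -> float:
        return self.close_dur_s + self.hold_dur_s + self.open_dur_s

    @property
    def end_s(self) -> float:
        return self.onset_s + self.total_dur_s


def _default_open_effects() -> dict:
    # Device effects on resting-open IPF relative to the 4.5 mm baseline;
    # unaffected fellow eyes open to 9.1 mm on average.
    return {
        "angle_0": 2.4,
        "angle_30": 1.7,
        "angle_60": 1.8,
        "angle_90": 2.0,
        "angle_180": 2.6,
        "unaffected": 4.6,
    }


def _default_spont_effects() -> dict:
    # Device effects on the spontaneous blink minimum relative to the 2.0 mm
    # no-device baseline; unaffected eyes also blink incompletely (2.9 mm).
    return {
        "angle_0": 1.9,
        "angle_30": 1.4,
        "angle_60": 1.0,
        "angle_90": 1.4,
        "angle_180": 1.4,
        "unaffected": 0.9,
    }


@dataclass
class SimulationConfig:
    """Study-level generator parameters (all lengths in mm, rates per min)."""

    n_participants: int = 16
    p_bilateral: float = 0.35
    baseline_open_mm: float = 4.5
    participant_sd_mm: float = 1.5
    condition_open_effect_mm: dict = field(default_factory=_default_open_effects)
    baseline_spont_min_mm: float = 2.0
    condition_spont_min_effect_mm: dict = field(default_factory=_default_spont_effects)
    volitional_min_mm: float = 0.4
    spont_rate_per_min: float = 12.0
    noise_sd_mm: float = 0.15
    comfort_baseline: float = 6.0
    comfort_device: float = 7.6
    comfort_sd: float = 1.5
    comfort_participant_sd: float = 0.8
    missing_fraction: float = 0.2
    participant_angle_sd_mm: float = 0.0
    frame_rate: float = 30.0
    spont_segment_s: float = 60.0
    n_volitional: int = 3
    # blink timing defaults (seconds); +/-30% uniform jitter applied per event
    spont_close_s: float = 0.100
    spont_hold_s: float = 0.133
    spont_open_s: float = 0.200
    vol_close_s: float = 0.25
    vol_hold_s: float = 2.0
    vol_open_s: float = 0.30
    duration_jitter: float = 0.30
    # loose-frame latching (magnets adhering, lid stuck open): off by
    # default; when on, device recordings may contain a stuck-open window
    # in which spontaneous blinks are suppressed
    latch_artifact: bool = False
    latch_prob: float = 0.3
    latch_dur_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.participant_sd_mm < 0 or self.noise_sd_mm < 0:
            raise ValidationError("standard deviations must be >= 0")
        if self.spont_rate_per_min <= 0 or self.frame_rate <= 0:
            raise ValidationError("rates must be positive")
        if not (0 <= self.p_bilateral <= 1 and 0 <= self.missing_fraction <= 1):
            raise ValidationError("probabilities must lie in [0, 1]")

    # -- population truth -------------------------------------------------
    def open_mean(self, condition: str) -> float:
        """Configured (pre-clamp) resting-open level for a condition."""
        eff = 0.0 if condition == "baseline" else self.condition_open_effect_mm[condition]
        return self.baseline_open_mm + eff

    def spont_min_mean(self, condition: str) -> float:
        """Configured (pre-clamp) spontaneous blink minimum for a condition."""
        eff = 0.0 if condition == "baseline" else self.condition_spont_min_effect_mm[condition]
        return self.baseline_spont_min_mm + eff

    def true_condition_means(self) -> pd.DataFrame:
        """Exact population (condition, state) cell means of the generator.

        The participant intercept is normal, but generated levels are
        floored (resting open at 2.5 mm, blink minima at 0.05 mm), so the
        population mean is the truncated-normal expectation
        ``E[max(mu + u, floor)]``, not the raw configured mean.  Assumes the
        default ``participant_angle_sd_mm = 0``.
        """
        from scipy.stats import norm

        def e_max(mu: float, floor: float) -> float:
            sd = self.participant_sd_mm
            if sd == 0:
                return max(mu, floor)
            z = (mu - floor) / sd
            return floor + (mu - floor) * norm.cdf(z) + sd * norm.pdf(z)

        rows = []
        for cond in ("baseline", *ANGLE_CONDITIONS, "unaffected"):
            rows.append((cond, "open", e_max(self.open_mean(cond), 2.5)))
            rows.append((cond, "spont_blink",
                         e_max(self.spont_min_mean(cond), 0.05)))
            rows.append((cond, "vol_blink", self.volitional_min_mm))
        return pd.DataFrame(rows, columns=["condition", "state", "true_mm"])


@dataclass
class GroundTruth:
    """Everything the generator knows: events, true means, intercepts."""

    annotations: dict  # recording_id -> AnnotationSet (source="ground_truth")
    true_condition_means: pd.DataFrame
    participant_intercepts: dict  # participant_id -> mm
    config: SimulationConfig


# ---------------------------------------------------------------------------
# waveform
# ---------------------------------------------------------------------------

def blink_waveform(t, baseline_mm: float, spec: BlinkSpec):
    """Piecewise-linear blink: baseline → fall → hold at minimum → rise.

    Vectorised over ``t`` (seconds); returns mm.
    """
    knots_t = np.array(
        [
            spec.onset_s,
            spec.onset_s + spec.close_dur_s,
            spec.onset_s + spec.close_dur_s + spec.hold_dur_s,
            spec.end_s,
        ]
    )
    knots_v = np.array([baseline_mm, spec.min_ipf_mm, spec.min_ipf_mm, baseline_mm])
    return np.interp(t, knots_t, knots_v)


# ---------------------------------------------------------------------------
# one recording
# ---------------------------------------------------------------------------

def _jittered(base: float, frac: float, rng) -> float:
    return base * (1.0 + rng.uniform(-frac, frac))


def _layout_spontaneous(config: SimulationConfig, n_events: int, rng,
                        lo: float, hi: float, min_gap: float = 0.6):
    """Place non-overlapping spontaneous blink intervals in [lo, hi].

    Onsets are uniform conditional on the intervals (plus a minimum open
    gap between them) fitting the segment: the free time is split into
    random spacings.  Durations are re-jittered on the rare infeasible
    draw; an impossible layout raises after 100 attempts.
    """
    for _ in range(100):
        durs = [
            (
                _jittered(config.spont_close_s, config.duration_jitter, rng),
                _jittered(config.spont_hold_s, config.duration_jitter, rng),
                _jittered(config.spont_open_s, config.duration_jitter, rng),
            )
            for _ in range(n_events)
        ]
        totals = [sum(d) for d in durs]
        free = (hi - lo) - sum(totals) - (n_events - 1) * min_gap
        if free < 0:
            continue
        u = rng.random(n_events + 1)
        gaps = free * u / u.sum()
        onsets = []
        t = lo
        for k in range(n_events):
            t += gaps[k]
            onsets.append(t)
            t += totals[k] + min_gap
        return list(zip(onsets, durs))
    raise GenerationError(
        f"could not place {n_events} non-overlapping blinks after 100 attempts"
    )


def simulate_recording(recording: Recording, config: SimulationConfig,
                       participant_offset: float, rng) -> tuple[IPFTrace, AnnotationSet]:
    """Simulate one recording's IPF trace and exact ground-truth events.

    ``participant_offset`` is the participant's random intercept (mm); it
    shifts the resting-open level and the spontaneous blink minima (ptosis
    severity affects both) but not volitional minima, which reflect the
    intact ability to close the eye on request.
    """
    # Floor the resting-open level: the generator does not model complete
    # ptosis, where blinks leave no visible aperture change.  The floor keeps
    # every simulated blink's amplitude (>= ~2.3 mm) well above measurement
    # noise, so events are detectable in principle.
    open_level = max(config.open_mean(recording.condition) + participant_offset, 2.5)
    spont_min = float(
        np.clip(config.spont_min_mean(recording.condition) + participant_offset,
                0.05, open_level - 0.3)
    )
    vol_min = float(np.clip(config.volitional_min_mm, 0.05, open_level - 0.3))

    fs = recording.frame_rate
    spont_seg = (recording.volitional_start
                 if recording.volitional_start is not None
                 else config.spont_segment_s)
    has_vol = recording.volitional_start is not None

    # optional stuck-open (latching) window on device recordings
    latch_window = None
    if (config.latch_artifact and recording.lid_magnet != "none"
            and rng.random() < config.latch_prob):
        start = rng.uniform(1.0, max(spont_seg - config.latch_dur_s - 1.0, 1.0))
        latch_window = (start, start + config.latch_dur_s)

    specs: list[BlinkSpec] = []
    n_spont = rng.poisson(config.spont_rate_per_min * spont_seg / 60.0)
    if n_spont:
        for onset, (c, h, o) in _layout_spontaneous(
            config, n_spont, rng, lo=0.5, hi=spont_seg - 1.0
        ):
            if latch_window and latch_window[0] <= onset <= latch_window[1]:
                continue  # lid latched open: blink suppressed
            specs.append(BlinkSpec(onset, c, h, o, spont_min, "spontaneous"))

    if has_vol:
        t0 = spont_seg + 2.0
        for k in range(config.n_volitional):
            c = _jittered(config.vol_close_s, config.duration_jitter, rng)
            h = max(_jittered(config.vol_hold_s, config.duration_jitter, rng), 1.0)
            o = _jittered(config.vol_open_s, config.duration_jitter, rng)
            specs.append(BlinkSpec(t0, c, h, o, vol_min, "volitional"))
            t0 += c + h + o + 1.2
        total_s = t0 + 1.5
    else:
        total_s = spont_seg

    n_frames = int(round(total_s * fs)) + 1
    frame = np.arange(n_frames)
    t = frame / fs
    values = np.full(n_frames, open_level)
    for spec in specs:
        values += blink_waveform(t, open_level, spec) - open_level
    if config.noise_sd_mm > 0:
        values = values + rng.normal(0.0, config.noise_sd_mm, size=n_frames)
    values = np.clip(values, 0.0, None)

    trace = IPFTrace(frame, t, values, unit="mm")
    events = [
        BlinkAnnotation(s.onset_s, s.end_s, s.type, s.min_ipf_mm) for s in specs
    ]
    return trace, AnnotationSet(events=events, source="ground_truth")


# ---------------------------------------------------------------------------
# whole study
# ---------------------------------------------------------------------------

def _recording_rng(seed: int, recording_id: str):
    """Substream keyed by stable hash of the recording id.

    Insertion-order independent: the stream depends only on (seed, id).
    """
    digest = hashlib.sha256(recording_id.encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def _comfort_value(mean: float, part_eff: float, rng, config: SimulationConfig) -> int:
    raw = mean + part_eff + rng.normal(0.0, config.comfort_sd)
    return int(np.clip(round(raw), 1, 10))


def simulate_study(config: SimulationConfig):
    """Simulate a full crossover study.

    Returns ``(recordings, traces, ground_truth)`` where ``traces`` maps
    recording_id -> IPFTrace.  Per participant: a baseline recording plus the
    five angular conditions on each affected eye (angles dropped at
    ``missing_fraction``, never the baseline) and, for unilateral
    participants, one unaffected-eye recording.  Fully reproducible from
    ``config.seed``.
    """
    if config.n_participants < 2:
        raise ValidationError("need at least 2 participants to fit the models")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5A11]))
    recordings: list[Recording] = []
    traces: dict[str, IPFTrace] = {}
    annotations: dict[str, AnnotationSet] = {}
    intercepts: dict[str, float] = {}

    vol_start = config.spont_segment_s
    for i in range(config.n_participants):
        pid = f"P{i + 1:03d}"
        u = rng.normal(0.0, config.participant_sd_mm)
        intercepts[pid] = float(u)
        comfort_u = rng.normal(0.0, config.comfort_participant_sd)
        bilateral = rng.random() < config.p_bilateral
        first_eye = rng.choice(["left", "right"])
        affected = [first_eye, ("left" if first_eye == "right" else "right")] if bilateral \
            else [first_eye]
        magnet = rng.choice(["type1", "type2"], p=[5 / 17, 12 / 17])
        frame_style = rng.choice(["standard", "custom"], p=[7 / 17, 10 / 17])
        angle_dev = {}
        if config.participant_angle_sd_mm > 0:
            for eye in affected:
                for cond in ANGLE_CONDITIONS:
                    angle_dev[(eye, cond)] = rng.normal(
                        0.0, config.participant_angle_sd_mm
                    )

        plan: list[tuple[str, str, Optional[int]]] = []
        for eye in affected:
            plan.append((eye, "baseline",
                         _comfort_value(config.comfort_baseline, comfort_u, rng, config)))
            for cond in ANGLE_CONDITIONS:
                if rng.random() < config.missing_fraction:
                    continue
                plan.append((eye, cond,
                             _comfort_value(config.comfort_device, comfort_u, rng, config)))
        if not bilateral:
            fellow = "left" if first_eye == "right" else "right"
            plan.append((fellow, "unaffected", None))

        for eye, cond, comfort in plan:
            rid = f"{pid}_{eye}_{cond}"
            rec = Recording(
                recording_id=rid,
                participant_id=pid,
                eye=eye,
                condition=cond,
                lid_magnet=magnet if cond in ANGLE_CONDITIONS else "none",
                frame_style=frame_style if cond in ANGLE_CONDITIONS else "none",
                comfort=comfort,
                frame_rate=config.frame_rate,
                volitional_start=vol_start,
            )
            rec_rng = _recording_rng(config.seed, rid)
            offset = u + angle_dev.get((eye, cond), 0.0)
            trace, ann = simulate_recording(rec, config, offset, rec_rng)
            recordings.append(rec)
            traces[rid] = trace
            annotations[rid] = ann

    truth = GroundTruth(
        annotations=annotations,
        true_condition_means=config.true_condition_means(),
        participant_intercepts=intercepts,
        config=config,
    )
    return recordings, traces, truth


# ---------------------------------------------------------------------------
# rendered eye frames (for the calibration stage)
# ---------------------------------------------------------------------------

LID_INTENSITY = 230
SCLERA_INTENSITY = 200
IRIS_INTENSITY = 60


@dataclass
class SyntheticFrame:
    """A rendered grayscale eye frame with known geometry."""

    intensity: np.ndarray  # uint8, rows x cols
    true_hvid_px: float
    true_ipf_px: float
    mm_per_px: float


def render_eye_frame(ipf_mm: float, hvid_mm: float = 11.67,
                     mm_per_px: float = 0.1, size: tuple[int, int] = (240, 320)
                     ) -> SyntheticFrame:
    """Render a schematic eye: lids (bright) truncating an elliptical
    aperture containing sclera and a dark iris disc of diameter
    ``hvid_mm / mm_per_px`` pixels.

    The aperture's vertical diameter is ``ipf_mm / mm_per_px`` pixels — the
    interpalpebral fissure.  Ground-truth pixel geometry is stored on the
    frame for round-trip tests.
    """
    rows, cols = size
    hvid_px = hvid_mm / mm_per_px
    ipf_px = ipf_mm / mm_per_px
    if ipf_mm < 0:
        raise GeometryError("ipf_mm must be >= 0")
    half_w = 0.9 * hvid_px  # aperture horizontal semi-axis
    if 2 * half_w > cols - 4 or ipf_px > rows - 4 or hvid_px > cols - 4:
        raise GeometryError(
            f"eye geometry (hvid {hvid_px:.0f} px, ipf {ipf_px:.0f} px) "
            f"exceeds the {rows}x{cols} grid"
        )
    img = np.full((rows, cols), LID_INTENSITY, dtype=np.uint8)
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    yy, xx = np.ogrid[:rows, :cols]
    if ipf_px > 0:
        b = ipf_px / 2.0
        aperture = ((yy - cy) / b) ** 2 + ((xx - cx) / half_w) ** 2 < 1.0
        img[aperture] = SCLERA_INTENSITY
        r = hvid_px / 2.0
        iris = (yy - cy) ** 2 + (xx - cx) ** 2 < r ** 2
        img[aperture & iris] = IRIS_INTENSITY
    return SyntheticFrame(
        intensity=img,
        true_hvid_px=hvid_px,
        true_ipf_px=ipf_px if ipf_px > 0 else 0.0,
        mm_per_px=mm_per_px,
    )
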