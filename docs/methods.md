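# Methods

This note documents the models, algorithms, and design choices behind
`palpebra`: what the synthetic-data generator assumes, how blink
segmentation and metric extraction work, how the study-level statistics are
fitted, and what the package's validation experiments do and do not show.

## Signal model and the synthetic-study generator

An IPF trace is modelled as a per-recording constant resting-open level with
piecewise-linear blink dips and additive frame-level measurement noise:

```
IPF(t) = open_level + Σ_events [w_e(t) − open_level] + ε(t),   ε ~ N(0, σ²), clamped at 0
```

where each blink waveform `w_e` falls linearly over `close_dur` to the blink
minimum, holds, and rises linearly back. Spontaneous blinks are sub-second
(defaults: close 100 ms, hold 133 ms, open 200 ms, ±30% uniform jitter per
event); the hold is sized so that, at 30 frames/s, about three samples sit in
the minimal region — the premise behind the three-smallest extraction rule,
which presumes roughly three usable points around a spontaneous-blink
minimum. Volitional blinks are square waves (close 250 ms, hold 2 s,
open 300 ms): the hold is sized so the plateau dominates the detected
period, because the within-period 40th–60th percentile band otherwise
drifts into the plateau's upper quantiles (see Metric extraction). Blink onsets within the one-minute spontaneous segment are
uniform conditional on non-overlap (a minimum 0.6 s open gap), with the
event count Poisson at 12/min — a typical adult spontaneous blink rate; the
study does not report its cohort's rate, so this is a generator choice.

Study structure: each participant carries a random intercept
`u ~ N(0, 1.5²)` (ptosis severity) that shifts the resting-open level and
the spontaneous blink minima; volitional minima do not carry it, reflecting
the clinical observation that volitional closure is essentially complete
regardless of severity or device setting. Per-condition means default to
the study's values: baseline opening 4.5 mm with device effects
+1.7…+2.6 mm (angles 30°…180°) and +4.6 mm for unaffected fellow eyes
(9.1 mm); spontaneous minima 2.0 mm baseline with device effects
+1.0…+1.9 mm and +0.9 mm for unaffected eyes (2.9 mm); volitional minima
0.4 mm everywhere. Comfort ratings are integer-rounded clipped normals
(baseline mean 6.0, device 7.6, residual sd 1.5, participant sd 0.8).
Device conditions are deleted completely at random at rate 0.2 (never the
baseline), emulating the study's missing cells.

Degenerate cases are floored for physical validity: the resting-open level
at 2.5 mm and event minima at 0.05 mm (and below the open level). The floor
keeps every simulated blink's amplitude ≥ ~2.3 mm — well above noise — so
ground-truth events are detectable in principle; complete ptosis (a resting
fissure near zero, where a blink produces no visible aperture change) is
explicitly **not** simulated. Because the intercept is normal, the floors
truncate the population means slightly; `SimulationConfig.true_condition_means`
returns the exact truncated-normal expectations
(`E[max(μ+u, floor)]`), which are the generating means the recovery
experiments score against (e.g. baseline open 4.564 rather than 4.5).

Reproducibility: participant-level draws come from one stream seeded by the
master seed; each recording gets a substream keyed by a stable SHA-256 hash
of its recording id, so traces are independent of generation order.

What the generator does **not** emulate: lid-position drift, blink-amplitude
autocorrelation, tracking dropouts, device latching artifacts (a stuck-open
lid from magnet adhesion), or non-Gaussian measurement error. Passing
recovery tests therefore show the pipeline is correct *under this signal
model*, not that it is robust to every artifact of real clinical video.

## Calibration

Synthetic frames render lids (intensity 230), sclera (200), and an iris
disc (60) of diameter HVID/mm_per_px inside an elliptical aperture whose
vertical diameter is the IPF. Segmentation is a fixed threshold (iris < 128;
aperture < 215) — adequate because the frames are high-contrast by
construction; iris localization in clinical photographs is out of scope.
HVID is the widest horizontal run of iris pixels, IPF the greatest vertical
aperture extent, and `mm_per_px = 11.67 / HVID_px`. Pixel discretisation
bounds both measurements within one pixel of truth for scales
0.05–0.3 mm/px (verified by the render-and-remeasure sweep).

## Blink segmentation

Derivatives are central differences (one-sided at the edges) of the
optionally 3-point-moving-average-smoothed trace; the second derivative is
the same operator applied twice. Smoothing defaults on: frame-by-frame
manual measurement implies jitter, and smoothing cuts the noise-induced
velocity sd from ~3.2 to ~1.5 mm/s at the default 0.15 mm noise.

Detection: a run of frames with d1 below −10 mm/s opens an event; the onset
is the last frame before the crossing, snapped to the nearest local |d2|
maximum within 2 frames (the sharpest inflection of the downstroke); the
event closes at the first frame after the subsequent rise run (d1 >
+10 mm/s) where the IPF has recovered to ≥ 70% of the local pre-event
median. Events closer than 0.1 s are merged *before* the minimum-duration
filter (66 ms) discards noise spikes; events touching the trace boundaries
are counted as truncated and excluded, since their minima are unobservable.
The ±10 mm/s defaults sit ~7σ above noise-induced derivatives yet a factor
≥1.5 below the weakest simulated closing speeds (amplitude ≥ 2.3 mm over
≤ 130 ms ≈ 18 mm/s); all thresholds are configurable.

Classification: when the protocol marker (`volitional_start`) is present,
events starting after it are volitional; otherwise events lasting ≥ 1 s are
volitional (volitional blinks last over a second; spontaneous ones a
fraction of one).

## Metric extraction

Percentiles use linear interpolation between order statistics, and the
40th–60th band is inclusive (`P40 ≤ v ≤ P60`, ties kept). The o-IPF pools
all open-mask frames; the volitional band is computed within each blink
period; the spontaneous rule takes the three smallest within-period values
(all of them, flagged, if a period holds fewer than three). Both selectors
are verified exactly against independent sort-based oracles. Per-event
minima are averaged to one per-recording summary value, but the point-level
selections are preserved as individual observations for the models, where
the point classes (open band, three-smallest, volitional band) are the
modelling unit.

A property of the volitional band rule worth knowing: because the blink
period necessarily includes closing/opening slope frames, which sit at the
top of the within-period distribution, the 40th–60th percentile band of
the *whole period* corresponds to upper quantiles of the plateau alone and
so sits slightly above the plateau centre under measurement noise — about
+0.05 mm at the default conditions (slope frames ~15% of the period,
noise sd 0.15 mm). The effect shrinks as the hold lengthens; it is a
characteristic of the selector, not an implementation artifact.

## Study-level models

The IPF model is `IPF ~ condition × state` (no-device baseline and open
state as reference levels) with random intercepts for participant and for
condition-within-participant-eye, fitted by REML; comfort is
`comfort ~ condition` with the same random effects, one observation per
recording, Likert ratings treated as interval data. Wald z tests and
`estimate ± 1.96·se` CIs are reported per term; contrasts use the full
fixed-effect covariance. Unaffected-eye observations are excluded from the
main fit by default (they provide the reference band, not a device
condition). No multiple-testing adjustment is applied.

Numerically, the REML objective is evaluated on sufficient statistics: all
covariates are constant within a (recording, state) cell, so the likelihood
factorises exactly into within-cell contrasts (residual variance only) and
cell means with per-participant covariance
`σ²_participant·J + σ²_cond_eye·S + σ²·diag(1/n_cell)`. The three
log-variances are optimised by Nelder-Mead from method-of-moments starts
(three starting points). This matters because the band-selected points make
the within-cell residual variance tiny (~0.002 mm²), which puts generic
mixed-model optimizers on a badly scaled profiled surface; on
well-conditioned data the fit matches lme4's REML to ~4 significant
figures (cross-checked in the test suite, along with statsmodels MixedLM).

The profile (parallelism) analysis restricts to eyes with observations at
all five angular positions and tests, per eyelid state, whether the per-eye
profiles of the four adjacent-angle mean differences are equal. The
implementation compares the saturated cell-means model against the additive
eye + angle model with an exact F test — equality of segment-difference
vectors across eyes is precisely the absence of an eye × angle interaction.
Under i.i.d. within-cell noise the test is exactly calibrated (empirical
type-I error 0.05 ± 0.02 at 2000 null replicates). This is one concrete
reading of a repeated-measures "piecewise parallelism" MANOVA; the exact
original construction (reported as z statistics) is not recoverable, so
the package reports F, degrees of freedom, and p.

The expected eyelid-magnet rolling direction is a categorical lookup per
magnet polarisation and angle (type 1, north up: minimal at 0°/30°, outward
from 60°; type 2, north out: outward at 0°/30°, minimal at 60°, inward at
90°/180°), and agreement is observed/expected rounded half-up to two
decimals — the printed-table convention (5/8 → 0.63). Cohort demographics
collapse duplicate enrollments to unique individuals for the median age,
count gender and laterality over table rows, and count contributing
participants as rows minus exclusions.

## Validation experiments and problem sizes

The experiments in `palpebra.validation` (also driven by
`scripts/acceptance.py`) use the study's own scale: 16-participant studies,
one-minute 30 frames/s recordings, 0.15 mm noise. Parameter recovery runs
100 replicate studies through the full pipeline (~3 minutes on one CPU) and
scores Wald-CI coverage of the generating cell means; detection is scored
on 500 one-minute recordings; the parallelism null uses 2000 synthetic
8-eye tables generated directly at the observation level (the test's own
model), which is what a size calibration requires and keeps the run in
seconds; the calibration sweep renders 120 random geometries across six
pixel scales.

## Known limitations

* The generator's participant effect is a single shared intercept; real
  ptosis severity plausibly modulates device *effects*, not just levels
  (a `participant_angle_sd_mm` knob exists, default 0).
* Volitional minima carry no participant intercept while the model assumes
  a shared one; REML absorbs the mismatch into the residual, a mild,
  documented model-generator discrepancy.
* Blink waveforms are piecewise linear; real lid trajectories are smooth,
  so derivative magnitudes near onsets are idealised.
* Comfort is generated and modelled as interval data; ordinal models are
  out of scope.
* Calibration operates on schematic synthetic frames only.
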