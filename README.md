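# palpebra

Eyelid blink kinematics from interpalpebral-fissure traces: simulation,
derivative-based blink segmentation, percentile-based metric extraction, and
crossover mixed-model analysis.

## The problem

Severe blepharoptosis (a drooping upper eyelid that blocks the visual axis)
can be treated non-surgically with a magnetic levator prosthesis: a
spectacle-mounted magnet attracts small magnets adhered to the eyelid and
lifts it. Rotating a diametrically magnetized spectacle magnet through angular
positions (0°–180°) titrates the lifting force. Evaluating such a device means
quantifying eyelid kinematics from video: how far the eye opens at rest, and
how completely it still closes during spontaneous and volitional blinks.

The measurement is the **interpalpebral fissure (IPF)** — the greatest
vertical distance between the lid margins — tracked frame-by-frame at
30 frames/s and calibrated from pixels to millimetres using the adult
population mean horizontal visible iris diameter (HVID, 11.67 mm) as an
in-image ruler. From each one-minute recording the pipeline extracts:

* **o-IPF** (resting opening): the mean of between-blink IPF values inside
  the 40th–60th percentile band of the open-period distribution;
* **spontaneous m-IPF**: per blink, the mean of the three smallest
  within-period IPF values;
* **volitional m-IPF**: per requested blink, the mean of the within-period
  values inside the 40th–60th percentile band (the square-wave plateau).

Blink periods are segmented from the first and second discrete derivatives of
the IPF trace: a run of frames with velocity below −10 mm/s starts an event
(onset refined to the nearest |d²IPF/dt²| maximum), and the event ends after
the subsequent rise once the IPF recovers to 70% of its local pre-event
level.

Study-level inference uses linear mixed-effects models (REML): IPF ~ angular
position × eyelid state, with random intercepts for participant and for
condition-within-participant-eye; comfort ratings (Likert 1–10, treated as
interval data) ~ angular position with the same random effects. A profile
(parallelism) analysis — an exact F test of the eye × angle interaction,
equivalently of equality of each eye's adjacent-angle difference profile —
tests whether participants respond *differently* to the angular positions.

Because the underlying clinical videos are not public, the package ships a
fully annotated synthetic-study generator that emulates the study's signal
structure (baseline opening 4.5 mm rising to 6.2–7.1 mm under the device,
incomplete spontaneous blinks at 2.0–3.9 mm, near-complete ~0.4 mm volitional
closure, participant-level variation, measurement noise, missing conditions),
so every stage is testable against exact ground truth.

## Worked example

```python
from palpebra import SimulationConfig, fit_ipf_mixed_model, cell_mean
from palpebra.validation import run_study_pipeline

cfg = SimulationConfig(seed=42)          # 16 participants, study defaults
recordings, traces, truth, table = run_study_pipeline(cfg)
model = fit_ipf_mixed_model(table)
for cond in ("baseline", "angle_30", "angle_180"):
    est, se, lo, hi = cell_mean(model, cond, "open")
    print(f"{cond:10s} o-IPF {est:4.2f} mm (95% CI {lo:4.2f}-{hi:4.2f})")
```

prints (one synthetic study at the default seed):

```
baseline   o-IPF 4.64 mm (95% CI 4.01-5.26)
angle_30   o-IPF 6.36 mm (95% CI 5.73-6.99)
angle_180  o-IPF 7.24 mm (95% CI 6.61-7.87)
```

i.e. the pipeline recovers this study's generating means — baseline opening
near 4.5 mm, ~6.2 mm at the weakest device setting and ~7.1 mm at the
strongest (the half-millimetre offsets here are this replicate's sampled
participants) — with the device effect highly significant against baseline.

The same pipeline is available from the shell:

```bash
palpebra run --seed 42 --out study_run     # simulate → detect → summarize →
                                           # analyze → report, with a hashed
                                           # output manifest
```

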