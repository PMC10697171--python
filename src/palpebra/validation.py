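"""End-to-end validation experiments on synthetic studies.

These are the package's own checks that the full pipeline — simulate,
detect, extract, model — recovers what the generator put in, at the study's
scale (16 participants, one-minute 30 frames/s recordings, 0.15 mm
measurement noise).  They are used by the test suite and by
``scripts/acceptance.py``; each takes an explicit seed and returns plain
numbers.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .detection import SegmentationParams, classify_blinks, detect_blink_periods
from .stats import (
    build_observation_table,
    cell_mean,
    comfort_cell_mean,
    fit_comfort_model,
    fit_ipf_mixed_model,
    profile_parallelism_test,
)
from .synthetic import SimulationConfig, render_eye_frame, simulate_study
from .calibration import measure_hvid_px, measure_ipf_px
from .trace_io import ANGLE_CONDITIONS, Recording

__all__ = [
    "run_study_pipeline",
    "recovery_experiment",
    "detection_benchmark",
    "parallelism_null_size",
    "calibration_sweep",
    "percentile_band_oracle",
    "three_smallest_oracle",
    "selector_oracle_check",
]


def _subseed(seed: int, k: int) -> int:
    """Derived integer seed, kept below 2**31."""
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# full pipeline on one synthetic study
# ---------------------------------------------------------------------------

def run_study_pipeline(config: SimulationConfig,
                       params: SegmentationParams = SegmentationParams()):
    """Simulate a study and run detection + extraction on every recording.

    Returns ``(recordings, traces, truth, table)`` where ``table`` is the
    long-format observation table built from *detected* events.
    """
    recordings, traces, truth = simulate_study(config)
    items = []
    for rec in recordings:
        trace = traces[rec.recording_id]
        seg = classify_blinks(detect_blink_periods(trace, params), rec, trace)
        items.append((rec, trace, seg))
    table = build_observation_table(items)
    return recordings, traces, truth, table


# ---------------------------------------------------------------------------
# parameter-recovery experiment
# ---------------------------------------------------------------------------

def recovery_experiment(n_replicates: int = 100, seed: int = 1,
                        config: Optional[SimulationConfig] = None) -> dict:
    """Replicate the full pipeline and score CI coverage of the generating
    condition means.

    Per replicate: simulate a study at the configured
    conditions, detect and classify blinks, build the observation table, fit
    the IPF mixed model and the comfort model, and record for every
    (condition, state) cell whether the generating mean falls inside the
    model's Wald 95% CI, along with the point estimate.

    Returns a dict with a per-cell DataFrame (``truth``, ``coverage`` count,
    ``mean_estimate``) and the comfort-model analogues.
    """
    base = config if config is not None else SimulationConfig()
    cells = [(c, s) for c in ("baseline", *ANGLE_CONDITIONS)
             for s in ("open", "spont_blink", "vol_blink")]
    tcm = base.true_condition_means().set_index(["condition", "state"])
    truth = {cell: float(tcm.loc[cell, "true_mm"]) for cell in cells}

    covered = {cell: 0 for cell in cells}
    estimates = {cell: [] for cell in cells}
    comfort_truth = {"baseline": base.comfort_baseline, "device": base.comfort_device}
    comfort_covered = {k: 0 for k in comfort_truth}
    comfort_estimates = {k: [] for k in comfort_truth}
    n_done = 0

    for r in range(n_replicates):
        cfg = replace(base, seed=_subseed(seed, r))
        _, _, _, table = run_study_pipeline(cfg)
        model = fit_ipf_mixed_model(table)
        for cell in cells:
            est, _, lo, hi = cell_mean(model, *cell)
            estimates[cell].append(est)
            if lo <= truth[cell] <= hi:
                covered[cell] += 1
        cmodel = fit_comfort_model(table)
        b_est, _, b_lo, b_hi = comfort_cell_mean(cmodel, "baseline")
        comfort_estimates["baseline"].append(b_est)
        if b_lo <= comfort_truth["baseline"] <= b_hi:
            comfort_covered["baseline"] += 1
        # device comfort: average of the five angle cell means, scored
        # against a CI built from the average of their SEs
        dev = [comfort_cell_mean(cmodel, c) for c in ANGLE_CONDITIONS]
        d_est = float(np.mean([d[0] for d in dev]))
        comfort_estimates["device"].append(d_est)
        d_se = float(np.mean([d[1] for d in dev]))
        if d_est - 1.96 * d_se <= comfort_truth["device"] <= d_est + 1.96 * d_se:
            comfort_covered["device"] += 1
        n_done += 1

    rows = [
        {
            "condition": c,
            "state": s,
            "truth_mm": truth[(c, s)],
            "coverage": covered[(c, s)],
            "n_replicates": n_done,
            "mean_estimate_mm": float(np.mean(estimates[(c, s)])),
        }
        for c, s in cells
    ]
    comfort_rows = [
        {
            "cell": k,
            "truth": comfort_truth[k],
            "coverage": comfort_covered[k],
            "n_replicates": n_done,
            "mean_estimate": float(np.mean(comfort_estimates[k])),
        }
        for k in comfort_truth
    ]
    return {
        "cells": pd.DataFrame(rows),
        "comfort": pd.DataFrame(comfort_rows),
        "n_replicates": n_done,
    }


# ---------------------------------------------------------------------------
# blink-detection benchmark
# ---------------------------------------------------------------------------

def detection_benchmark(n_recordings: int = 500, seed: int = 1,
                        config: Optional[SimulationConfig] = None,
                        params: SegmentationParams = SegmentationParams()) -> dict:
    """Event-level precision/recall of detection on 60-s recordings.

    Each recording draws a fresh participant intercept and cycles through
    the study conditions; ground-truth events count as recalled when an
    overlapping detected event exists, and detected events as correct when
    they overlap a ground-truth event.
    """
    from .synthetic import simulate_recording

    cfg = config if config is not None else SimulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD37EC7]))
    conditions = ("baseline", *ANGLE_CONDITIONS)
    tp = fp = fn = 0
    for i in range(n_recordings):
        cond = conditions[i % len(conditions)]
        rec = Recording(
            recording_id=f"bench_{i:04d}",
            participant_id=f"B{i:04d}",
            eye="left",
            condition=cond,
            lid_magnet="type2" if cond != "baseline" else "none",
            frame_rate=cfg.frame_rate,
            volitional_start=None,  # 60-s spontaneous segment only
        )
        offset = rng.normal(0.0, cfg.participant_sd_mm)
        trace, ann = simulate_recording(rec, cfg, offset, rng)
        seg = detect_blink_periods(trace, params)
        det = [(trace.time_s[e.start_idx], trace.time_s[e.end_idx])
               for e in seg.events]
        for ev in ann.events:
            if any(s < ev.end_s and e > ev.start_s for s, e in det):
                tp += 1
            else:
                fn += 1
        for s, e in det:
            if not any(s < ev.end_s and e > ev.start_s for ev in ann.events):
                fp += 1
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return {
        "precision": precision,
        "recall": recall,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "n_recordings": n_recordings,
    }


# ---------------------------------------------------------------------------
# parallelism-test calibration
# ---------------------------------------------------------------------------

def parallelism_null_size(n_replicates: int = 2000, n_eyes: int = 8,
                          n_per_cell: int = 20, noise_sd: float = 0.15,
                          seed: int = 1, alpha: float = 0.05) -> dict:
    """Empirical type-I error of the parallelism test under the parallel null.

    Generates point-level observation tables in which every eye shares one
    angle profile (the default device open effects) on top of its own
    intercept, with i.i.d. measurement noise, and counts rejections at
    ``alpha``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9A7A]))
    base = SimulationConfig()
    effects = np.array([base.condition_open_effect_mm[a] for a in ANGLE_CONDITIONS])
    rejections = 0
    n_rows = n_eyes * len(ANGLE_CONDITIONS) * n_per_cell
    eye_ids = np.repeat([f"E{e:02d}" for e in range(n_eyes)],
                        len(ANGLE_CONDITIONS) * n_per_cell)
    cond_col = np.tile(np.repeat(list(ANGLE_CONDITIONS), n_per_cell), n_eyes)
    eff_col = np.tile(np.repeat(effects, n_per_cell), n_eyes)
    for _ in range(n_replicates):
        intercepts = rng.normal(base.baseline_open_mm, base.participant_sd_mm,
                                size=n_eyes)
        y = (np.repeat(intercepts, len(ANGLE_CONDITIONS) * n_per_cell)
             + eff_col + rng.normal(0.0, noise_sd, size=n_rows))
        table = pd.DataFrame(
            {
                "participant_id": eye_ids,
                "eye": "left",
                "condition": cond_col,
                "state": "open",
                "ipf_mm": y,
            }
        )
        res = profile_parallelism_test(table, "open")
        if res.p < alpha:
            rejections += 1
    return {
        "type1_error": rejections / n_replicates,
        "n_replicates": n_replicates,
        "alpha": alpha,
    }


# ---------------------------------------------------------------------------
# calibration round-trip
# ---------------------------------------------------------------------------

def calibration_sweep(seed: int = 1, scales: Sequence[float] = (0.05, 0.1, 0.15,
                                                                0.2, 0.25, 0.3),
                      n_per_scale: int = 20, hvid_mm: float = 11.67) -> dict:
    """Render-and-remeasure round trip across pixel scales.

    At each mm/px scale, renders frames with random IPF, measures HVID and
    IPF back in pixels, and records the worst absolute errors (pixels).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCA11B]))
    max_hvid_err = 0.0
    max_ipf_err = 0.0
    for s in scales:
        hvid_px = hvid_mm / s
        for _ in range(n_per_scale):
            ipf_mm = rng.uniform(2.0, 10.0)
            rows = 2 * (int(ipf_mm / s) // 2) + 12
            cols = 2 * (int(2 * 0.9 * hvid_px) // 2) + 12
            frame = render_eye_frame(ipf_mm, hvid_mm=hvid_mm, mm_per_px=s,
                                     size=(rows, cols))
            hvid_meas = measure_hvid_px(frame)
            ipf_meas = measure_ipf_px(frame)
            max_hvid_err = max(max_hvid_err, abs(hvid_meas - frame.true_hvid_px))
            max_ipf_err = max(max_ipf_err, abs(ipf_meas - frame.true_ipf_px))
    return {
        "max_hvid_err_px": max_hvid_err,
        "max_ipf_err_px": max_ipf_err,
        "n_frames": len(tuple(scales)) * n_per_scale,
    }


# ---------------------------------------------------------------------------
# brute-force selector oracles
# ---------------------------------------------------------------------------

def _interp_percentile(sorted_vals, p: float) -> float:
    """Linear-interpolation percentile from pre-sorted values (0<=p<=100)."""
    n = len(sorted_vals)
    h = (n - 1) * (p / 100.0)
    f = math.floor(h)
    if f >= n - 1:
        return float(sorted_vals[-1])
    return float(sorted_vals[f] + (h - f) * (sorted_vals[f + 1] - sorted_vals[f]))


def percentile_band_oracle(values, lo: float = 40.0, hi: float = 60.0):
    """Sort-based reimplementation of the 40th–60th percentile band selector."""
    s = sorted(float(v) for v in values)
    p_lo = _interp_percentile(s, lo)
    p_hi = _interp_percentile(s, hi)
    return [v for v in s if p_lo <= v <= p_hi]


def three_smallest_oracle(values):
    return sorted(float(v) for v in values)[:3]


def selector_oracle_check(n_vectors: int = 10000, seed: int = 1) -> dict:
    """Exact agreement of both selectors with their sort-based oracles."""
    from .kinematics import percentile_band_values, three_smallest_values

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0AC1E]))
    band_mismatch = 0
    smallest_mismatch = 0
    for _ in range(n_vectors):
        n = int(rng.integers(5, 80))
        v = rng.normal(5.0, 2.0, size=n)
        if rng.random() < 0.3:  # exercise ties
            v = np.round(v, 1)
        impl = np.sort(percentile_band_values(v))
        oracle = np.array(percentile_band_oracle(v))
        if impl.size != oracle.size or not np.array_equal(impl, oracle):
            band_mismatch += 1
        impl3 = np.sort(three_smallest_values(v))
        oracle3 = np.array(three_smallest_oracle(v))
        if not np.array_equal(impl3, oracle3):
            smallest_mismatch += 1
    return {
        "band_mismatches": band_mismatch,
        "three_smallest_mismatches": smallest_mismatch,
        "n_vectors": n_vectors,
    }
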