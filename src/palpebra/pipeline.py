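"""Stage-chained study pipeline: simulate → detect → summarize → analyze → report.

Each stage reads its predecessor's files and writes its own, so any stage can
be re-run in isolation; :func:`run_pipeline` chains them, logs parameters and
seeds, and emits a manifest with a SHA-256 hash of every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import trace_io
from .detection import SegmentationParams, classify_blinks, detect_blink_periods
from .kinematics import summarize_recording
from .stats import (
    build_observation_table,
    condition_means_table,
    demographics_summary,
    fit_comfort_model,
    fit_ipf_mixed_model,
    profile_parallelism_test,
)
from .synthetic import SimulationConfig, simulate_study
from .trace_io import ANGLE_CONDITIONS, ValidationError

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("palpebra")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


@dataclass
class PipelineConfig:
    out_dir: str = "palpebra_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    include_unaffected: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        seg = SegmentationParams(**raw.pop("segmentation", {}))
        return cls(simulation=sim, segmentation=seg, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, out: Path) -> None:
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    log.info("simulate: n_participants=%d seed=%d", sim.n_participants, sim.seed)
    recordings, traces, truth = simulate_study(sim)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    trace_io.write_manifest(recordings, out / "manifest.csv")
    for rid, trace in traces.items():
        trace_io.write_trace(trace, out / "traces" / f"{rid}.csv")
    trace_io.write_annotations(truth.annotations, out / "ground_truth.json")
    truth.true_condition_means.to_csv(out / "true_means.csv", index=False)


def stage_detect(config: PipelineConfig, out: Path) -> None:
    recordings = trace_io.read_manifest(out / "manifest.csv")
    detected = {}
    for rec in recordings:
        path = out / "traces" / f"{rec.recording_id}.csv"
        try:
            trace = trace_io.read_trace(path, frame_rate=rec.frame_rate)
            seg = classify_blinks(
                detect_blink_periods(trace, config.segmentation), rec, trace
            )
        except (trace_io.TraceFormatError, ValidationError, OSError) as exc:
            raise PipelineError("detect", f"{path.name}: {exc}") from exc
        detected[rec.recording_id] = trace_io.AnnotationSet(
            events=[
                trace_io.BlinkAnnotation(
                    start_s=float(trace.time_s[e.start_idx]),
                    end_s=float(trace.time_s[e.end_idx]),
                    type=e.type,
                )
                for e in seg.events
            ],
            source="detected",
        )
    trace_io.write_annotations(detected, out / "detected_events.json")
    log.info("detect: %d recordings, %d events", len(recordings),
             sum(len(a.events) for a in detected.values()))


def _segmented_items(config: PipelineConfig, out: Path):
    recordings = trace_io.read_manifest(out / "manifest.csv")
    for rec in recordings:
        trace = trace_io.read_trace(out / "traces" / f"{rec.recording_id}.csv",
                                    frame_rate=rec.frame_rate)
        seg = classify_blinks(
            detect_blink_periods(trace, config.segmentation), rec, trace
        )
        yield rec, trace, seg


def stage_summarize(config: PipelineConfig, out: Path) -> None:
    rows = []
    for rec, trace, seg in _segmented_items(config, out):
        s = summarize_recording(trace, seg, rec)
        d = dataclasses.asdict(s)
        d["flags"] = ";".join(s.flags)
        rows.append(d)
    pd.DataFrame(rows).to_csv(out / "summaries.csv", index=False)
    log.info("summarize: %d recordings", len(rows))


def stage_analyze(config: PipelineConfig, out: Path) -> None:
    table = build_observation_table(_segmented_items(config, out))
    table.to_csv(out / "observations.csv", index=False)
    model = fit_ipf_mixed_model(table, include_unaffected=config.include_unaffected)
    (out / "ipf_model.json").write_text(json.dumps(model.to_dict(), indent=1))
    cmodel = fit_comfort_model(table)
    (out / "comfort_model.json").write_text(json.dumps(cmodel.to_dict(), indent=1))
    profiles = []
    for state in ("open", "spont_blink"):
        try:
            pr = profile_parallelism_test(table, state)
        except ValidationError:
            continue
        profiles.append(
            {"state": state, "F": pr.statistic, "df1": pr.df[0],
             "df2": pr.df[1], "p": pr.p}
        )
    pd.DataFrame(profiles).to_csv(out / "profile_tests.csv", index=False)
    conds = [c for c in ("baseline", *ANGLE_CONDITIONS)
             if (table["condition"] == c).any()]
    condition_means_table(model, conds).to_csv(out / "condition_means.csv",
                                               index=False)
    log.info("analyze: %d observations, model converged=%s",
             len(table), model.converged)


def stage_report(config: PipelineConfig, out: Path) -> None:
    means = pd.read_csv(out / "condition_means.csv")
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        for state, marker in (("open", "s"), ("spont_blink", "D")):
            sub = means[means["state"] == state]
            x = range(len(sub))
            ax.errorbar(
                x, sub["mean_mm"],
                yerr=[sub["mean_mm"] - sub["ci95_lo"],
                      sub["ci95_hi"] - sub["mean_mm"]],
                marker=marker, capsize=3, label=state, linestyle="none",
            )
            ax.set_xticks(list(x), sub["condition"], rotation=30)
        ax.set_ylabel("IPF (mm)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "condition_means.png", dpi=100)
        plt.close(fig)
    except Exception as exc:  # plotting is best-effort
        log.warning("report: plot skipped (%s)", exc)
    log.info("report: condition means table with %d rows", len(means))


STAGES = [
    ("simulate", stage_simulate),
    ("detect", stage_detect),
    ("summarize", stage_summarize),
    ("analyze", stage_analyze),
    ("report", stage_report),
]

_OUTPUTS = [
    "manifest.csv",
    "ground_truth.json",
    "detected_events.json",
    "summaries.csv",
    "observations.csv",
    "ipf_model.json",
    "comfort_model.json",
    "profile_tests.csv",
    "condition_means.csv",
]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a manifest of outputs with content hashes.

    Raises :class:`PipelineError` naming the failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    try:
        log.info("pipeline start: seed=%d out=%s", config.seed, out)
        for name, fn in STAGES:
            try:
                fn(config, out)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        manifest = {
            "seed": config.seed,
            "outputs": {
                f: _sha256(out / f) for f in _OUTPUTS if (out / f).exists()
            },
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
        log.info("pipeline done: %d outputs", len(manifest["outputs"]))
        return manifest
    finally:
        log.removeHandler(fh)
        fh.close()
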