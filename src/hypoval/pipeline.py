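"""Pipeline orchestration: simulate -> detect -> validate -> report.

``run_pipeline`` executes the full validation workflow from a single
configuration and writes delimited-text artifacts (burden, window labels,
alarm onsets, threshold metrics, ROC points) plus a run manifest recording
the configuration hash and seed, so a run is reproducible byte for byte.
``make_fixture`` builds deterministic miniature cohorts exercising each
labeling code path, for tests and examples.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .diagnostics import (
    ROCCurve,
    ThresholdMetrics,
    evaluate_thresholds,
    optimal_threshold,
)
from .errors import ConfigurationError, PipelineError
from .events import (
    MIN_EVENT_DURATION_S,
    PRESSURE_THRESHOLD_MMHG,
    cohort_burden,
    compute_burden,
    detect_censor_segments,
    detect_events,
)
from .forward import (
    DEFAULT_WINDOW_S,
    PatientThresholdSummary,
    ScreeningWindowLabel,
    ConfusionCounts,
    summarize_patient,
)
from .synthetic import GroundTruth, SimulationConfig, generate_cohort, simulate_patient
from .trace_io import CohortManifest, TraceRecord, read_manifest

logger = logging.getLogger("hypoval")


def parse_thresholds(spec: str) -> list[float]:
    """Parse a ``start:stop:step`` threshold grid, inclusive of both ends."""
    try:
        start, stop, step = (float(x) for x in spec.split(":"))
    except ValueError as exc:
        raise ConfigurationError(f"thresholds: expected 'start:stop:step', got {spec!r}") from exc
    if step <= 0 or stop < start:
        raise ConfigurationError(f"thresholds: need step > 0 and stop >= start, got {spec!r}")
    n = int(round((stop - start) / step))
    grid = [start + k * step for k in range(n + 1)]
    if grid[-1] > stop + 1e-9:
        grid.pop()
    return grid


@dataclass
class PipelineConfig:
    """Analysis parameters, all defaulted to the validation protocol's values."""

    outdir: str = "hypoval_run"
    manifest: str | None = None                      # existing cohort, or
    simulation: SimulationConfig | None = None       # simulate one
    pressure_threshold: float = PRESSURE_THRESHOLD_MMHG
    min_event_duration: float = MIN_EVENT_DURATION_S
    window: float = DEFAULT_WINDOW_S
    thresholds: str = "0:100:5"
    censoring: bool = True
    negative_preemption: bool = True
    aut_mode: str = "events"
    replicates: int = 100_000
    bootstrap_seed: int = 0

    def __post_init__(self) -> None:
        if self.manifest is None and self.simulation is None:
            raise ConfigurationError("config needs either 'manifest' or a 'simulation' block")
        if self.aut_mode not in ("events", "all"):
            raise ConfigurationError(f"aut_mode: must be 'events' or 'all', got {self.aut_mode!r}")
        if self.replicates < 1:
            raise ConfigurationError(f"replicates: must be >= 1, got {self.replicates!r}")
        if self.min_event_duration <= 0 or self.window <= 0 or self.pressure_threshold <= 0:
            raise ConfigurationError("pressure_threshold, min_event_duration and window must be > 0")
        parse_thresholds(self.thresholds)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunSummary:
    """Artifact paths and headline metrics of one pipeline run."""

    paths: dict[str, str]
    auc: float | None
    optimal_threshold: float | None
    metrics_at_optimal: ThresholdMetrics | None
    stage_counts: dict[str, int] = field(default_factory=dict)


def _load_records(config: PipelineConfig, outdir: Path
                  ) -> tuple[list[TraceRecord], dict[str, GroundTruth] | None]:
    if config.simulation is not None:
        manifest, truths = generate_cohort(config.simulation, outdir / "cohort")
        records = list(manifest.iter_records())
        return records, truths
    manifest = read_manifest(config.manifest)
    return list(manifest.iter_records()), None


def run_pipeline(config: PipelineConfig) -> RunSummary:
    """Execute all stages and write the output files; see the module docstring."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = parse_thresholds(config.thresholds)
    paths: dict[str, str] = {}
    stage_counts: dict[str, int] = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    records, _truths = stage("load", lambda: _load_records(config, outdir))
    stage_counts["patients"] = len(records)
    logger.info("loaded %d patient record(s)", len(records))

    def detect():
        per_events, per_censors, burdens = {}, {}, []
        for rec in records:
            evs = detect_events(rec, config.pressure_threshold, config.min_event_duration)
            cens = detect_censor_segments(rec)
            per_events[rec.patient_id] = evs
            per_censors[rec.patient_id] = cens
            burdens.append(compute_burden(rec, evs, aut_mode=config.aut_mode))
        return per_events, per_censors, burdens

    per_events, per_censors, burdens = stage("detect", detect)
    stage_counts["events"] = sum(len(v) for v in per_events.values())
    stage_counts["censor_segments"] = sum(len(v) for v in per_censors.values())
    logger.info("detected %d event(s), %d censor segment(s)",
                stage_counts["events"], stage_counts["censor_segments"])

    def write_burden():
        rows = [vars(b) for b in burdens]
        summary = cohort_burden(burdens)
        df = pd.DataFrame(rows)
        for stat in ("median", "q25", "q75"):
            df.loc[len(df)] = {"patient_id": f"cohort:{stat}",
                               **{k[: -len(stat) - 1]: v for k, v in summary.items()
                                  if k.endswith("_" + stat)}}
        df.loc[len(df)] = {"patient_id": "cohort:total",
                           "monitoring_time": summary["monitoring_time_total"],
                           "n_events": summary["n_events_total"],
                           "hypo_duration": summary["hypo_duration_total"]}
        p = outdir / "burden.csv"
        df.to_csv(p, index=False, float_format="%.4f")
        paths["burden"] = str(p)
        # intervals file: events and censor spans
        iv_rows = [
            {"patient_id": pid, "kind": "event", "start_s": ev.onset_s, "end_s": ev.end_s}
            for pid, evs in per_events.items() for ev in evs
        ] + [
            {"patient_id": pid, "kind": "censor", "start_s": cs.start_s, "end_s": cs.end_s}
            for pid, cks in per_censors.items() for cs in cks
        ]
        pi = outdir / "intervals.csv"
        pd.DataFrame(iv_rows, columns=["patient_id", "kind", "start_s", "end_s"]
                     ).to_csv(pi, index=False, float_format="%.1f")
        paths["intervals"] = str(pi)

    stage("burden", write_burden)

    def label():
        summaries: dict[float, list[PatientThresholdSummary]] = {t: [] for t in thresholds}
        label_rows, alarm_rows = [], []
        n_discarded = 0
        for rec in records:
            summ, labels = summarize_patient(
                rec, per_events[rec.patient_id], per_censors[rec.patient_id], thresholds,
                window=config.window, censoring=config.censoring,
                negative_preemption=config.negative_preemption)
            for thr in thresholds:
                summaries[thr].append(summ[thr])
                for lab in labels[thr]:
                    n_discarded += lab.label == "DISCARDED"
                    label_rows.append({
                        "patient_id": rec.patient_id, "threshold": thr,
                        "start_s": lab.window_start, "end_s": lab.window_end,
                        "label": lab.label,
                        "time_to_event_s": "" if lab.time_to_event is None else lab.time_to_event,
                        "censored_overlap": int(lab.censored_overlap),
                        "reason": lab.reason or ""})
                alarm_rows.append({"patient_id": rec.patient_id, "threshold": thr,
                                   "n_alarms": summ[thr].n_alarms,
                                   "n_alarms_followed": summ[thr].n_alarms_followed})
        pl = outdir / "labels.csv"
        pd.DataFrame(label_rows).to_csv(pl, index=False)
        paths["labels"] = str(pl)
        pa = outdir / "alarms.csv"
        pd.DataFrame(alarm_rows).to_csv(pa, index=False)
        paths["alarms"] = str(pa)
        return summaries, len(label_rows), n_discarded

    summaries, n_windows, n_discarded = stage("validate", label)
    stage_counts["windows"] = n_windows
    stage_counts["windows_discarded"] = n_discarded
    logger.info("labeled %d window(s) across %d threshold(s); %d discarded",
                n_windows, len(thresholds), n_discarded)

    def report():
        metrics, roc = evaluate_thresholds(summaries, n_replicates=config.replicates,
                                           seed=config.bootstrap_seed)
        pm = outdir / "metrics.csv"
        metrics_frame(metrics).to_csv(pm, index=False, float_format="%.6f")
        paths["metrics"] = str(pm)
        if roc is not None:
            pr = outdir / "roc.csv"
            with open(pr, "w") as fh:
                fh.write(f"# auc,{roc.auc.value:.6f},{roc.auc.lower:.6f},{roc.auc.upper:.6f}\n")
                fh.write("fpr,sensitivity\n")
                for x, y in roc.points:
                    fh.write(f"{x:.6f},{y:.6f}\n")
            paths["roc"] = str(pr)
        return metrics, roc

    metrics, roc = stage("report", report)

    try:
        opt = optimal_threshold(metrics)
        at_opt = next(m for m in metrics if m.threshold == opt)
    except Exception:
        opt, at_opt = None, None
    summary = RunSummary(paths=paths, auc=None if roc is None else roc.auc.value,
                         optimal_threshold=opt, metrics_at_optimal=at_opt,
                         stage_counts=stage_counts)

    run_manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "bootstrap_seed": config.bootstrap_seed,
        "stage_counts": stage_counts,
        "auc": summary.auc,
        "optimal_threshold": opt,
        "paths": paths,
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2)
    paths["run_manifest"] = str(outdir / "run_manifest.json")
    return summary


def _est_cols(name: str, est) -> dict[str, float | str]:
    if est is None:
        return {name: "", f"{name}_lo": "", f"{name}_hi": ""}
    return {name: est.value, f"{name}_lo": est.lower, f"{name}_hi": est.upper}


def metrics_frame(metrics: list[ThresholdMetrics]) -> pd.DataFrame:
    """Tabular form of the threshold metrics (one row per threshold)."""
    rows = []
    for m in metrics:
        row: dict = {"threshold": m.threshold, "tp": m.counts.tp, "fp": m.counts.fp,
                     "tn": m.counts.tn, "fn": m.counts.fn}
        for name in ("sensitivity", "specificity", "youden_j", "ppv", "npv",
                     "time_to_event", "event_rate"):
            row.update(_est_cols(name, getattr(m, name)))
        rows.append(row)
    return pd.DataFrame(rows)


# -- miniature fixtures -----------------------------------------------------

_FIXTURE_KINDS = ("perfect_oracle", "noisy", "no_events", "artifact_heavy")


def make_fixture(kind: str, seed: int = 0
                 ) -> tuple[list[TraceRecord], dict[str, GroundTruth], SimulationConfig]:
    """Deterministic miniature cohorts (4 patients x 2 h) for tests and demos.

    ``perfect_oracle``: noise-free index with a 20-min look-ahead — the
    pipeline should recover perfect diagnostics.  ``noisy``: misses,
    false-alarm bursts and additive noise populate all four confusion cells.
    ``no_events``: episode rate zero.  ``artifact_heavy``: every episode ends
    in a vasopressor-like rescue, so every patient has censor segments.
    """
    if kind not in _FIXTURE_KINDS:
        raise ConfigurationError(f"kind: unknown fixture {kind!r}; choose from {_FIXTURE_KINDS}")
    base = SimulationConfig(
        n_patients=4, duration_per_patient=2 * 3600.0, episode_rate=2.0,
        episode_depth_mean=6.0, episode_depth_sd=1.5,
        episode_duration_mean=240.0, episode_duration_sd=60.0,
        index_noise_sd=0.0, miss_probability=0.0, false_alarm_rate=0.0,
        artifact_probability=0.0, rng_seed=seed)
    overrides = {
        "perfect_oracle": dict(index_horizon=1200.0),
        "noisy": dict(index_noise_sd=3.0, miss_probability=0.25, false_alarm_rate=1.5,
                      index_horizon=300.0),
        "no_events": dict(episode_rate=0.0),
        "artifact_heavy": dict(artifact_probability=1.0, episode_rate=3.0),
    }[kind]
    config = base.replace(**overrides)
    records, truths = [], {}
    for i in range(1, config.n_patients + 1):
        pid = f"P{i:03d}"
        rec, truth = simulate_patient(config, pid)
        records.append(rec)
        truths[pid] = truth
    return records, truths, config
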