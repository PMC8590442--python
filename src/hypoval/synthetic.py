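"""Synthetic ICU cohort generator.

Produces multi-hour mean-arterial-pressure traces with ground-truth
hypotensive episodes, a transparent surrogate predictive index, and
vasopressor-like rescue artifacts.  The generator emulates the statistical
shape of an ICU validation cohort — a mean-reverting baseline around
75 mmHg, episodic excursions below the 65 mmHg hypotension threshold at a
Poisson rate of a fraction of an event per hour, and an index whose
elevation precedes each episode by minutes — so the downstream labeling and
diagnostics can be exercised end-to-end with a known answer.

The surrogate index is deliberately simple and fully transparent::

    index(t) = 100 * logistic(gain * (65 - min pressure over [t, t + horizon)))

plus optional Gaussian noise, clipped to [0, 100].  Imperfection is injected
through three explicit mechanisms: per-episode *misses* (the index fails to
anticipate an episode), *false-alarm bursts* at Poisson times, and additive
noise.  Each mechanism is recorded in the ground truth so tests can compare
recovered diagnostics against construction values.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit

from .errors import AlignmentError, ConfigurationError
from .trace_io import (
    CohortManifest,
    TraceRecord,
    write_manifest,
    write_trace,
)

HYPOTENSION_THRESHOLD_MMHG = 65.0

#: pre-onset descent from baseline to the hypotension threshold, seconds
_PRE_RAMP_S = 60.0
#: in-episode descent from threshold to nadir, seconds
_DOWN_RAMP_S = 60.0
#: natural recovery slope, mmHg per 20-s step; slow enough that an
#: uninterrupted recovery never trips the intervention-censoring rules
_RECOVERY_STEP_MMHG = 1.0


@dataclass
class SimulationConfig:
    """Full parameterization of a synthetic cohort.

    Defaults describe the study conditions the generator emulates: 41
    patients monitored ~70 h each at a 20-s cadence, a hypotensive-episode
    rate of 0.3/h (≈ 21 events per patient), episodes reaching a median of
    ~5 mmHg below the 65 mmHg threshold for ~5 min, and a surrogate index
    that looks 5 min ahead with mild noise, a 5% per-episode miss rate and
    occasional false-alarm bursts.
    """

    n_patients: int = 41
    duration_per_patient: float = 70 * 3600.0  # seconds
    sample_interval: float = 20.0              # seconds
    map_baseline_mean: float = 75.0            # mmHg
    map_baseline_sd: float = 1.5               # mmHg (stationary sd of the AR(1) baseline)
    map_mean_reversion: float = 0.9            # AR(1) coefficient, per sample
    episode_rate: float = 0.3                  # events per hour (0 allowed: no episodes)
    episode_depth_mean: float = 5.0            # mmHg below 65
    episode_depth_sd: float = 2.0
    episode_duration_mean: float = 300.0       # seconds below 65
    episode_duration_sd: float = 120.0
    index_horizon: float = 300.0               # seconds the surrogate looks ahead
    index_gain: float = 1.0                    # logistic slope, per mmHg
    index_noise_sd: float = 5.0                # index units
    miss_probability: float = 0.05             # per-episode chance the index fails to anticipate
    false_alarm_rate: float = 0.2              # spurious index bursts per hour
    false_alarm_duration: float = 120.0        # seconds per burst
    false_alarm_levels: tuple[float, float] = (10.0, 100.0)  # burst level drawn uniformly
    artifact_probability: float = 0.1          # per-episode chance of a vasopressor-like rescue
    artifact_rise: float = 6.0                 # mmHg per 20-s step during a rescue
    min_episode_gap: float = 60.0              # enforced quiet gap between episode footprints, s
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def require(cond: bool, name: str, why: str) -> None:
            if not cond:
                raise ConfigurationError(f"{name}: {why} (got {getattr(self, name)!r})")

        require(self.n_patients >= 1, "n_patients", "must be >= 1")
        require(self.duration_per_patient > 0, "duration_per_patient", "must be > 0")
        require(self.sample_interval > 0, "sample_interval", "must be > 0")
        n = self.duration_per_patient / self.sample_interval
        require(abs(n - round(n)) < 1e-9, "sample_interval", "must divide duration_per_patient")
        require(self.map_baseline_mean > HYPOTENSION_THRESHOLD_MMHG, "map_baseline_mean",
                "must exceed the 65 mmHg hypotension threshold")
        require(self.map_baseline_sd >= 0, "map_baseline_sd", "must be >= 0")
        require(0 < self.map_mean_reversion < 1, "map_mean_reversion", "must lie in (0, 1)")
        require(self.episode_rate >= 0, "episode_rate", "must be >= 0")
        require(self.episode_depth_mean > 0, "episode_depth_mean", "must be > 0")
        require(self.episode_depth_sd >= 0, "episode_depth_sd", "must be >= 0")
        require(self.episode_duration_mean >= 60, "episode_duration_mean",
                "must be >= 60 s so injected episodes qualify as events")
        require(self.episode_duration_sd >= 0, "episode_duration_sd", "must be >= 0")
        require(self.index_horizon >= self.sample_interval, "index_horizon",
                "must cover at least one sample")
        require(self.index_gain > 0, "index_gain", "must be > 0")
        require(self.index_noise_sd >= 0, "index_noise_sd", "must be >= 0")
        require(0 <= self.miss_probability <= 1, "miss_probability", "must lie in [0, 1]")
        require(self.false_alarm_rate >= 0, "false_alarm_rate", "must be >= 0")
        require(self.false_alarm_duration > 0, "false_alarm_duration", "must be > 0")
        lo, hi = self.false_alarm_levels
        require(0 <= lo <= hi <= 100, "false_alarm_levels", "must satisfy 0 <= lo <= hi <= 100")
        require(0 <= self.artifact_probability <= 1, "artifact_probability", "must lie in [0, 1]")
        require(self.artifact_rise >= 5.0, "artifact_rise",
                "must be >= 5 mmHg per step to model an abrupt rescue")
        require(self.min_episode_gap >= 0, "min_episode_gap", "must be >= 0")
        require(isinstance(self.rng_seed, (int, np.integer)), "rng_seed", "must be an integer")

    @property
    def n_samples(self) -> int:
        return round(self.duration_per_patient / self.sample_interval)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["false_alarm_levels"] = list(d["false_alarm_levels"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "false_alarm_levels" in d:
            d["false_alarm_levels"] = tuple(d["false_alarm_levels"])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class Episode:
    """One injected hypotensive episode (ground truth)."""

    onset_s: float          # first sample strictly below 65 mmHg
    end_s: float            # first sample at/above 65 mmHg again
    depth: float            # mmHg below 65 at the nadir
    missed: bool = False    # index fails to anticipate this episode
    rescued: bool = False   # terminated by an abrupt vasopressor-like rise


@dataclass
class GroundTruth:
    """Injected episodes and artifact spans for one patient."""

    episodes: list[Episode] = field(default_factory=list)
    artifacts: list[tuple[float, float]] = field(default_factory=list)


def _patient_ordinal(patient_id) -> int:
    """Stable per-patient ordinal used to derive the patient's RNG substream."""
    if isinstance(patient_id, (int, np.integer)):
        return int(patient_id)
    m = re.search(r"(\d+)$", str(patient_id))
    if m is None:
        raise ConfigurationError(
            f"patient_id: need an integer or an identifier with a trailing number (got {patient_id!r})"
        )
    return int(m.group(1))


def _patient_rng(config: SimulationConfig, patient_id, stream: int) -> np.random.Generator:
    # independent, individually reproducible substreams per patient and channel
    return np.random.default_rng([config.rng_seed, _patient_ordinal(patient_id), stream])


def _episode_profile(config: SimulationConfig, depth: float, duration: float,
                     rescued: bool) -> np.ndarray:
    """Pressure values of one episode footprint, starting one pre-ramp before onset.

    Shape: linear descent from baseline to the 65 mmHg threshold over 60 s,
    linear descent to the nadir over 60 s, a plateau sized so the sub-65 span
    approximates ``duration``, then either a slow natural recovery (+1 mmHg
    per step, which never trips the censoring rules) or an abrupt rescue
    (+``artifact_rise`` mmHg per step) back to baseline.
    """
    iv = config.sample_interval
    bm = config.map_baseline_mean
    thr = HYPOTENSION_THRESHOLD_MMHG
    nadir = thr - depth
    pre_n = max(1, round(_PRE_RAMP_S / iv))
    down_n = max(1, round(_DOWN_RAMP_S / iv))
    pre = [thr + (bm - thr) * j / (pre_n + 1) for j in range(pre_n, 0, -1)]
    down = [thr - depth * k / (down_n + 1) for k in range(1, down_n + 1)]
    step = config.artifact_rise if rescued else _RECOVERY_STEP_MMHG
    recovery: list[float] = []
    v = nadir + step
    while v < bm:
        recovery.append(v)
        v += step
    n_rec_sub65 = sum(1 for v in recovery if v < thr)
    plateau_n = max(1, round(duration / iv) - len(down) - n_rec_sub65)
    return np.array(pre + down + [nadir] * plateau_n + recovery), pre_n


def simulate_map_trace(config: SimulationConfig, patient_id) -> tuple[TraceRecord, GroundTruth]:
    """Simulate one patient's pressure series with ground-truth episodes.

    The baseline is a stationary AR(1) process around ``map_baseline_mean``.
    Episodes arrive at Poisson times (rate ``episode_rate`` per hour); an
    arrival that would overlap the previous episode's footprint is shifted to
    the first free slot, so the injected count stays Poisson apart from a
    small end-of-trace loss.  Pressures are rounded to 0.1 mmHg so the series
    round-trips exactly through the trace file format.  Deterministic for a
    fixed seed and patient id; the returned index channel is all-missing
    (fill it with :func:`simulate_index`).
    """
    config.validate()
    rng = _patient_rng(config, patient_id, stream=0)
    iv = config.sample_interval
    n = config.n_samples
    t = np.arange(n) * iv

    phi = config.map_mean_reversion
    innov = rng.normal(0.0, config.map_baseline_sd * math.sqrt(1.0 - phi * phi), n)
    x = lfilter([1.0], [1.0, -phi], innov)
    x += rng.normal(0.0, config.map_baseline_sd) * phi ** np.arange(n)  # stationary start
    pressure = config.map_baseline_mean + x

    truth = GroundTruth()
    if config.episode_rate > 0:
        rate_per_s = config.episode_rate / 3600.0
        arrivals = []
        tt = rng.exponential(1.0 / rate_per_s)
        while tt < config.duration_per_patient:
            arrivals.append(tt)
            tt += rng.exponential(1.0 / rate_per_s)
        next_free = _PRE_RAMP_S + iv
        for arrival in arrivals:
            depth = float(np.clip(rng.normal(config.episode_depth_mean, config.episode_depth_sd),
                                  2.0, 45.0))
            duration = max(60.0, float(rng.normal(config.episode_duration_mean,
                                                  config.episode_duration_sd)))
            rescued = bool(rng.random() < config.artifact_probability)
            missed = bool(rng.random() < config.miss_probability)
            onset_s = max(arrival, next_free)
            onset_i = round(onset_s / iv)
            profile, pre_n = _episode_profile(config, depth, duration, rescued)
            profile = np.round(profile, 1)  # trace precision; keeps ground truth exact
            start_i = onset_i - pre_n
            stop_i = start_i + len(profile)
            if start_i < 1 or stop_i > n - 1:
                continue  # no room before trace end; episode dropped
            pressure[start_i:stop_i] = profile
            sub65 = np.flatnonzero(profile < HYPOTENSION_THRESHOLD_MMHG)
            ep_onset = t[start_i + sub65[0]]
            ep_end = t[start_i + sub65[-1] + 1]
            truth.episodes.append(Episode(ep_onset, ep_end, depth, missed=missed, rescued=rescued))
            if rescued:
                # rise starts from the last nadir sample; record until back at baseline
                last_nadir = start_i + sub65[np.flatnonzero(profile[sub65] == profile[sub65].min())[-1]]
                truth.artifacts.append((t[last_nadir], t[min(stop_i, n - 1)]))
            next_free = t[stop_i - 1] + iv + config.min_episode_gap + _PRE_RAMP_S
        truth.episodes.sort(key=lambda e: e.onset_s)

    pressure = np.round(pressure, 1)
    df = pd.DataFrame({"time_s": t, "map_mmhg": pressure, "index": np.nan})
    return TraceRecord(patient_id=str(patient_id), samples=df,
                       sample_interval=iv), truth


def index_from_future_min(future_min: np.ndarray | float, gain: float) -> np.ndarray | float:
    """Noise-free surrogate index: ``100 * logistic(gain * (65 - future_min))``."""
    return 100.0 * expit(gain * (HYPOTENSION_THRESHOLD_MMHG - np.asarray(future_min, float)))


def _forward_min(values: np.ndarray, width: int) -> np.ndarray:
    """Minimum over the half-open forward window of ``width`` samples, truncated at the end."""
    n = values.size
    padded = np.concatenate([values, np.full(width - 1, np.inf)])
    view = np.lib.stride_tricks.sliding_window_view(padded, width)[:n]
    return view.min(axis=1)


def simulate_index(pressure: np.ndarray, ground_truth: GroundTruth, config: SimulationConfig,
                   patient_id=0, times: np.ndarray | None = None) -> np.ndarray:
    """Surrogate predictive index for a simulated pressure series.

    The noise-free index at sample ``t`` is a logistic transform of how far
    the minimum pressure over the half-open look-ahead window
    ``[t, t + index_horizon)`` falls below 65 mmHg.  Episodes flagged as
    *missed* in the ground truth are hidden from the look-ahead (their span is
    replaced by the baseline mean), false-alarm bursts raise the index to a
    random level for ``false_alarm_duration`` seconds at Poisson times, and
    Gaussian noise with sd ``index_noise_sd`` is added before clipping to
    [0, 100].  Values are rounded to 0.01 so they round-trip through the
    trace format.  Deterministic for a fixed seed and patient id.
    """
    config.validate()
    iv = config.sample_interval
    pressure = np.asarray(pressure, float)
    n = pressure.size
    if times is not None:
        times = np.asarray(times, float)
        if times.shape != pressure.shape:
            raise AlignmentError("times and pressure differ in length")
        if n > 1 and not np.allclose(np.diff(times), iv):
            raise AlignmentError(f"series is not aligned to the {iv:g}-s sampling grid")
    rng = _patient_rng(config, patient_id, stream=1)

    effective = pressure.copy()
    for ep in ground_truth.episodes:
        if ep.missed:
            a, b = round(ep.onset_s / iv), round(ep.end_s / iv)
            effective[a:b] = config.map_baseline_mean

    width = round(config.index_horizon / iv)
    raw = np.asarray(index_from_future_min(_forward_min(effective, max(1, width)),
                                           config.index_gain))

    if config.false_alarm_rate > 0:
        rate_per_s = config.false_alarm_rate / 3600.0
        dur_n = max(1, round(config.false_alarm_duration / iv))
        tt = rng.exponential(1.0 / rate_per_s)
        while tt < n * iv:
            level = rng.uniform(*config.false_alarm_levels)
            a = round(tt / iv)
            raw[a:a + dur_n] = np.maximum(raw[a:a + dur_n], level)
            tt += rng.exponential(1.0 / rate_per_s)

    if config.index_noise_sd > 0:
        raw = raw + rng.normal(0.0, config.index_noise_sd, n)
    return np.round(np.clip(raw, 0.0, 100.0), 2)


def simulate_patient(config: SimulationConfig, patient_id) -> tuple[TraceRecord, GroundTruth]:
    """Simulate a complete patient record (pressure plus index channel)."""
    record, truth = simulate_map_trace(config, patient_id)
    idx = simulate_index(record.pressure, truth, config, patient_id=patient_id,
                         times=record.times)
    record.samples["index"] = idx
    return record, truth


def generate_cohort(config: SimulationConfig, outdir: str | Path
                    ) -> tuple[CohortManifest, dict[str, GroundTruth]]:
    """Write one trace file per patient plus a cohort manifest.

    Patient ids are ``P001`` .. ``P{n}``; each patient's series derives from
    its own RNG substream, so regeneration with the same config is
    byte-identical.  Returns the manifest and the per-patient ground truth.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows, truths = [], {}
    for i in range(1, config.n_patients + 1):
        pid = f"P{i:03d}"
        record, truth = simulate_patient(config, pid)
        fname = f"{pid}.csv"
        write_trace(record, outdir / fname)
        rows.append({"patient_id": pid, "path": fname,
                     "duration_s": record.monitored_seconds})
        truths[pid] = truth
    manifest = CohortManifest(entries=pd.DataFrame(rows),
                              provenance="synthetic cohort generated by hypoval",
                              seed=config.rng_seed, root=outdir)
    write_manifest(manifest, outdir / "manifest.csv")
    return manifest, truths
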