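"""Reading, writing and validation of patient trace files and cohort manifests.

A trace is a delimited text file with header ``time_s,map_mmhg,index``: one row
per 20-s sample of mean arterial pressure (MAP, mmHg) and a 0-100 predictive
index.  Time is in seconds from record start.  The index column may be empty;
such samples participate in hypotension detection but not alarm detection.

Recording gaps longer than 60 s split a record into segments.  All downstream
windows and events are computed per segment, never across a gap, because a
one-minute qualification rule cannot be evaluated across missing data.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CohortError, TraceDataError, TraceFormatError

logger = logging.getLogger("hypoval")

TRACE_COLUMNS = ("time_s", "map_mmhg", "index")

#: nominal sampling cadence of the pressure/index channels, seconds
DEFAULT_SAMPLE_INTERVAL = 20.0

#: inter-sample gaps strictly longer than this split a record into segments
GAP_THRESHOLD_S = 60.0

# numeric formatting used on write (pressure to 0.1 mmHg, index to 0.01)
_TIME_FMT = "%.1f"
_PRESSURE_FMT = "%.1f"
_INDEX_FMT = "%.2f"


@dataclass
class TraceRecord:
    """One patient's aligned pressure/index series.

    Parameters
    ----------
    patient_id:
        Identifier, unique within a cohort.
    samples:
        DataFrame with columns ``time_s``, ``map_mmhg``, ``index``; index
        values may be NaN (missing).
    sample_interval:
        Nominal spacing between samples within a segment, seconds.
    gap_threshold:
        Gaps strictly greater than this split the record into segments.
    """

    patient_id: str
    samples: pd.DataFrame
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL
    gap_threshold: float = GAP_THRESHOLD_S

    def __post_init__(self) -> None:
        missing = [c for c in TRACE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise TraceFormatError(f"trace for {self.patient_id!r} lacks columns {missing}")
        df = self.samples.loc[:, list(TRACE_COLUMNS)].reset_index(drop=True)
        for col in TRACE_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        t = df["time_s"].to_numpy(float)
        if t.size and np.isnan(t).any():
            raise TraceDataError(f"{self.patient_id}: non-numeric time values")
        decreasing = np.flatnonzero(np.diff(t) < 0)
        if decreasing.size:
            row = int(decreasing[0]) + 1
            raise TraceDataError(
                f"{self.patient_id}: non-monotone time at row {row} "
                f"(t={t[row]:g} after t={t[row - 1]:g})"
            )
        self.samples = df

    # -- array views --------------------------------------------------------
    @property
    def times(self) -> np.ndarray:
        return self.samples["time_s"].to_numpy(float)

    @property
    def pressure(self) -> np.ndarray:
        return self.samples["map_mmhg"].to_numpy(float)

    @property
    def index(self) -> np.ndarray:
        return self.samples["index"].to_numpy(float)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def segments(self) -> list[tuple[int, int]]:
        """Half-open ``(start, stop)`` sample-index ranges between recording gaps."""
        t = self.times
        if t.size == 0:
            return []
        breaks = np.flatnonzero(np.diff(t) > self.gap_threshold) + 1
        bounds = np.concatenate(([0], breaks, [t.size]))
        return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]

    @property
    def monitored_seconds(self) -> float:
        """Total monitored time: per segment, last minus first sample plus one interval."""
        t = self.times
        return float(
            sum(t[b - 1] - t[a] + self.sample_interval for a, b in self.segments)
        )


@dataclass
class Finding:
    """One validation finding: the sample time it concerns, the field and a message."""

    time_s: float
    field: str
    message: str


def validate_trace(record: TraceRecord) -> list[Finding]:
    """Report-only checks of the soft range invariants.

    Flags pressures outside the physiologically plausible 10-250 mmHg band
    (non-positive pressures are reported as invalid), index values outside
    [0, 100], and duplicate timestamps.  Clean records yield an empty list.
    """
    findings: list[Finding] = []
    t, p, x = record.times, record.pressure, record.index
    for i in np.flatnonzero(~np.isnan(p) & (p <= 0)):
        findings.append(Finding(t[i], "map_mmhg", f"non-positive pressure {p[i]:g} mmHg"))
    for i in np.flatnonzero(~np.isnan(p) & (p > 0) & ((p < 10) | (p > 250))):
        findings.append(Finding(t[i], "map_mmhg", f"pressure {p[i]:g} mmHg outside 10-250 mmHg"))
    for i in np.flatnonzero(~np.isnan(x) & ((x < 0) | (x > 100))):
        findings.append(Finding(t[i], "index", f"index {x[i]:g} outside [0, 100]"))
    for i in np.flatnonzero(np.diff(t) == 0) + 1:
        findings.append(Finding(t[i], "time_s", f"duplicate timestamp {t[i]:g}"))
    return findings


def read_trace(path: str | Path, patient_id: str | None = None) -> TraceRecord:
    """Read and validate a trace file.

    Samples with unparseable time or pressure are dropped with a logged count;
    a missing index value is kept as NaN.  Raises :class:`TraceFormatError`
    when required columns are absent and :class:`TraceDataError` on
    non-monotone time.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise TraceFormatError(f"{path}: empty file, expected header {TRACE_COLUMNS}") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing columns {missing}")
    for col in TRACE_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df["time_s"].isna() | df["map_mmhg"].isna()
    if bad.any():
        logger.warning("%s: dropped %d unparseable sample(s)", path.name, int(bad.sum()))
        df = df.loc[~bad]
    pid = patient_id if patient_id is not None else path.stem
    return TraceRecord(patient_id=pid, samples=df.reset_index(drop=True))


def write_trace(record: TraceRecord, path: str | Path) -> None:
    """Write a trace file; pressures are formatted to 0.1 mmHg, index to 0.01."""
    path = Path(path)
    t, p, x = record.times, record.pressure, record.index
    with open(path, "w", newline="") as fh:
        fh.write(",".join(TRACE_COLUMNS) + "\n")
        for i in range(record.n_samples):
            xi = "" if np.isnan(x[i]) else _INDEX_FMT % x[i]
            fh.write(f"{_TIME_FMT % t[i]},{_PRESSURE_FMT % p[i]},{xi}\n")


# -- cohort manifests -------------------------------------------------------

@dataclass
class CohortManifest:
    """List of patient traces plus provenance.

    ``entries`` has columns ``patient_id``, ``path``, ``duration_s``; paths
    are stored relative to the manifest file (or absolute).
    """

    entries: pd.DataFrame
    provenance: str = ""
    seed: int | None = None
    root: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        need = {"patient_id", "path", "duration_s"}
        if not need.issubset(self.entries.columns):
            raise TraceFormatError(f"manifest lacks columns {sorted(need - set(self.entries.columns))}")
        ids = self.entries["patient_id"].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise CohortError(f"duplicate patient_id {dup!r} in manifest")

    def resolve(self, path: str) -> Path:
        p = Path(path)
        return p if p.is_absolute() else self.root / p

    def iter_records(self):
        """Yield :class:`TraceRecord` for every manifest entry."""
        for row in self.entries.itertuples(index=False):
            yield read_trace(self.resolve(row.path), patient_id=str(row.patient_id))


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if manifest.provenance:
            fh.write(f"# provenance: {manifest.provenance}\n")
        if manifest.seed is not None:
            fh.write(f"# seed: {manifest.seed}\n")
        fh.write("patient_id,path,duration_s\n")
        for row in manifest.entries.itertuples(index=False):
            fh.write(f"{row.patient_id},{row.path},{row.duration_s:.1f}\n")


def read_manifest(path: str | Path, check_paths: bool = True) -> CohortManifest:
    """Load a cohort manifest; every listed trace path must resolve."""
    path = Path(path)
    provenance, seed = "", None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("provenance:"):
                provenance = body.split(":", 1)[1].strip()
            elif body.startswith("seed:"):
                seed = int(body.split(":", 1)[1])
    df = pd.read_csv(path, comment="#")
    manifest = CohortManifest(entries=df, provenance=provenance, seed=seed, root=path.parent)
    if check_paths:
        for row in df.itertuples(index=False):
            p = manifest.resolve(row.path)
            if not p.exists():
                raise CohortError(f"manifest entry {row.patient_id!r}: file not found: {p}")
    return manifest
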