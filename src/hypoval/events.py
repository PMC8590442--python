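"""Hypotensive-event detection, intervention censoring, and burden statistics.

A hypotensive event is a MAP below 65 mmHg sustained for at least one minute;
at a 20-s cadence that is three or more consecutive sub-threshold samples,
with the event ending at the first sample at which MAP reaches 65 mmHg again.
Spans showing an abrupt pressure rise from a sub-70 mmHg baseline (>= 5 mmHg
within 20 s, or >= 8 mmHg within 2 min) are attributed to clinical
interventions such as vasopressor boluses or positional maneuvers and are
flagged for censoring.  Censoring affects only the labeling of screening
windows downstream; event detection and burden statistics always use the
uncensored series.

Burden statistics follow the usual depth-times-duration summaries: the area
under the 65 mmHg threshold (AUT, mmHg*min) and the time-weighted average
(TWA = AUT / monitoring time, mmHg), which normalizes exposure to case
length.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CohortError
from .trace_io import TraceRecord

#: hypotension definition: MAP below this for at least MIN_EVENT_DURATION_S
PRESSURE_THRESHOLD_MMHG = 65.0
MIN_EVENT_DURATION_S = 60.0

#: censoring rules: abrupt rises from a baseline below this are intervention-like
CENSOR_BASELINE_MMHG = 70.0
CENSOR_RISE_20S_MMHG = 5.0
CENSOR_RISE_2MIN_MMHG = 8.0
CENSOR_LOOKAHEAD_S = 120.0

RULE_20S = "rise_20s"
RULE_2MIN = "rise_2min"


@dataclass
class HypotensionEvent:
    """A qualifying sub-threshold excursion.

    ``onset_s`` is the first sub-threshold sample; ``end_s`` the first sample
    at which pressure reaches the threshold again (or the segment end plus
    one interval when recording stops mid-event).  ``depth_area`` is the
    event's contribution to the AUT in mmHg*min.
    """

    onset_s: float
    end_s: float
    depth_area: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.onset_s


@dataclass
class CensorSegment:
    """A span flagged as intervention-influenced; ``rules`` names the rise rule(s) that fired."""

    start_s: float
    end_s: float
    rules: frozenset[str]


@dataclass
class BurdenStats:
    """Per-patient hypotension burden (all durations in minutes)."""

    patient_id: str
    monitoring_time: float  # minutes
    n_events: int
    hypo_duration: float    # minutes
    hypo_percent: float     # % of case time
    aut: float              # mmHg*min
    twa: float              # mmHg


def detect_events(record: TraceRecord,
                  pressure_threshold: float = PRESSURE_THRESHOLD_MMHG,
                  min_duration: float = MIN_EVENT_DURATION_S) -> list[HypotensionEvent]:
    """Detect qualifying hypotensive events, per recording segment.

    Maximal runs of consecutive samples with pressure strictly below the
    threshold qualify when their span (onset sample to first recovered
    sample) is at least ``min_duration``.
    """
    iv = record.sample_interval
    t, p = record.times, record.pressure
    events: list[HypotensionEvent] = []
    for a, b in record.segments:
        below = p[a:b] < pressure_threshold
        if not below.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([False], below, [False])).astype(int)))
        for start, stop in zip(edges[::2], edges[1::2]):  # run = [start, stop)
            onset = t[a + start]
            end = t[a + stop] if stop < b - a else t[b - 1] + iv
            if end - onset >= min_duration:
                depth = pressure_threshold - p[a + start:a + stop]
                area = float(depth.sum() * iv / 60.0)
                events.append(HypotensionEvent(onset, end, area))
    return events


def detect_censor_segments(record: TraceRecord) -> list[CensorSegment]:
    """Flag intervention-influenced spans; overlapping spans are merged.

    From every baseline sample with pressure below 70 mmHg, a span is emitted
    when (a) the next sample is at least 5 mmHg higher, or (b) any sample in
    the following 2 min is at least 8 mmHg higher.  The span runs from the
    baseline sample to the (first) sample satisfying the rise.
    """
    t, p = record.times, record.pressure
    raw: list[tuple[float, float, str]] = []
    for a, b in record.segments:
        candidates = np.flatnonzero(p[a:b] < CENSOR_BASELINE_MMHG) + a
        for i in candidates:
            if i + 1 < b and p[i + 1] >= p[i] + CENSOR_RISE_20S_MMHG:
                raw.append((t[i], t[i + 1], RULE_20S))
            j = i + 1
            while j < b and t[j] - t[i] <= CENSOR_LOOKAHEAD_S:
                if p[j] >= p[i] + CENSOR_RISE_2MIN_MMHG:
                    raw.append((t[i], t[j], RULE_2MIN))
                    break
                j += 1
    raw.sort(key=lambda s: (s[0], s[1]))
    merged: list[CensorSegment] = []
    for start, end, rule in raw:
        if merged and start <= merged[-1].end_s:
            last = merged[-1]
            merged[-1] = CensorSegment(last.start_s, max(last.end_s, end),
                                       last.rules | {rule})
        else:
            merged.append(CensorSegment(start, end, frozenset({rule})))
    return merged


def compute_burden(record: TraceRecord, events: list[HypotensionEvent],
                   aut_mode: str = "events") -> BurdenStats:
    """Per-patient burden statistics.

    ``aut_mode="events"`` integrates depth below 65 mmHg over qualifying
    events only (consistent with the event-based hypotension definition);
    ``aut_mode="all"`` integrates over every sub-threshold sample regardless
    of run length.  Integration is a left-rectangle rule at the native 20-s
    cadence.
    """
    if aut_mode not in ("events", "all"):
        raise CohortError(f"aut_mode must be 'events' or 'all', got {aut_mode!r}")
    monitoring_min = record.monitored_seconds / 60.0
    hypo_min = sum(ev.duration_s for ev in events) / 60.0
    if aut_mode == "events":
        aut = float(sum(ev.depth_area for ev in events))
    else:
        depth = np.clip(PRESSURE_THRESHOLD_MMHG - record.pressure, 0.0, None)
        aut = float(np.nansum(depth) * record.sample_interval / 60.0)
    twa = aut / monitoring_min if monitoring_min > 0 else 0.0
    pct = 100.0 * hypo_min / monitoring_min if monitoring_min > 0 else 0.0
    return BurdenStats(record.patient_id, monitoring_min, len(events), hypo_min,
                       pct, aut, twa)


_QUANTILE_FIELDS = ("monitoring_time", "n_events", "hypo_duration", "hypo_percent",
                    "aut", "twa")


def cohort_burden(per_patient: list[BurdenStats]) -> dict:
    """Cohort summary: medians with 25th-75th percentiles, totals, and the
    percentage of patients with at least one event."""
    if not per_patient:
        raise CohortError("cohort_burden requires at least one patient")
    df = pd.DataFrame([vars(s) for s in per_patient])
    out: dict = {"n_patients": len(per_patient)}
    for col in _QUANTILE_FIELDS:
        out[f"{col}_median"] = float(df[col].median())
        out[f"{col}_q25"] = float(df[col].quantile(0.25))
        out[f"{col}_q75"] = float(df[col].quantile(0.75))
    out["monitoring_time_total"] = float(df["monitoring_time"].sum())
    out["n_events_total"] = int(df["n_events"].sum())
    out["hypo_duration_total"] = float(df["hypo_duration"].sum())
    out["pct_patients_with_event"] = float(100.0 * (df["n_events"] >= 1).mean())
    return out
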