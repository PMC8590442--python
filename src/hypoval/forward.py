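"""Forward analysis: alarm/quiet qualification and screening-window labeling.

The forward analysis evaluates a continuous 0-100 index as an alarm system.
Scanning each recording segment with a cursor:

1. From the cursor, the next anchor is the earlier of an *alarm* anchor (index
   strictly above the threshold for at least 1 min, i.e. >= 3 consecutive
   20-s samples) and a *quiet* anchor (index at or below the threshold for
   more than 1 min, i.e. >= 4 consecutive samples).
2. A 20-min screening window opens at the anchor.
3. A positive (alarm-anchored) window is TP when it contains at least one
   hypotensive-event onset — the time to event is onset minus anchor — and an
   FP candidate otherwise.
4. A negative (quiet-anchored) window is preempted at the first alarm anchor
   inside it: with an event onset before the preemption it is FN, otherwise
   it is discarded and the cursor jumps to the preempting alarm.  An
   unpreempted negative window is FN when it contains an event onset, TN
   otherwise.
5. After a labeled window the cursor moves to the window end — windows never
   overlap, so no event is counted twice, and TN windows are capped at one
   per 20 min.
6. A positive window anchored inside an ongoing hypotensive event is
   discarded (an alarm during hypotension is not a prediction) and the cursor
   moves to the event end.
7. An FP candidate overlapping an intervention-censored span is discarded:
   abrupt pressure rises after an alarm mean the alarm was most likely
   answered by an intervention, not that it was wrong.

Windows truncated by the segment end (fewer than 20 min remaining) are
discarded: a short tail cannot fairly host a full screen.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import CohortError, ConfigurationError
from .events import CensorSegment, HypotensionEvent
from .trace_io import TraceRecord

#: screening-window length, seconds (20 min)
DEFAULT_WINDOW_S = 1200.0

#: samples needed to qualify: alarm = "at least 1 min", quiet = "more than 1 min"
ALARM_QUALIFY_SAMPLES = 3
QUIET_QUALIFY_SAMPLES = 4

TP, FP, TN, FN, DISCARDED = "TP", "FP", "TN", "FN", "DISCARDED"


@dataclass
class AlarmOnset:
    """First sample of a maximal supra-threshold index run lasting >= 1 min."""

    time_s: float
    threshold: float


@dataclass
class ScreeningWindowLabel:
    """One screened 20-min forward window."""

    threshold: float
    window_start: float
    window_end: float
    label: str
    time_to_event: float | None = None   # TP only: event onset minus anchor, s
    censored_overlap: bool = False
    reason: str | None = None            # for DISCARDED windows


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)

    def as_array(self) -> np.ndarray:
        return np.array([self.tp, self.fp, self.tn, self.fn], dtype=float)


def _qualify_mask(values: np.ndarray, ok: np.ndarray, k: int) -> np.ndarray:
    """True where ``ok`` holds for ``k`` consecutive samples starting here."""
    n = ok.size
    out = np.zeros(n, dtype=bool)
    if n >= k:
        run = np.convolve(ok.astype(int), np.ones(k, dtype=int), mode="valid") == k
        out[: n - k + 1] = run
    return out


def find_alarm_onsets(record: TraceRecord, threshold: float) -> list[AlarmOnset]:
    """Onsets of maximal runs with index strictly above the threshold for >= 1 min.

    Missing index samples break runs.  The strict inequality means a
    threshold of 100 never fires for an index bounded by 100.
    """
    if not 0 <= threshold <= 100:
        raise ConfigurationError(f"threshold must lie in [0, 100], got {threshold!r}")
    iv = record.sample_interval
    t, x = record.times, record.index
    onsets: list[AlarmOnset] = []
    for a, b in record.segments:
        above = np.isfinite(x[a:b]) & (x[a:b] > threshold)
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False])).astype(int)))
        for start, stop in zip(edges[::2], edges[1::2]):
            onset = t[a + start]
            end = t[a + stop] if stop < b - a else t[b - 1] + iv
            if end - onset >= ALARM_QUALIFY_SAMPLES * iv:
                onsets.append(AlarmOnset(onset, threshold))
    return onsets


def label_windows(record: TraceRecord,
                  events: Sequence[HypotensionEvent],
                  censor_segments: Sequence[CensorSegment],
                  threshold: float,
                  window: float = DEFAULT_WINDOW_S,
                  censoring: bool = True,
                  negative_preemption: bool = True) -> list[ScreeningWindowLabel]:
    """Label forward screening windows at one index threshold.

    Implements the cursor-driven scan described in the module docstring.
    ``censoring=False`` disables rule 7; ``negative_preemption=False`` makes
    negative windows non-interruptible (the preempting alarm is then simply
    the next anchor after the window).
    """
    iv = record.sample_interval
    if window <= 0 or abs(window / iv - round(window / iv)) > 1e-9:
        raise ConfigurationError(
            f"window must be a positive multiple of the sample interval {iv:g} s, got {window!r}")
    if not 0 <= threshold <= 100:
        raise ConfigurationError(f"threshold must lie in [0, 100], got {threshold!r}")

    ev_onsets = np.array(sorted(ev.onset_s for ev in events))
    ev_list = sorted(events, key=lambda e: e.onset_s)
    labels: list[ScreeningWindowLabel] = []

    for a, b in record.segments:
        t = record.times[a:b]
        x = record.index[a:b]
        n = t.size
        finite = np.isfinite(x)
        alarm_ok = _qualify_mask(x, finite & (x > threshold), ALARM_QUALIFY_SAMPLES)
        quiet_ok = _qualify_mask(x, finite & (x <= threshold), QUIET_QUALIFY_SAMPLES)
        alarm_at = np.flatnonzero(alarm_ok)
        quiet_at = np.flatnonzero(quiet_ok)
        seg_end = t[-1] + iv

        cursor = t[0]
        while True:
            c = int(np.searchsorted(t, cursor, side="left"))
            if c >= n:
                break
            ia = alarm_at[np.searchsorted(alarm_at, c)] if np.searchsorted(alarm_at, c) < alarm_at.size else None
            iq = quiet_at[np.searchsorted(quiet_at, c)] if np.searchsorted(quiet_at, c) < quiet_at.size else None
            if ia is None and iq is None:
                break
            anchor_i = int(min(v for v in (ia, iq) if v is not None))
            is_alarm = ia is not None and anchor_i == ia
            u = t[anchor_i]

            if u + window > seg_end + 1e-9:
                labels.append(ScreeningWindowLabel(threshold, u, seg_end, DISCARDED,
                                                   reason="truncated"))
                break

            if is_alarm:
                ongoing = next((ev for ev in ev_list if ev.onset_s <= u < ev.end_s), None)
                if ongoing is not None:
                    labels.append(ScreeningWindowLabel(threshold, u, u + window, DISCARDED,
                                                       reason="alarm_during_event"))
                    cursor = ongoing.end_s
                    continue
                lo = np.searchsorted(ev_onsets, u, side="right")
                hi = np.searchsorted(ev_onsets, u + window, side="left")
                if hi > lo:
                    labels.append(ScreeningWindowLabel(threshold, u, u + window, TP,
                                                       time_to_event=float(ev_onsets[lo] - u)))
                else:
                    overlap = censoring and any(
                        cs.start_s < u + window and cs.end_s > u for cs in censor_segments)
                    if overlap:
                        labels.append(ScreeningWindowLabel(threshold, u, u + window, DISCARDED,
                                                           censored_overlap=True,
                                                           reason="censored"))
                    else:
                        labels.append(ScreeningWindowLabel(threshold, u, u + window, FP))
                cursor = u + window
            else:
                preempt_i = None
                if negative_preemption:
                    pos = np.searchsorted(alarm_at, anchor_i + 1)
                    if pos < alarm_at.size and t[alarm_at[pos]] < u + window:
                        preempt_i = int(alarm_at[pos])
                lo = np.searchsorted(ev_onsets, u, side="right")
                if preempt_i is not None:
                    v = t[preempt_i]
                    hi = np.searchsorted(ev_onsets, v, side="left")
                    if hi > lo:
                        labels.append(ScreeningWindowLabel(threshold, u, u + window, FN))
                        cursor = u + window
                    else:
                        labels.append(ScreeningWindowLabel(threshold, u, v, DISCARDED,
                                                           reason="preempted"))
                        cursor = v
                else:
                    hi = np.searchsorted(ev_onsets, u + window, side="left")
                    labels.append(ScreeningWindowLabel(threshold, u, u + window,
                                                       FN if hi > lo else TN))
                    cursor = u + window
    return labels


def count_labels(labels: Iterable[ScreeningWindowLabel]) -> ConfusionCounts:
    """Confusion counts from one patient's labels; discarded windows are excluded."""
    counts = ConfusionCounts()
    for lab in labels:
        if lab.label == TP:
            counts.tp += 1
        elif lab.label == FP:
            counts.fp += 1
        elif lab.label == TN:
            counts.tn += 1
        elif lab.label == FN:
            counts.fn += 1
    return counts


def pool_counts(per_patient_labels: Mapping[str, Sequence[ScreeningWindowLabel]]
                ) -> tuple[dict[str, ConfusionCounts], ConfusionCounts]:
    """Per-patient and pooled confusion counts at a common threshold."""
    thresholds = {lab.threshold for labs in per_patient_labels.values() for lab in labs}
    if len(thresholds) > 1:
        raise CohortError(f"labels mix thresholds {sorted(thresholds)}; pool one threshold at a time")
    per_patient = {pid: count_labels(labs) for pid, labs in per_patient_labels.items()}
    pooled = sum(per_patient.values(), ConfusionCounts())
    return per_patient, pooled


def alarm_follow_counts(record: TraceRecord, events: Sequence[HypotensionEvent],
                        threshold: float, window: float = DEFAULT_WINDOW_S
                        ) -> tuple[int, int]:
    """(number of qualifying alarm onsets, number followed by an event onset within the window).

    Alarm onsets are taken before any window shifting or discarding.
    """
    onsets = find_alarm_onsets(record, threshold)
    ev_onsets = np.array(sorted(ev.onset_s for ev in events))
    followed = sum(
        1 for o in onsets
        if np.searchsorted(ev_onsets, o.time_s + window, side="left")
        > np.searchsorted(ev_onsets, o.time_s, side="right"))
    return len(onsets), followed


def alarm_event_rate(record: TraceRecord, events: Sequence[HypotensionEvent],
                     threshold: float, window: float = DEFAULT_WINDOW_S) -> float | None:
    """Fraction of alarm onsets followed by at least one event onset within the window.

    Returns ``None`` (undefined) when there are no qualifying alarm onsets.
    """
    n, followed = alarm_follow_counts(record, events, threshold, window)
    return followed / n if n else None


@dataclass
class PatientThresholdSummary:
    """Everything the bootstrap needs from one patient at one threshold."""

    patient_id: str
    threshold: float
    counts: ConfusionCounts
    time_to_event: np.ndarray  # seconds, one per TP window
    n_alarms: int
    n_alarms_followed: int


def summarize_patient(record: TraceRecord, events: Sequence[HypotensionEvent],
                      censor_segments: Sequence[CensorSegment],
                      thresholds: Sequence[float],
                      window: float = DEFAULT_WINDOW_S,
                      censoring: bool = True,
                      negative_preemption: bool = True
                      ) -> tuple[dict[float, PatientThresholdSummary],
                                 dict[float, list[ScreeningWindowLabel]]]:
    """Label one patient at every threshold and collect bootstrap inputs."""
    summaries: dict[float, PatientThresholdSummary] = {}
    all_labels: dict[float, list[ScreeningWindowLabel]] = {}
    for thr in thresholds:
        labels = label_windows(record, events, censor_segments, thr, window=window,
                               censoring=censoring, negative_preemption=negative_preemption)
        counts = count_labels(labels)
        tte = np.array([lab.time_to_event for lab in labels if lab.label == TP], dtype=float)
        n_alarms, followed = alarm_follow_counts(record, events, thr, window)
        summaries[thr] = PatientThresholdSummary(record.patient_id, thr, counts, tte,
                                                 n_alarms, followed)
        all_labels[thr] = labels
    return summaries, all_labels
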