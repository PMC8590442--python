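"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain per-sample Python loops, directly from
the labeling rules, sharing no code with the package: events, censor spans,
alarm onsets, the cursor-driven forward labeler, the alarm event rate, and a
hand-rolled trapezoid integrator.
"""
from __future__ import annotations

import math


def split_segments(times, gap=60.0):
    """Index ranges (start, stop) between gaps strictly longer than ``gap`` seconds."""
    segs, start = [], 0
    for i in range(1, len(times)):
        if times[i] - times[i - 1] > gap:
            segs.append((start, i))
            start = i
    segs.append((start, len(times)))
    return segs


def brute_events(times, pressure, threshold=65.0, min_duration=60.0, interval=20.0):
    """(onset, end) of maximal sub-threshold runs spanning at least min_duration."""
    events = []
    for a, b in split_segments(times):
        i = a
        while i < b:
            if pressure[i] < threshold:
                j = i
                while j < b and pressure[j] < threshold:
                    j += 1
                onset = times[i]
                end = times[j] if j < b else times[b - 1] + interval
                if end - onset >= min_duration:
                    events.append((onset, end))
                i = j
            else:
                i += 1
    return events


def brute_censors(times, pressure):
    """Merged intervention-censor spans from evaluating both rise rules at every baseline."""
    raw = []
    for a, b in split_segments(times):
        for i in range(a, b):
            if pressure[i] >= 70.0:
                continue
            if i + 1 < b and pressure[i + 1] >= pressure[i] + 5.0:
                raw.append((times[i], times[i + 1]))
            for j in range(i + 1, b):
                if times[j] - times[i] > 120.0:
                    break
                if pressure[j] >= pressure[i] + 8.0:
                    raw.append((times[i], times[j]))
                    break
    raw.sort()
    merged = []
    for s, e in raw:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _is_num(x):
    return x is not None and not (isinstance(x, float) and math.isnan(x))


def brute_alarm_onsets(times, index, threshold, interval=20.0):
    """Onsets of maximal runs strictly above the threshold lasting >= 60 s."""
    onsets = []
    for a, b in split_segments(times):
        i = a
        while i < b:
            if _is_num(index[i]) and index[i] > threshold:
                j = i
                while j < b and _is_num(index[j]) and index[j] > threshold:
                    j += 1
                end = times[j] if j < b else times[b - 1] + interval
                if end - times[i] >= 60.0:
                    onsets.append(times[i])
                i = j
            else:
                i += 1
    return onsets


def brute_event_rate(times, pressure, index, threshold, window=1200.0):
    onsets = brute_alarm_onsets(times, index, threshold)
    if not onsets:
        return None
    events = brute_events(times, pressure)
    followed = sum(1 for o in onsets
                   if any(o < ev[0] < o + window for ev in events))
    return followed / len(onsets)


def brute_label_windows(times, pressure, index, threshold, window=1200.0, interval=20.0,
                        censoring=True, negative_preemption=True):
    """Cursor-driven forward labeler, written rule by rule with explicit loops.

    Returns tuples (label, window_start, window_end, time_to_event).
    """
    events = brute_events(times, pressure)
    censors = brute_censors(times, pressure) if censoring else []
    labels = []
    for a, b in split_segments(times):
        t = times[a:b]
        x = index[a:b]
        n = b - a

        def alarm_ok(i):
            if i + 2 >= n:
                return False
            return all(_is_num(x[i + k]) and x[i + k] > threshold for k in range(3))

        def quiet_ok(i):
            if i + 3 >= n:
                return False
            return all(_is_num(x[i + k]) and x[i + k] <= threshold for k in range(4))

        seg_end = t[n - 1] + interval
        cursor = t[0]
        while True:
            anchor = None
            for i in range(n):
                if t[i] < cursor:
                    continue
                if alarm_ok(i) or quiet_ok(i):
                    anchor = i
                    break
            if anchor is None:
                break
            u = t[anchor]
            if u + window > seg_end + 1e-9:
                labels.append(("DISCARDED", u, seg_end, None))
                break
            if alarm_ok(anchor):
                ongoing = None
                for ev in events:
                    if ev[0] <= u < ev[1]:
                        ongoing = ev
                        break
                if ongoing is not None:
                    labels.append(("DISCARDED", u, u + window, None))
                    cursor = ongoing[1]
                    continue
                onsets_in = [ev[0] for ev in events if u < ev[0] < u + window]
                if onsets_in:
                    labels.append(("TP", u, u + window, min(onsets_in) - u))
                elif any(cs[0] < u + window and cs[1] > u for cs in censors):
                    labels.append(("DISCARDED", u, u + window, None))
                else:
                    labels.append(("FP", u, u + window, None))
                cursor = u + window
            else:
                preempt = None
                if negative_preemption:
                    for i in range(anchor + 1, n):
                        if t[i] >= u + window:
                            break
                        if alarm_ok(i):
                            preempt = t[i]
                            break
                if preempt is not None:
                    if any(u < ev[0] < preempt for ev in events):
                        labels.append(("FN", u, u + window, None))
                        cursor = u + window
                    else:
                        labels.append(("DISCARDED", u, preempt, None))
                        cursor = preempt
                else:
                    has_event = any(u < ev[0] < u + window for ev in events)
                    labels.append(("FN" if has_event else "TN", u, u + window, None))
                    cursor = u + window
    return labels


def brute_trapezoid(points):
    """Trapezoid area under a polyline, written out longhand."""
    area = 0.0
    for (x1, y1), (x2, y2) in zip(points[:-1], points[1:]):
        area += (x2 - x1) * (y1 + y2) / 2.0
    return area
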