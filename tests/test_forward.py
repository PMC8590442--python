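import numpy as np
import pytest

from hypoval import (
    CohortError,
    ConfigurationError,
    ConfusionCounts,
    alarm_event_rate,
    count_labels,
    detect_censor_segments,
    detect_events,
    find_alarm_onsets,
    label_windows,
    make_fixture,
    pool_counts,
    summarize_patient,
)
from bruteforce import brute_alarm_onsets, brute_event_rate, brute_label_windows
from conftest import make_record, random_trace


def labeled(rec, threshold, **kw):
    events = detect_events(rec)
    censors = detect_censor_segments(rec)
    return label_windows(rec, events, censors, threshold, **kw)


class TestAlarmOnsets:
    def test_constant_high_index_one_onset(self):
        rec = make_record([75] * 10, index=[95] * 10)
        (onset,) = find_alarm_onsets(rec, 90.0)
        assert onset.time_s == 0.0

    def test_threshold_100_never_fires(self):
        rec = make_record([75] * 10, index=[100] * 10)
        assert find_alarm_onsets(rec, 100.0) == []

    def test_short_run_does_not_qualify(self):
        rec = make_record([75] * 7, index=[80, 95, 95, 80, 95, 95, 95])
        (onset,) = find_alarm_onsets(rec, 90.0)
        assert onset.time_s == 80.0

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            t, p, x = random_trace(rng, int(rng.integers(5, 200)),
                                   gap_prob=0.02, nan_index_prob=0.05)
            rec = make_record(p, index=x, times=t)
            for thr in (0.0, 30.0, 60.0, 90.0):
                got = [o.time_s for o in find_alarm_onsets(rec, thr)]
                assert got == brute_alarm_onsets(list(t), list(x), thr)


class TestLabelWindows:
    def test_quiet_100_minutes_gives_five_capped_tns(self):
        n = 300  # 100 min
        rec = make_record([75.0] * n, index=[0.0] * n)
        labels = labeled(rec, 50.0)
        assert [l.label for l in labels] == ["TN"] * 5

    def test_alarm_before_event_is_tp_with_time_to_event(self):
        n = 60
        p = np.full(n, 75.0)
        p[15:24] = 60.0  # event onset at 300 s
        x = np.full(n, 95.0)
        rec = make_record(p, index=x)
        labels = labeled(rec, 90.0)
        assert labels[0].label == "TP"
        assert 0 < labels[0].time_to_event <= 300.0

    def test_alarm_during_hypotension_is_discarded(self):
        n = 65
        p = np.full(n, 75.0)
        p[0:9] = 60.0  # trace starts mid-event
        x = np.full(n, 95.0)
        rec = make_record(p, index=x)
        labels = labeled(rec, 90.0)
        assert labels[0].label == "DISCARDED"
        assert labels[0].reason == "alarm_during_event"

    def test_false_alarm_overlapping_censor_is_discarded(self):
        n = 70
        p = np.full(n, 75.0)
        p[10], p[11] = 68.0, 74.0  # censored rescue-like rise, no event
        x = np.full(n, 95.0)
        rec = make_record(p, index=x)
        labels = labeled(rec, 90.0)
        assert labels[0].label == "DISCARDED"
        assert labels[0].censored_overlap
        # with censoring disabled the same window is an FP
        labels = labeled(rec, 90.0, censoring=False)
        assert labels[0].label == "FP"

    def test_negative_window_preempted_by_alarm_is_discarded(self):
        n = 70
        x = np.concatenate([np.zeros(10), np.full(n - 10, 95.0)])
        rec = make_record(np.full(n, 75.0), index=x)
        labels = labeled(rec, 50.0)
        assert labels[0].label == "DISCARDED"
        assert labels[0].reason == "preempted"
        assert labels[0].window_end == 200.0  # cursor jumps to the alarm
        assert labels[1].window_start == 200.0

    def test_event_before_preemption_is_fn(self):
        n = 70
        p = np.full(n, 75.0)
        p[5:9] = 60.0  # missed event at 100 s
        x = np.concatenate([np.zeros(20), np.full(n - 20, 95.0)])
        rec = make_record(p, index=x)
        labels = labeled(rec, 50.0)
        assert labels[0].label == "FN"

    def test_short_tail_discarded_as_truncated(self):
        rec = make_record([75.0] * 30, index=[0.0] * 30)  # 10 min only
        (lab,) = labeled(rec, 50.0)
        assert lab.label == "DISCARDED" and lab.reason == "truncated"

    def test_window_must_be_multiple_of_interval(self):
        rec = make_record([75.0] * 10, index=[0.0] * 10)
        with pytest.raises(ConfigurationError, match="window"):
            labeled(rec, 50.0, window=1210.0)

    def test_matches_bruteforce_on_random_traces(self):
        rng = np.random.default_rng(99)
        thresholds = (0.0, 25.0, 50.0, 75.0, 95.0)
        for _ in range(40):
            t, p, x = random_trace(rng, int(rng.integers(10, 200)),
                                   gap_prob=0.02, nan_index_prob=0.05)
            rec = make_record(p, index=x, times=t)
            for thr in thresholds:
                got = [(l.label, l.window_start, l.window_end,
                        l.time_to_event) for l in labeled(rec, thr)]
                assert got == brute_label_windows(list(t), list(p), list(x), thr), \
                    (thr, list(t), list(p), list(x))

    def test_windows_non_overlapping_and_events_counted_once(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            t, p, x = random_trace(rng, 200, gap_prob=0.01)
            rec = make_record(p, index=x, times=t)
            events = detect_events(rec)
            labels = [l for l in labeled(rec, 50.0) if l.label != "DISCARDED"]
            spans = sorted((l.window_start, l.window_end) for l in labels)
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))
            for ev in events:
                holders = [s for s in spans if s[0] < ev.onset_s < s[1]]
                assert len(holders) <= 1

    def test_unreachable_threshold_makes_all_events_fn(self):
        recs, truths, _ = make_fixture("perfect_oracle", seed=1)
        for rec in recs:
            events = detect_events(rec)
            labels = labeled(rec, 100.0)
            c = count_labels(labels)
            assert c.tp == 0 and c.fp == 0
            windowed = sum(1 for l in labels if l.label in ("FN",))
            assert c.fn == windowed


class TestPooling:
    def test_counts_from_labels(self):
        rec = make_record([75.0] * 300, index=[0.0] * 300)
        labels = labeled(rec, 50.0)
        c = count_labels(labels)
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 0, 5, 0)

    def test_empty_labels_all_zero(self):
        c = count_labels([])
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 0, 0, 0)

    def test_pooled_is_elementwise_sum(self):
        rec1 = make_record([75.0] * 300, index=[0.0] * 300, patient_id="A")
        rec2 = make_record([75.0] * 300, index=[95.0] * 300, patient_id="B")
        per, pooled = pool_counts({"A": labeled(rec1, 50.0), "B": labeled(rec2, 50.0)})
        assert pooled.tn == per["A"].tn + per["B"].tn
        assert pooled.fp == per["A"].fp + per["B"].fp

    def test_mixed_thresholds_rejected(self):
        rec = make_record([75.0] * 300, index=[0.0] * 300)
        with pytest.raises(CohortError, match="threshold"):
            pool_counts({"A": labeled(rec, 50.0), "B": labeled(rec, 60.0)})


class TestEventRate:
    def test_perfect_oracle_rate_is_one(self):
        recs, _, _ = make_fixture("perfect_oracle", seed=2)
        for rec in recs:
            events = detect_events(rec)
            if not events:
                continue
            rate = alarm_event_rate(rec, events, 50.0)
            assert rate == 1.0

    def test_alarms_without_events_rate_zero(self):
        rec = make_record([75.0] * 60, index=[95.0] * 60)
        assert alarm_event_rate(rec, [], 90.0) == 0.0

    def test_no_alarms_is_undefined(self):
        rec = make_record([75.0] * 60, index=[0.0] * 60)
        assert alarm_event_rate(rec, [], 90.0) is None

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            t, p, x = random_trace(rng, 150, gap_prob=0.02)
            rec = make_record(p, index=x, times=t)
            events = detect_events(rec)
            for thr in (25.0, 50.0, 75.0):
                assert alarm_event_rate(rec, events, thr) == \
                    brute_event_rate(list(t), list(p), list(x), thr)


class TestMonotonicity:
    def test_fp_non_increasing_in_threshold_on_perfect_oracle(self):
        recs, _, _ = make_fixture("perfect_oracle", seed=4)
        thresholds = [float(v) for v in range(0, 101, 5)]
        pooled = []
        for thr in thresholds:
            total = ConfusionCounts()
            for rec in recs:
                total = total + count_labels(labeled(rec, thr))
            pooled.append(total.fp)
        assert all(a >= b for a, b in zip(pooled, pooled[1:]))
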