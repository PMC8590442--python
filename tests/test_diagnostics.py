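import numpy as np
import pytest

from hypoval import (
    CohortError,
    ConfusionCounts,
    Estimate,
    PatientThresholdSummary,
    ThresholdMetrics,
    bootstrap_metrics,
    build_roc,
    confusion_metrics,
    evaluate_thresholds,
    optimal_threshold,
    roc_points,
    trapezoid_auc,
    youden_j,
)
from bruteforce import brute_trapezoid


def summary(pid, thr, tp=0, fp=0, tn=0, fn=0, tte=(), alarms=0, followed=0):
    return PatientThresholdSummary(pid, thr, ConfusionCounts(tp, fp, tn, fn),
                                   np.asarray(tte, float), alarms, followed)


def tmetric(thr, sens, spec, j=None):
    e = lambda v: None if v is None else Estimate(v, v, v)
    jj = None if sens is None or spec is None else sens + spec - 1
    return ThresholdMetrics(thr, ConfusionCounts(), e(sens), e(spec), None, None,
                            e(jj if j is None else j), None, None)


class TestConfusionMetrics:
    def test_textbook_counts(self):
        m = confusion_metrics(ConfusionCounts(tp=3, fp=1, tn=5, fn=1))
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(5 / 6)
        assert m.ppv == pytest.approx(0.75)
        assert m.npv == pytest.approx(5 / 6)
        assert m.youden_j == pytest.approx(0.75 + 5 / 6 - 1)

    def test_zero_denominator_is_missing(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fp=2, tn=3, fn=0))
        assert m.sensitivity is None
        assert m.youden_j is None
        assert m.specificity == pytest.approx(0.6)

    def test_reported_operating_point(self):
        # a published ICU validation quotes sens 0.91 / spec 0.87 -> J 0.78
        assert youden_j(0.91, 0.87) == pytest.approx(0.78)


class TestROC:
    def test_perfect_classifier(self):
        pts = roc_points([0.0], [1.0])
        assert trapezoid_auc(pts) == pytest.approx(1.0)

    def test_diagonal_is_half(self):
        pts = roc_points([0.25, 0.5, 0.75], [0.25, 0.5, 0.75])
        assert trapezoid_auc(pts) == pytest.approx(0.5)

    def test_matches_independent_trapezoid_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            k = int(rng.integers(2, 15))
            pts = roc_points(rng.uniform(0, 1, k), rng.uniform(0, 1, k))
            assert trapezoid_auc(pts) == pytest.approx(
                brute_trapezoid(pts.tolist()), abs=1e-12)

    def test_collinear_point_does_not_change_auc(self):
        pts = roc_points([0.2, 0.6], [0.5, 0.9])
        base = trapezoid_auc(pts)
        with_mid = roc_points([0.2, 0.4, 0.6], [0.5, 0.7, 0.9])
        assert trapezoid_auc(with_mid) == pytest.approx(base, abs=1e-12)

    def test_needs_two_usable_points(self):
        with pytest.raises(CohortError):
            build_roc([tmetric(50.0, 1.0, None), tmetric(60.0, None, 1.0)])


class TestOptimalThreshold:
    def test_unique_maximum(self):
        ms = [tmetric(85.0, 0.92, 0.83), tmetric(90.0, 0.91, 0.87), tmetric(95.0, 0.80, 0.96)]
        assert optimal_threshold(ms) == 90.0

    def test_tie_breaks_to_higher_threshold(self):
        ms = [tmetric(85.0, 0.9, 0.9), tmetric(90.0, 0.85, 0.95)]
        assert optimal_threshold(ms) == 90.0

    def test_single_threshold(self):
        assert optimal_threshold([tmetric(35.0, 0.5, 0.5)]) == 35.0

    def test_all_missing_rejected(self):
        with pytest.raises(CohortError):
            optimal_threshold([tmetric(50.0, None, 0.9)])


class TestBootstrap:
    def test_single_patient_degenerate_ci(self):
        per = [summary("A", 50.0, tp=4, fp=1, tn=10, fn=1, tte=(100.0, 200.0, 220.0, 300.0),
                       alarms=5, followed=4)]
        res = bootstrap_metrics(per, n_replicates=500, seed=1)
        for name, est in res.metrics.items():
            assert est is not None, name
            assert est.lower == est.value == est.upper, name
        assert res.metrics["sensitivity"].value == pytest.approx(0.8)
        assert res.metrics["time_to_event"].value == pytest.approx(210.0)

    def test_same_seed_identical(self):
        per = [summary(p, 50.0, tp=3 + i, fp=i, tn=8, fn=1, tte=(50.0 * (i + 1),),
                       alarms=4, followed=3) for i, p in enumerate("ABCD")]
        r1 = bootstrap_metrics(per, n_replicates=400, seed=7)
        r2 = bootstrap_metrics(per, n_replicates=400, seed=7)
        assert r1.metrics == r2.metrics

    def test_undefined_replicates_excluded_not_imputed(self):
        # patient B has no positives: replicates drawing only B lack sensitivity
        per = [summary("A", 50.0, tp=2, fn=2, tn=5), summary("B", 50.0, tn=5)]
        res = bootstrap_metrics(per, n_replicates=2000, seed=3)
        assert res.n_excluded["sensitivity"] > 0
        assert res.metrics["sensitivity"].value == pytest.approx(0.5, abs=0.25)

    def test_ci_width_shrinks_with_cohort_size(self):
        rng = np.random.default_rng(11)

        def cohort(P, seed):
            per = []
            for p in range(P):
                tp = int(rng.integers(2, 6))
                fn = int(rng.integers(0, 3))
                per.append(summary(f"P{p}", 50.0, tp=tp, fn=fn, tn=10, fp=1))
            return bootstrap_metrics(per, n_replicates=1000, seed=seed)

        small = cohort(5, 1).metrics["sensitivity"]
        large = cohort(40, 1).metrics["sensitivity"]
        assert (large.upper - large.lower) < (small.upper - small.lower)

    def test_youden_identity_on_every_emitted_row(self):
        per = {thr: [summary(p, thr, tp=3 + i, fp=2, tn=9 - i, fn=1)
                     for i, p in enumerate("ABC")] for thr in (30.0, 60.0)}
        metrics, _ = evaluate_thresholds(per, n_replicates=500, seed=2)
        for m in metrics:
            assert m.youden_j.value == pytest.approx(
                m.sensitivity.value + m.specificity.value - 1.0, abs=1e-15)

    def test_roc_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(8)
        per = {thr: [summary(f"P{p}", thr,
                             tp=int(rng.integers(1, 6)), fp=int(rng.integers(0, 4)),
                             tn=int(rng.integers(3, 10)), fn=int(rng.integers(0, 3)))
                     for p in range(10)] for thr in (20.0, 50.0, 80.0)}
        metrics, roc = evaluate_thresholds(per, n_replicates=2000, seed=4)
        assert roc.auc.lower <= roc.auc.value <= roc.auc.upper
        assert 0.0 <= roc.auc.value <= 1.0
        for m in metrics:
            for est in (m.sensitivity, m.specificity, m.ppv, m.npv):
                assert est.lower <= est.value <= est.upper
                assert 0.0 <= est.lower and est.upper <= 1.0


class TestFigures:
    def test_roc_and_event_rate_figures_written(self, tmp_path):
        import matplotlib
        matplotlib.use("Agg")
        from hypoval import plot_event_rate, plot_roc

        per = {thr: [summary(f"P{p}", thr, tp=3, fp=1, tn=8, fn=1, tte=(200.0,),
                             alarms=4, followed=3) for p in range(4)]
               for thr in (20.0, 50.0, 80.0)}
        metrics, roc = evaluate_thresholds(per, n_replicates=300, seed=0)
        plot_roc(roc, path=tmp_path / "roc.png")
        plot_event_rate(metrics, path=tmp_path / "rate.png")
        assert (tmp_path / "roc.png").stat().st_size > 0
        assert (tmp_path / "rate.png").stat().st_size > 0
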