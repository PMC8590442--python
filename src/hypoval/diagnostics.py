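"""Threshold-wise diagnostics, ROC/AUC, Youden's J, and patient-level bootstrap.

From pooled confusion counts at each index threshold the usual diagnostics
follow: sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP), NPV
TN/(TN+FN), and Youden's J = sensitivity + specificity - 1, whose maximizer
over thresholds is the optimal alarm threshold.  A metric whose denominator
is zero is undefined and propagates as missing.

Because screening windows repeat within patients, confidence intervals come
from a bootstrap that resamples *patients* with replacement (keeping each
patient's windows together), re-pools counts, and recomputes every metric per
replicate.  Reported point estimates are the replicate medians with 2.5/97.5
percentile bounds; replicates where a metric is undefined are excluded from
that metric's percentiles (the exclusion count is recorded).  Youden's J is
reported as the identity sensitivity + specificity - 1 of the reported
medians, with its interval taken from the replicate J distribution.

The ROC curve uses the per-threshold point estimates, anchored at (0,0) and
(1,1) and integrated with the trapezoidal rule; its interval applies the same
integration to each bootstrap replicate.  The same patient resample is shared
across thresholds within a replicate, so each replicate traces a coherent
curve.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .errors import CohortError
from .forward import ConfusionCounts, PatientThresholdSummary

logger = logging.getLogger("hypoval")

DEFAULT_REPLICATES = 100_000

#: metric names carried through the bootstrap
METRICS = ("sensitivity", "specificity", "ppv", "npv", "time_to_event", "event_rate")


class Estimate(NamedTuple):
    """Point estimate with a 95% confidence interval."""

    value: float
    lower: float
    upper: float


@dataclass
class MetricPoint:
    """Plug-in diagnostics from one set of confusion counts (None = undefined)."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    youden_j: float | None


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def youden_j(sensitivity: float | None, specificity: float | None) -> float | None:
    """Youden's J statistic; missing when either component is missing."""
    if sensitivity is None or specificity is None:
        return None
    return sensitivity + specificity - 1.0


def confusion_metrics(counts: ConfusionCounts) -> MetricPoint:
    """Sensitivity, specificity, PPV, NPV and Youden's J from confusion counts."""
    sens = _ratio(counts.tp, counts.tp + counts.fn)
    spec = _ratio(counts.tn, counts.tn + counts.fp)
    ppv = _ratio(counts.tp, counts.tp + counts.fp)
    npv = _ratio(counts.tn, counts.tn + counts.fn)
    return MetricPoint(sens, spec, ppv, npv, youden_j(sens, spec))


@dataclass
class ThresholdMetrics:
    """Bootstrap-corrected diagnostics at one index threshold."""

    threshold: float
    counts: ConfusionCounts                     # pooled plug-in counts
    sensitivity: Estimate | None
    specificity: Estimate | None
    ppv: Estimate | None
    npv: Estimate | None
    youden_j: Estimate | None
    time_to_event: Estimate | None              # seconds, median over TP windows
    event_rate: Estimate | None
    n_excluded: dict[str, int] = field(default_factory=dict)


@dataclass
class ROCCurve:
    """ROC points (FPR, sensitivity) with anchors, and the trapezoidal AUC."""

    points: np.ndarray                          # (K, 2), sorted by FPR
    auc: Estimate


@dataclass
class BootstrapResult:
    """Replicate summaries for one threshold."""

    n_replicates: int
    seed: int
    metrics: dict[str, Estimate | None]
    n_excluded: dict[str, int]


# -- pure ROC helpers -------------------------------------------------------

def roc_points(fpr: Sequence[float], tpr: Sequence[float]) -> np.ndarray:
    """Sort operating points by FPR (ties broken by sensitivity) and add the
    (0,0) and (1,1) anchors."""
    x = np.concatenate(([0.0], np.asarray(fpr, float), [1.0]))
    y = np.concatenate(([0.0], np.asarray(tpr, float), [1.0]))
    order = np.lexsort((y, x))
    return np.column_stack((x[order], y[order]))


def trapezoid_auc(points: np.ndarray) -> float:
    """Area under a piecewise-linear ROC curve by the trapezoidal rule."""
    points = np.asarray(points, float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise CohortError("trapezoid_auc needs at least two ROC points")
    if np.any(points < -1e-12) or np.any(points > 1 + 1e-12):
        raise CohortError("ROC points must lie in the unit square")
    return float(np.trapezoid(points[:, 1], points[:, 0]))


# -- bootstrap engine -------------------------------------------------------

def _threshold_arrays(per_patient: Sequence[PatientThresholdSummary]):
    counts = np.stack([s.counts.as_array() for s in per_patient])       # (P, 4)
    alarms = np.array([s.n_alarms for s in per_patient], float)
    followed = np.array([s.n_alarms_followed for s in per_patient], float)
    tte_vals, tte_owner = [], []
    for p, s in enumerate(per_patient):
        tte_vals.extend(s.time_to_event.tolist())
        tte_owner.extend([p] * s.time_to_event.size)
    tte_vals = np.asarray(tte_vals, float)
    tte_owner = np.asarray(tte_owner, int)
    order = np.argsort(tte_vals, kind="stable")
    return counts, alarms, followed, tte_vals[order], tte_owner[order]


def _replicate_metrics(weights: np.ndarray, counts: np.ndarray, alarms: np.ndarray,
                       followed: np.ndarray, tte_vals: np.ndarray,
                       tte_owner: np.ndarray) -> dict[str, np.ndarray]:
    """Metric value per bootstrap replicate (NaN where undefined)."""
    pooled = weights @ counts                                            # (B, 4)
    tp, fp, tn, fn = pooled.T
    with np.errstate(divide="ignore", invalid="ignore"):
        out = {
            "sensitivity": np.where(tp + fn > 0, tp / (tp + fn), np.nan),
            "specificity": np.where(tn + fp > 0, tn / (tn + fp), np.nan),
            "ppv": np.where(tp + fp > 0, tp / (tp + fp), np.nan),
            "npv": np.where(tn + fn > 0, tn / (tn + fn), np.nan),
        }
        n_al = weights @ alarms
        out["event_rate"] = np.where(n_al > 0, (weights @ followed) / n_al, np.nan)
    out["time_to_event"] = _weighted_median(tte_vals, weights[:, tte_owner]) \
        if tte_vals.size else np.full(weights.shape[0], np.nan)
    return out


def _weighted_median(sorted_vals: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median of ``sorted_vals`` (ascending) under integer weights.

    Matches ``np.median`` of the expanded sample: when the cumulative weight
    hits exactly half the total, the two straddling values are averaged.
    """
    cw = np.cumsum(weights, axis=1)
    total = cw[:, -1]
    out = np.full(weights.shape[0], np.nan)
    pos = total > 0
    if not pos.any():
        return out
    half = total[pos] / 2.0
    cwp = cw[pos]
    j = (cwp >= half[:, None] - 1e-9).argmax(axis=1)
    med = sorted_vals[j]
    exact = np.abs(cwp[np.arange(j.size), j] - half) < 1e-9
    nxt = np.minimum(j + 1, sorted_vals.size - 1)
    med = np.where(exact, 0.5 * (sorted_vals[j] + sorted_vals[nxt]), med)
    out[pos] = med
    return out


def _summ(replicates: np.ndarray) -> tuple[Estimate | None, int]:
    n_bad = int(np.isnan(replicates).sum())
    if n_bad == replicates.size:
        return None, n_bad
    value = float(np.nanmedian(replicates))
    lo, hi = np.nanpercentile(replicates, [2.5, 97.5])
    return Estimate(value, float(lo), float(hi)), n_bad


def _replicate_auc(sens: np.ndarray, fpr: np.ndarray) -> np.ndarray:
    """Trapezoidal AUC per replicate row; NaN where any point is undefined."""
    B = sens.shape[0]
    out = np.full(B, np.nan)
    valid = ~(np.isnan(sens).any(axis=1) | np.isnan(fpr).any(axis=1))
    if valid.any():
        x = np.concatenate([np.zeros((valid.sum(), 1)), fpr[valid], np.ones((valid.sum(), 1))], axis=1)
        y = np.concatenate([np.zeros((valid.sum(), 1)), sens[valid], np.ones((valid.sum(), 1))], axis=1)
        # sort by FPR with sensitivity as a tiny tiebreak (counts are bounded,
        # so distinct FPRs differ by far more than the tiebreak scale)
        order = np.argsort(x + 1e-9 * y, axis=1, kind="stable")
        xs = np.take_along_axis(x, order, axis=1)
        ys = np.take_along_axis(y, order, axis=1)
        out[valid] = np.sum(0.5 * np.diff(xs, axis=1) * (ys[:, 1:] + ys[:, :-1]), axis=1)
    return out


def evaluate_thresholds(summaries: Mapping[float, Sequence[PatientThresholdSummary]],
                        n_replicates: int = DEFAULT_REPLICATES,
                        seed: int = 0,
                        chunk: int = 10_000
                        ) -> tuple[list[ThresholdMetrics], ROCCurve | None]:
    """Bootstrap-corrected metrics at every threshold plus the ROC curve.

    ``summaries`` maps threshold -> per-patient summaries (same patients, same
    order, at every threshold).  The patient resample is shared across
    thresholds within each replicate.
    """
    if not summaries:
        raise CohortError("evaluate_thresholds needs at least one threshold")
    thresholds = sorted(summaries)
    n_patients = {len(summaries[t]) for t in thresholds}
    if len(n_patients) != 1:
        raise CohortError("per-threshold summaries disagree on the patient set")
    P = n_patients.pop()
    if P < 1:
        raise CohortError("evaluate_thresholds needs at least one patient")

    arrays = {t: _threshold_arrays(summaries[t]) for t in thresholds}
    rng = np.random.default_rng(seed)
    reps: dict[float, dict[str, list[np.ndarray]]] = {
        t: {m: [] for m in METRICS} for t in thresholds}
    auc_reps: list[np.ndarray] = []

    done = 0
    while done < n_replicates:
        B = min(chunk, n_replicates - done)
        idx = rng.integers(0, P, size=(B, P))
        weights = np.zeros((B, P))
        np.add.at(weights, (np.arange(B)[:, None], idx), 1.0)
        sens_grid = np.empty((B, len(thresholds)))
        fpr_grid = np.empty((B, len(thresholds)))
        for k, thr in enumerate(thresholds):
            vals = _replicate_metrics(weights, *arrays[thr])
            for m in METRICS:
                reps[thr][m].append(vals[m])
            sens_grid[:, k] = vals["sensitivity"]
            fpr_grid[:, k] = 1.0 - vals["specificity"]
        auc_reps.append(_replicate_auc(sens_grid, fpr_grid))
        done += B

    results: list[ThresholdMetrics] = []
    for thr in thresholds:
        pooled = sum((s.counts for s in summaries[thr]), ConfusionCounts())
        est: dict[str, Estimate | None] = {}
        excl: dict[str, int] = {}
        for m in METRICS:
            est[m], excl[m] = _summ(np.concatenate(reps[thr][m]))
        if est["sensitivity"] is not None and est["specificity"] is not None:
            j_reps = np.concatenate(reps[thr]["sensitivity"]) \
                + np.concatenate(reps[thr]["specificity"]) - 1.0
            j_lo, j_hi = np.nanpercentile(j_reps, [2.5, 97.5])
            j = Estimate(est["sensitivity"].value + est["specificity"].value - 1.0,
                         float(j_lo), float(j_hi))
        else:
            j = None
        for m, n_bad in excl.items():
            if n_bad:
                logger.info("threshold %g: %d replicate(s) with undefined %s excluded",
                            thr, n_bad, m)
        results.append(ThresholdMetrics(thr, pooled, est["sensitivity"], est["specificity"],
                                        est["ppv"], est["npv"], j, est["time_to_event"],
                                        est["event_rate"], excl))

    try:
        roc = build_roc(results, replicate_auc=np.concatenate(auc_reps))
    except CohortError:
        roc = None  # fewer than two usable operating points (e.g. single-threshold runs)
    return results, roc


def build_roc(metrics: Sequence[ThresholdMetrics],
              replicate_auc: np.ndarray | None = None) -> ROCCurve:
    """ROC curve from per-threshold point estimates; AUC CI from replicate AUCs."""
    usable = [m for m in metrics if m.sensitivity is not None and m.specificity is not None]
    if len(usable) < 2:
        raise CohortError("ROC needs at least two thresholds with defined sensitivity and specificity")
    points = roc_points([1.0 - m.specificity.value for m in usable],
                        [m.sensitivity.value for m in usable])
    auc = trapezoid_auc(points)
    if replicate_auc is not None and np.isfinite(replicate_auc).any():
        lo, hi = np.nanpercentile(replicate_auc, [2.5, 97.5])
    else:
        lo = hi = auc
    return ROCCurve(points, Estimate(auc, float(lo), float(hi)))


def bootstrap_metrics(per_patient: Sequence[PatientThresholdSummary],
                      n_replicates: int = DEFAULT_REPLICATES,
                      seed: int = 0,
                      chunk: int = 10_000) -> BootstrapResult:
    """Patient-level bootstrap at a single threshold."""
    if not per_patient:
        raise CohortError("bootstrap_metrics needs at least one patient")
    thr = per_patient[0].threshold
    metrics_list, _ = evaluate_thresholds({thr: per_patient}, n_replicates=n_replicates,
                                          seed=seed, chunk=chunk)
    m = metrics_list[0]
    return BootstrapResult(n_replicates, seed,
                           {"sensitivity": m.sensitivity, "specificity": m.specificity,
                            "ppv": m.ppv, "npv": m.npv, "youden_j": m.youden_j,
                            "time_to_event": m.time_to_event, "event_rate": m.event_rate},
                           m.n_excluded)


def optimal_threshold(metrics: Sequence[ThresholdMetrics]) -> float:
    """Threshold maximizing the Youden's J point estimate; ties go to the higher threshold."""
    usable = [m for m in metrics if m.youden_j is not None]
    if not usable:
        raise CohortError("no threshold has a defined Youden's J")
    best_j = max(m.youden_j.value for m in usable)
    # J values within machine noise of the maximum count as tied
    tied = [m.threshold for m in usable if m.youden_j.value >= best_j - 1e-12]
    return max(tied)


# -- figures ----------------------------------------------------------------

def plot_roc(curve: ROCCurve, path=None, ax=None):
    """Plot the ROC curve with its AUC; returns the matplotlib axes."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.plot(curve.points[:, 0], curve.points[:, 1], marker="o", ms=3)
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("Sensitivity")
    ax.set_title(f"AUC {curve.auc.value:.2f} "
                 f"(95% CI {curve.auc.lower:.2f}-{curve.auc.upper:.2f})")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_event_rate(metrics: Sequence[ThresholdMetrics], path=None, ax=None):
    """Event rate (fraction of alarms followed by an event) against threshold."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    rows = [(m.threshold, m.event_rate) for m in metrics if m.event_rate is not None]
    thr = [r[0] for r in rows]
    ax.plot(thr, [r[1].value for r in rows], marker="o", ms=3)
    ax.fill_between(thr, [r[1].lower for r in rows], [r[1].upper for r in rows], alpha=0.2)
    ax.plot([0, 100], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("Index threshold")
    ax.set_ylabel("Event rate")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
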