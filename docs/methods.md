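# Methods

## The evaluation problem

A continuous hypotension-prediction index is a 0–100 signal sampled every
20 s alongside mean arterial pressure (MAP). The question it must answer is
prospective: *when the index rises above a threshold, does a hypotensive
event follow within a clinically useful horizon?* `hypoval` operationalizes
this as a **forward analysis**: the alarm is the anchor and the subsequent
20 min are screened for events, in contrast to a backward analysis that
anchors at events and inspects the index beforehand. The forward direction
matches bedside use — the clinician sees the alarm first — and is the
analysis this package implements; backward analysis is out of scope.

## Definitions

- **Hypotensive event**: MAP < 65 mmHg sustained for at least 1 min. At the
  20-s cadence this means ≥ 3 consecutive sub-threshold samples, measuring
  the span from the onset sample to the first sample back at ≥ 65 mmHg.
  That first recovered sample also defines the event end. If recording stops
  mid-event, the end is the last sample plus one interval.
- **Alarm qualification**: index strictly above the threshold for at least
  1 min (≥ 3 consecutive samples). Strictness matters at the boundary: an
  index bounded by 100 can never exceed a threshold of 100, so that row of a
  threshold sweep is all-negative by construction.
- **Quiet qualification**: index at or below the threshold for more than
  1 min, read literally as ≥ 4 consecutive samples ("more than" vs "at
  least"). Samples with missing index break both kinds of run.
- **Censoring**: from any baseline sample with MAP < 70 mmHg, a rise of
  ≥ 5 mmHg at the next sample or ≥ 8 mmHg within the following 2 min flags
  the span from the baseline to the rising sample as intervention-influenced
  (vasopressor bolus, positional maneuver). The sub-70 baseline condition
  applies to both rules: censoring targets rescues *from* hypotension.
  Overlapping flagged spans are merged.

## Window labeling

Each recording segment is scanned with a cursor. From the cursor, the next
anchor is the earlier of the next alarm qualification and the next quiet
qualification; a 20-min window opens there.

- Positive (alarm) window: **TP** if it contains ≥ 1 event onset (time to
  event = first onset − anchor), otherwise an FP candidate. An FP candidate
  overlapping a censored span is discarded — such spans would otherwise be
  counted as false positives even though the alarm was most plausibly
  answered by an intervention. A positive window anchored *inside* an ongoing
  event is discarded and the cursor jumps to the event end: an alarm during
  hypotension is detection, not prediction.
- Negative (quiet) window: preempted at the first alarm qualification inside
  it. If an event onset occurred before the preemption the window is **FN**;
  otherwise it is discarded and the cursor jumps to the preempting alarm,
  which then opens its own positive window. An unpreempted negative window is
  **FN** if it contains an event onset and **TN** otherwise.
- After any labeled window the cursor moves to the window end. Windows are
  therefore pairwise disjoint: no event is counted twice, and TN windows are
  capped at one per 20 min, containing the overrepresentation of quiet time.
- A window with less than 20 min of segment remaining is discarded — a short
  tail cannot fairly host a full screen.

Two points the protocol leaves open were resolved as follows, each behind a
switch. Negative windows are preemptible by alarms (default; the
non-preemptible variant is `negative_preemption=False`): preemption hands the
alarm its own fair screening window instead of silently absorbing it.
Alarms during ongoing hypotension do not open predictive windows (rule
above); the event-end jump prevents the tail of an event from generating
spurious positives. Censoring is applied at labeling time only — event
detection and burden statistics always use the uncensored series, since the
intervention changes the *interpretation* of the alarm, not the fact of the
preceding hypotension.

Half-open conventions are used throughout: a window `[u, u + 1200)` contains
onsets strictly after `u` and strictly before `u + 1200`, so time-to-event is
always positive and adjacent windows share no sample.

## Burden statistics

Per patient: monitoring time (summed segment spans), number of events, time
in hypotension, the area under the 65 mmHg threshold
(AUT = ∫ max(0, 65 − MAP) dt, mmHg·min, left-rectangle rule at the native
20-s cadence, no resampling) and the time-weighted average
TWA = AUT / monitoring time (mmHg). TWA·monitoring time = AUT is an exact
identity, asserted in tests. By default the AUT integrates over qualifying
events only, consistent with the event-based hypotension definition;
`aut_mode="all"` integrates every sub-65 sample including dips shorter than
1 min. Cohort summaries report medians with 25th–75th percentiles, totals,
and the fraction of patients with ≥ 1 event.

## Diagnostics and bootstrap

Sensitivity, specificity, PPV and NPV follow their standard ratio
definitions on pooled counts; any ratio with a zero denominator is missing
and propagates (it is excluded, never imputed). Youden's
J = sensitivity + specificity − 1 selects the optimal threshold over the
grid 0, 5, …, 100; ties within machine precision go to the higher threshold
(fewer alarms at equal discrimination).

Screening windows repeat within patients, so confidence intervals resample
**patients** with replacement (cohort size preserved). Each replicate
re-pools counts and recomputes every metric; the same patient resample is
shared across thresholds so each replicate traces a coherent ROC curve.
Reported point estimates are replicate medians with percentile (2.5/97.5)
95% intervals; the default is 100,000 replicates (tests and the acceptance
script use 1,000–10,000, which changes the intervals negligibly at these
cohort sizes). Replicates where a metric is undefined are dropped for that
metric, with the exclusion count logged. Reported Youden's J is the identity
applied to the reported sensitivity and specificity medians — so the printed
row always satisfies J = sens + spec − 1 exactly — while its interval comes
from the replicate J distribution.

The ROC curve uses the per-threshold point estimates with (0,0) and (1,1)
anchors, sorted by false-positive rate, integrated by the trapezoidal rule;
the AUC interval applies the same integration replicate-wise. Replicates
with any undefined operating point are excluded from the AUC percentiles.

## The synthetic cohort generator

The generator produces the conditions the pipeline assumes, with every
deviation from perfection explicit and recorded in the ground truth.

- **Baseline**: stationary AR(1) around 75 mmHg (sd 1.5 mmHg, mean-reversion
  0.9 per sample) — calm enough that spurious sub-65 runs essentially never
  occur at the defaults.
- **Episodes**: Poisson arrivals (default 0.3/h; an arrival that would
  overlap the previous episode's footprint is shifted to the next free slot,
  preserving the count apart from a small end-of-trace loss). Shape: 60-s
  descent from baseline to 65 mmHg, 60-s descent to the nadir
  (depth ~ N(5, 2²) mmHg below 65, clipped to [2, 45]), a plateau sized to
  the drawn duration (N(300, 120²) s, floored at 60 s so every injected
  episode qualifies), then recovery at +1 mmHg per 20-s step — deliberately
  slower than both censoring rules, so natural recoveries are never censored.
  With probability `artifact_probability` the episode instead ends in a
  rescue of +6 mmHg per step from the nadir, which by construction trips the
  20-s censoring rule. Pressures are rounded to 0.1 mmHg (and the index to
  0.01) *before* ground truth is derived, so traces round-trip exactly
  through the file format and detection matches ground truth sample for
  sample.
- **Index**: `100·logistic(gain·(65 − min MAP over [t, t+horizon)))` with a
  5-min default horizon, which yields median warning times of ~4–5 min.
  Imperfections: per-episode misses (the episode span is hidden from the
  look-ahead; default probability 0.05), false-alarm bursts (Poisson, default
  0.2/h, 2 min at a level drawn uniformly from [10, 100] — the uniform level
  makes specificity rise gradually with threshold), and additive Gaussian
  noise (default sd 5).
- **Reproducibility**: one global seed; per-patient substreams are derived
  from (seed, patient ordinal, channel), so any patient regenerates
  individually and cohort regeneration is byte-identical.
- **Default scale**: 41 patients × 70 h — at 0.3 events/h this reproduces the
  kind of cohort the pipeline targets (≈ 21 events per patient, ≈ 2–3% of
  case time hypotensive, TWA ≈ 0.08 mmHg).

What the generator does **not** emulate: waveform morphology, pharmacokinetic
vasopressor responses, circadian or treatment-driven nonstationarity,
measurement dropouts correlated with clinical state, or an index with
realistic autocorrelated errors. Passing the recovery tests therefore shows
that the *pipeline* is correct (it recovers known answers from data obeying
its assumptions), not that any particular bedside index performs well on
real patients.

One generator parameter exists specifically for construction-exact
experiments: `min_episode_gap`. With the default 60 s, two episodes can fall
inside one screening window (a missed episode adjacent to a detected one is
absorbed into the detected episode's TP window), so window-level sensitivity
is only approximately 1 − miss probability. Setting the gap beyond
window + horizon (e.g. 1500 s) makes episodes and windows correspond one to
one, and the recovery tests for known sensitivity use exactly that setting.

## Numerical and I/O choices

- Trace dialect: CSV `time_s,map_mmhg,index`, time in seconds from record
  start; missing index allowed (the sample participates in event detection
  but not alarm detection). Recording gaps > 60 s split a record into
  segments; events, qualifications and windows are never evaluated across a
  gap, because a 1-min qualification cannot be judged across missing data.
- Out-of-range values (MAP outside 10–250 mmHg, index outside [0, 100],
  duplicate timestamps) are report-only findings; only decreasing timestamps
  and missing columns are hard errors, and unparseable rows are dropped with
  a logged count.
- The replicate-median for time-to-event uses a weighted median consistent
  with `numpy.median` on the expanded sample (straddling values averaged at
  exact half-weight).
- Bootstrap memory is bounded by chunking replicates (10,000 per chunk).

## Known limitations

- Event rate is defined per alarm onset (before window shifting), which is
  why it differs from PPV; with no alarms at a threshold it is undefined.
- A quiet anchor falling inside an ongoing (undetected) event opens a
  negative window that contains no *onset* and thus counts TN; the labeling
  rules account events strictly by onsets. This only arises for indices that
  fail during hypotension itself.
- Percentile bootstrap intervals are approximate for small cohorts; with few
  patients or few events per patient they undercover slightly, as the
  coverage test over 200 simulated experiments documents at realistic scale.
- The AUT/TWA integration is left-rectangle at 20 s; against a trapezoid
  oracle it agrees to within ~5% on synthetic traces.
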