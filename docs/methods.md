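# Methods

This note documents the models, conventions and design choices behind
`pphypo`, in the order the pipeline applies them.

## Data model and preprocessing (`pphypo.cgm_io`)

A CGM series is a glucose vector on a strict 5-minute grid (index k ↔
minute 5·k), in mg/dL, with NaN marking missing sensor readings, plus the
raw meal-announcement grid indices and the clock time of the first sample.
All thresholds are fixed internally in mg/dL — 70 (alert), 54 (severe),
80 (near-hypo), i.e. 3.9 / 3.0 / 4.4 mmol/L at 18.016 mg/dL per mmol/L —
to avoid unit-conversion drift; mmol/L input is converted on read.

**Gap filling.** Maximal runs of 1–2 consecutive missing readings are
filled with a natural cubic spline fitted once on all present points of
the series; runs of ≥ 3 are left missing and simply suppress the samples
that would need them. Fitting globally (rather than locally around each
gap) uses all available shape information and makes the operation
idempotent; the choice matters little for 1–2-point gaps but is the
documented convention. Series with fewer than 4 present points are
rejected (spline underdetermined).

**Meal filtering.** Announcements in the nocturnal interval
[23:00, 07:00) are discarded — half-open, so an 07:00 announcement
survives. Repeat announcements are then collapsed: an announcement
survives iff the nearest later surviving announcement is ≥ 120 min away
(exactly 120 min does not merge). This backward formulation has the
property that removing an announcement that would be dropped anyway never
changes the result, which a forward-transitive scan does not satisfy.

**Windows.** The postprandial window is indexed t = 0..42 (0 = meal-time
point, 42 = 3.5 h). Windows of meals closer than 3.5 h may overlap in
series time; windows are truncated at the series end rather than padded.

## Features and labels (`pphypo.features`)

Samples are emitted for t = 1..42. RIG uses the running maximum of window
steps 0..t with smallest-index tie-break; peak at index 0 means "no rise"
and yields RIG = 0 (which also avoids a zero time-difference). GRC at
t = 1 uses the meal-time point as its left operand. The label needs the
point at t+6 (30-min horizon), so a full sample requires window points
0..t and t+6; a sample with any required point missing is skipped and
counted, never imputed beyond the ≤ 2-point spline fill. Features are
computed on raw mg/dL and only then MinMax-scaled with extrema learned on
the training folds of the current split (test values may fall outside
[0, 1]; a degenerate feature maps to 0). The two-feature ablation
{CGM, GRC} is applied at model-matrix time, so labels, folds and events
are identical across ablations.

## Synthetic cohort (`pphypo.synthetic`)

The generator emulates the study conditions: 100 series of 3 days at
5-min sampling, ~3 announced daytime meals/day (08:00/13:00/19:00 ± 20
min), occasional redundant pre-meal finger-sticks and nocturnal sticks to
exercise the filters, ~2% missing samples, and smooth AR(1) sensor noise
(coefficient 0.7, stationary SD 5 mg/dL) appropriate for retrospective
CGM traces. A meal response is

    baseline + amplitude·(τ/tp)·e^(1−τ/tp) − drop·(1 − 2^(−τ/halflife)),

floored at 40 mg/dL — the simplest form that realizes the four
postprandial archetypes (no peak; low peak then fall; steep peak then
rapid fall; fall-from-meal under insulin on board) with three shape
parameters each. Beyond 240 min post-meal the drop term relaxes back
toward zero with a 90-min half-life so multi-day traces return to
baseline; this tail is part of series assembly, not of the single-meal
response form. With probability `hypo_probability` a meal's insulin drop
is scaled up (×1.0–1.25) to plant a hypoglycemic excursion; otherwise it
is scaled down and capped relative to the series baseline so non-planted
meals cannot cross 70 mg/dL — ground truth is therefore exactly the event
extraction on the noiseless curve, and label noise is attributable to the
sensor model alone. Evening meals may carry a delayed nocturnal dip
(trough 6.5–8.5 h post-meal): it adds sub-70 readings outside the 4-h
labeled window, decoupling the cohort-level sub-70 fraction from the
label imbalance, as in clinical cohorts where much hypoglycemia is
nocturnal. Archetype parameters were calibrated once so the default
cohort lands at ~6–8% of readings below 70 mg/dL (target band 5–15%) and
a negative:positive sample ratio of ~10–17:1, and were frozen.

What the generator does **not** model: physiological glucose–insulin
dynamics (no Bergman/Hovorka ODEs), carbohydrate content, exercise,
stress, circadian basal drift, or sensor artifacts beyond AR(1) noise and
dropout. Passing tests on this cohort therefore demonstrate that the
pipeline recovers planted, smoothly-shaped excursions under mild sensor
noise — not clinical-grade performance; clinical metric values are
expected to be worse than the synthetic ones.

## Training (`pphypo.training`)

The false-negative cost is the exact rational negative:positive label
ratio of the training folds (`fractions.Fraction`), false-positive cost 1,
correct decisions 0. Costs enter as per-class sample weights for the
forest, SVMs and logistic regression; for KNN — which has no weighted-
class form in scikit-learn — positive neighbor votes are multiplied by
the cost before the majority comparison, giving the score
w·n⁺/(w·n⁺+n⁻). The linear SVM uses `LinearSVC` (liblinear); both SVMs
expose scores through a logistic map of the signed margin, which is
monotone (AUC unchanged) and makes the 0.5 threshold coincide with the
decision boundary. The decision threshold is 0.5 throughout; ROC/AUC is
threshold-free.

Cross-validation is grouped by **patient** (series of dual-session
patients stay together): patients are shuffled by seed and dealt
round-robin into k = 5 folds. Hyperparameters come from a subject-grouped
inner grid search minimizing the cost-weighted misclassification loss
(cost_fn·FN + FP)/n, ties broken by declared grid order. Two grids ship:
`DEFAULT_GRIDS` (wider) and `FAST_GRIDS` (RF: 100 trees × depth {8, ∞};
LinearSVC/LR: C ∈ {0.1, 1, 10}; SVC-RBF: C = 10, γ = scale; KNN:
k ∈ {5, 15, 31}). The cohort-scale experiments and the acceptance script
use `FAST_GRIDS` with a 2-fold inner search — at ~38,000 samples the RBF
SVM costs tens of seconds per fit, and the compact grid keeps a full
five-family, 5-fold run in the couple-of-minutes range on one CPU without
materially changing the results at this problem size.

## Metrics (`pphypo.event_metrics`)

Sample level: sensitivity, specificity, precision, F1, with zero-
denominator ratios reported as NaN (never 0) and excluded from cross-fold
averages; AUC by trapezoidal integration over the empirical ROC (equal to
the Mann–Whitney rank statistic with ties ½).

Event level, all boundary conventions explicit:

* event = maximal run of ≥ 2 consecutive readings < 70 mg/dL; runs whose
  recovery gap is ≤ 10 min (≤ 2 grid steps) merge; 15 min splits;
* an event is postprandial iff its start lies in (meal+5, meal+240] min
  and is assigned to the latest such meal (single-count under window
  overlap);
* events starting ≤ 10 min post-meal are *excluded-immediate*: there is no
  room for two prior prediction steps, so they count in NH but not in the
  TP/miss denominators; an alarm whose only forward event is excluded is
  not counted false;
* alarm = maximal run of ≥ 2 consecutive positive predictions at adjacent
  steps (skipped samples break runs), stamped at the run's first step;
  runs wholly inside an ongoing event are discarded;
* matching: an event is truly alarmed iff an alarm fires in
  [start−60, start); the earliest defines DT ∈ (0, 60]; an alarm with no
  event starting in (alarm, alarm+60] is false; FAR = FP_e/(TP_e+FP_e),
  NaN when no alarms;
* severity: an event is severe if any constituent reading < 54 mg/dL; a
  false alarm is "near-hypo-associated" if a stretch of ≥ 2 consecutive
  readings ≤ 80 mg/dL starts within the 60 min after it;
* DT and FAR are averaged per fold, then mean (SD) across folds; folds
  with undefined values are omitted from the average.

## Orchestration and reproducibility (`pphypo.pipeline`)

One experiment seed fans out (via `numpy` SeedSequence-derived children)
to the cohort simulation, the fold shuffle, the inner grid search and the
stochastic learners, so identical configurations produce byte-identical
report files. Outputs are per-fold and mean (SD) summary CSVs, a JSON
manifest per trained model (family, hyperparameters, cost, scaler
extrema, fold), and a JSONL stage log. `compare_runs` produces per-fold
paired metric deltas for ablation comparisons on a shared fold structure.

## Known limitations

* The synthetic archetypes are qualitative; no claim of physiological
  fidelity is made beyond the cohort-level statistics named above.
* The decision threshold is fixed at 0.5; only AUC is threshold-free.
* Event matching assumes the 5-min grid; irregular sampling is out of
  scope, as are real-time (unsmoothed) sensor noise models, alarm
  snoozing policies, and significance testing across families.
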