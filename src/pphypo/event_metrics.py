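"""Sample-level metrics and the event/alarm calculus.

Sample level: sensitivity, specificity, precision, F1 and the trapezoidal
ROC AUC over the per-sample scores.

Event level: a *hypoglycemic event* is a merged run of at least two
consecutive readings below 70 mg/dL whose start falls 5 min-4 h after a
meal; runs separated by at most 10 min (two grid steps) of recovery are
merged.  An *alarm* is a maximal run of at least two consecutive positive
predictions at adjacent prediction steps, stamped at the run's first step;
runs lying wholly inside an ongoing event are not alarms.  An event is
truly alarmed when an alarm fires within the 60 min before its start; the
earliest such alarm defines the detection time (DT).  Alarms with no event
starting in the following 60 min are false (FP_e), and

    FAR = FP_e / (TP_e + FP_e).

Events starting within 10 min of the meal are excluded from the alarm
accounting (no room for two prior predictions) but still counted in NH.
Severity strata: an event is *severe* when any constituent reading is
below 54 mg/dL (3.0 mmol/L); a *near-hypoglycemic* stretch is two or more
consecutive readings at or below 80 mg/dL (4.4 mmol/L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cgm_io import (
    CGMSeries,
    GRID_MINUTES,
    HYPO_ALERT_MGDL,
    NEAR_HYPO_MGDL,
    SEVERE_HYPO_MGDL,
    MealAnnouncement,
)

#: postprandial interval for event accounting: (meal + 5 min, meal + 4 h]
POSTPRANDIAL_MIN = 5
POSTPRANDIAL_MAX = 240
#: alarm/event matching horizon, minutes
MATCH_MINUTES = 60
#: merge events separated by at most this much recovery, minutes
EVENT_MERGE_GAP_MIN = 10
#: immediate-post-meal exclusion: event start <= meal + 10 min
IMMEDIATE_EXCLUSION_MIN = 10
#: minimum run lengths, grid steps
MIN_EVENT_RUN = 2
MIN_ALARM_RUN = 2


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class SampleMetrics:
    """Per-sample ratios; undefined ratios (zero denominator) are NaN."""

    sensitivity: float
    specificity: float
    precision: float
    f1: float
    auc: float


@dataclass(frozen=True)
class HypoEvent:
    series_id: str
    start_minute: int
    end_minute: int          # minute of the last constituent point
    meal_index: int
    severe: bool
    excluded_immediate: bool


@dataclass(frozen=True)
class AlarmRecord:
    series_id: str
    alarm_minute: int        # series minute of the first positive of the run
    meal_index: int


@dataclass
class EventMetrics:
    nh: int = 0
    tp_e: int = 0
    fp_e: int = 0
    far: float = math.nan
    dt: float = math.nan     # mean minutes over truly alarmed events
    severe_alarmed: int = 0
    severe_missed: int = 0
    near_hypo_fa_frac: float = math.nan
    matched: list[tuple[HypoEvent, AlarmRecord]] = field(default_factory=list)
    missed_events: list[HypoEvent] = field(default_factory=list)
    false_alarms: list[AlarmRecord] = field(default_factory=list)


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Trapezoidal area under the ROC curve over all score thresholds."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return math.nan
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    # threshold at each distinct score: cumulative TP/FP after each tie block
    distinct = np.r_[np.flatnonzero(np.diff(s) != 0), len(s) - 1]
    tps = np.cumsum(y)[distinct]
    fps = (distinct + 1) - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return float(np.trapezoid(tpr, fpr))


def sample_metrics(
    labels: Sequence[int],
    predictions: Sequence[int],
    scores: Sequence[float],
) -> tuple[ConfusionCounts, SampleMetrics]:
    """Confusion counts and the standard ratios plus trapezoidal AUC."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if len(y) == 0:
        raise ValueError("no samples to evaluate")
    if not (len(y) == len(p) == len(scores)):
        raise ValueError("labels, predictions and scores must be equal length")
    tp = int(np.sum((y == 1) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    sens = _safe_ratio(tp, tp + fn)
    spec = _safe_ratio(tn, tn + fp)
    prec = _safe_ratio(tp, tp + fp)
    f1 = (
        2 * prec * sens / (prec + sens)
        if not (math.isnan(prec) or math.isnan(sens)) and (prec + sens) > 0
        else math.nan
    )
    return ConfusionCounts(tp, tn, fp, fn), SampleMetrics(
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        f1=f1,
        auc=roc_auc(y, scores),
    )


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) inclusive index pairs."""
    runs = []
    k, n = 0, len(mask)
    while k < n:
        if mask[k]:
            j = k
            while j + 1 < n and mask[j + 1]:
                j += 1
            runs.append((k, j))
            k = j + 1
        else:
            k += 1
    return runs


def extract_hypo_events(
    series: CGMSeries,
    meals: Sequence[MealAnnouncement],
    glucose: np.ndarray | None = None,
) -> list[HypoEvent]:
    """Postprandial hypoglycemic events of a series.

    Pipeline: maximal runs of >=2 consecutive readings < 70 mg/dL; runs
    whose recovery gap is <= 10 min are merged; an event is kept iff its
    start lies in (meal+5 min, meal+240 min] for some meal, and is assigned
    to the latest such meal.  ``glucose`` overrides the series trace (used
    to extract ground truth from a noiseless curve).  Missing readings
    break runs.
    """
    g = series.glucose if glucose is None else np.asarray(glucose, dtype=float)
    with np.errstate(invalid="ignore"):
        hypo = (g < HYPO_ALERT_MGDL) & ~np.isnan(g)
    runs = [r for r in _bool_runs(hypo) if r[1] - r[0] + 1 >= MIN_EVENT_RUN]
    merged: list[tuple[int, int]] = []
    for first, last in runs:
        if merged and GRID_MINUTES * (first - merged[-1][1] - 1) <= EVENT_MERGE_GAP_MIN:
            merged[-1] = (merged[-1][0], last)
        else:
            merged.append((first, last))

    events: list[HypoEvent] = []
    for first, last in merged:
        start_min = GRID_MINUTES * first
        owner = None
        for meal in meals:  # latest meal whose interval contains the start
            meal_min = GRID_MINUTES * meal.grid_index
            if meal_min + POSTPRANDIAL_MIN < start_min <= meal_min + POSTPRANDIAL_MAX:
                owner = meal
        if owner is None:
            continue
        meal_min = GRID_MINUTES * owner.grid_index
        events.append(
            HypoEvent(
                series_id=series.series_id,
                start_minute=start_min,
                end_minute=GRID_MINUTES * last,
                meal_index=owner.meal_index,
                severe=bool(np.nanmin(g[first : last + 1]) < SEVERE_HYPO_MGDL),
                excluded_immediate=start_min <= meal_min + IMMEDIATE_EXCLUSION_MIN,
            )
        )
    return events


def detect_alarms(
    predictions: Mapping[int, int],
    series_id: str,
    meal: MealAnnouncement,
    events: Sequence[HypoEvent] = (),
) -> list[AlarmRecord]:
    """Alarms raised by one meal window's hard predictions.

    ``predictions`` maps prediction step t (1..42) to a 0/1 hard label;
    absent steps (skipped samples) break runs.  Each maximal run of >=2
    consecutive positives yields one alarm stamped at the run's first step.
    Runs lying wholly inside an ongoing hypoglycemic event are discarded.
    """
    if not predictions:
        return []
    t_max = max(predictions)
    arr = np.zeros(t_max + 1, dtype=bool)
    for t, p in predictions.items():
        arr[t] = bool(p)
    meal_min = GRID_MINUTES * meal.grid_index
    alarms = []
    for first, last in _bool_runs(arr):
        if last - first + 1 < MIN_ALARM_RUN:
            continue
        run_start = meal_min + GRID_MINUTES * first
        run_end = meal_min + GRID_MINUTES * last
        inside = any(
            ev.start_minute <= run_start and run_end <= ev.end_minute for ev in events
        )
        if inside:
            continue
        alarms.append(
            AlarmRecord(series_id=series_id, alarm_minute=run_start, meal_index=meal.meal_index)
        )
    return alarms


def match_alarms_events(
    alarms: Sequence[AlarmRecord],
    events: Sequence[HypoEvent],
) -> EventMetrics:
    """Match alarms to events within the 60-min horizon and compute FAR/DT.

    An event (not excluded-immediate) is truly alarmed iff at least one
    alarm fires in [start-60, start); the earliest such alarm defines
    DT = start - alarm_minute.  An alarm matched to no event starting in
    (alarm, alarm+60] is false.  Excluded-immediate events count in NH only.
    """
    m = EventMetrics(nh=len(events))
    alarmed_any: set[int] = set()  # indices of events (incl. excluded) with an alarm
    dts: list[float] = []
    for i, ev in enumerate(events):
        cands = [
            a
            for a in alarms
            if a.series_id == ev.series_id
            and ev.start_minute - MATCH_MINUTES <= a.alarm_minute < ev.start_minute
        ]
        if cands:
            alarmed_any.add(i)
            if not ev.excluded_immediate:
                first = min(cands, key=lambda a: a.alarm_minute)
                m.tp_e += 1
                dts.append(float(ev.start_minute - first.alarm_minute))
                m.matched.append((ev, first))
        elif not ev.excluded_immediate:
            m.missed_events.append(ev)

    for a in alarms:
        has_event = any(
            ev.series_id == a.series_id
            and a.alarm_minute < ev.start_minute <= a.alarm_minute + MATCH_MINUTES
            for ev in events
        )
        if not has_event:
            m.fp_e += 1
            m.false_alarms.append(a)

    m.far = _safe_ratio(m.fp_e, m.tp_e + m.fp_e)
    m.dt = float(np.mean(dts)) if dts else math.nan
    stats = severe_event_stats(events, {events[i].start_minute for i in alarmed_any
                                        if not events[i].excluded_immediate})
    m.severe_alarmed, m.severe_missed = stats
    return m


def severe_event_stats(
    events: Sequence[HypoEvent], alarmed_start_minutes: set[int]
) -> tuple[int, int]:
    """Partition severe (<54 mg/dL) non-excluded events into alarmed/missed."""
    alarmed = missed = 0
    for ev in events:
        if not ev.severe or ev.excluded_immediate:
            continue
        if ev.start_minute in alarmed_start_minutes:
            alarmed += 1
        else:
            missed += 1
    return alarmed, missed


def near_hypo_false_alarm_fraction(
    false_alarms: Sequence[AlarmRecord],
    series_map: Mapping[str, CGMSeries],
) -> float:
    """Fraction of false alarms followed within 60 min by a near-hypo stretch.

    A near-hypoglycemic stretch is >=2 consecutive readings <= 80 mg/dL;
    the stretch must *start* within (alarm, alarm + 60] minutes.  NaN when
    there are no false alarms.
    """
    if not false_alarms:
        return math.nan
    qualifying = 0
    for a in false_alarms:
        g = series_map[a.series_id].glucose
        with np.errstate(invalid="ignore"):
            near = (g <= NEAR_HYPO_MGDL) & ~np.isnan(g)
        for first, last in _bool_runs(near):
            if last - first + 1 < 2:
                continue
            start_min = GRID_MINUTES * first
            if a.alarm_minute < start_min <= a.alarm_minute + MATCH_MINUTES:
                qualifying += 1
                break
    return qualifying / len(false_alarms)
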