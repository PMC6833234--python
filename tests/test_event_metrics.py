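"""Sample metrics, ROC AUC, and the event/alarm calculus, each checked
against exhaustive brute-force implementations of the run/merge/matching
rules on random inputs."""

import math

import numpy as np
import pytest

from pphypo.cgm_io import GRID_MINUTES, HYPO_ALERT_MGDL
from pphypo.event_metrics import (
    AlarmRecord,
    HypoEvent,
    detect_alarms,
    extract_hypo_events,
    match_alarms_events,
    near_hypo_false_alarm_fraction,
    roc_auc,
    sample_metrics,
    severe_event_stats,
)
from conftest import make_series, meal


# ----------------------------------------------------------------- oracles

def brute_runs(flags, min_len):
    """All maximal True runs of length >= min_len, by direct scan."""
    runs, start = [], None
    for k, v in enumerate(list(flags) + [False]):
        if v and start is None:
            start = k
        elif not v and start is not None:
            if k - start >= min_len:
                runs.append((start, k - 1))
            start = None
    return runs


def brute_events(glucose, meal_indices):
    """Run/merge/postprandial rules recomputed step by step."""
    hypo = [(not math.isnan(g)) and g < HYPO_ALERT_MGDL for g in glucose]
    runs = brute_runs(hypo, 2)
    merged = []
    for r in runs:
        if merged and 5 * (r[0] - merged[-1][1] - 1) <= 10:
            merged[-1] = (merged[-1][0], r[1])
        else:
            merged.append(r)
    out = []
    for first, last in merged:
        start_min = 5 * first
        owners = [
            m for m in meal_indices if 5 * m + 5 < start_min <= 5 * m + 240
        ]
        if owners:
            out.append((start_min, 5 * last, 5 * max(owners)))
    return out


def brute_alarms(pred_by_t):
    """Maximal >=2 runs of consecutive positive steps, stamped at run start."""
    if not pred_by_t:
        return []
    t_max = max(pred_by_t)
    flags = [bool(pred_by_t.get(t, 0)) for t in range(t_max + 1)]
    return [5 * first for first, _ in brute_runs(flags, 2)]


def rank_auc(labels, scores):
    """Probability a random positive outscores a random negative, ties 1/2."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    if not pos or not neg:
        return math.nan
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# ------------------------------------------------------------ sample level

class TestSampleMetrics:
    def test_direct_ratios(self):
        y = [1] * 8 + [1] * 2 + [0] * 90 + [0] * 10
        p = [1] * 8 + [0] * 2 + [0] * 90 + [1] * 10
        counts, m = sample_metrics(y, p, [float(v) for v in p])
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (8, 2, 90, 10)
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.9)
        assert m.precision == pytest.approx(8 / 18)
        assert m.f1 == pytest.approx(2 * (8 / 18) * 0.8 / (8 / 18 + 0.8))

    def test_undefined_ratios_are_nan_not_zero(self):
        counts, m = sample_metrics([0, 0], [0, 0], [0.1, 0.2])
        assert math.isnan(m.sensitivity)
        assert m.specificity == 1.0
        assert math.isnan(m.precision)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            sample_metrics([], [], [])

    def test_constant_scores_auc_half(self):
        assert roc_auc([1, 0, 1, 0], [0.3] * 4) == pytest.approx(0.5)

    def test_separating_scores_auc_one(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == pytest.approx(1.0)

    def test_trapezoidal_auc_equals_rank_statistic(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(4, 60))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                y[0], y[-1] = 0, 1
            s = np.round(rng.random(n), 2)  # coarse grid -> plenty of ties
            assert roc_auc(y, s) == pytest.approx(rank_auc(y, s), abs=1e-9)


# ------------------------------------------------------------- event level

def series_from_flags(flags, meal_indices=(0,)):
    g = np.where(np.asarray(flags, dtype=bool), 60.0, 120.0)
    return make_series(g, raw_meal_times=list(meal_indices))


class TestExtractEvents:
    def test_lone_point_is_no_event(self):
        s = series_from_flags([0, 0, 1, 0, 0] + [0] * 40)
        assert extract_hypo_events(s, [meal(0)]) == []

    def test_short_gap_merges_runs(self):
        # two sub-70 runs separated by one recovered point (5-min gap)
        flags = [0] * 5 + [1, 1, 0, 1, 1] + [0] * 35
        (ev,) = extract_hypo_events(series_from_flags(flags), [meal(0)])
        assert (ev.start_minute, ev.end_minute) == (25, 45)

    def test_long_gap_splits_runs(self):
        flags = [0] * 5 + [1, 1, 0, 0, 0, 1, 1] + [0] * 35
        events = extract_hypo_events(series_from_flags(flags), [meal(0)])
        assert len(events) == 2

    def test_event_outside_postprandial_interval_dropped(self):
        flags = [0] * 50 + [1, 1] + [0] * 20   # starts 250 min post-meal
        assert extract_hypo_events(series_from_flags(flags), [meal(0)]) == []

    def test_overlap_assigns_latest_meal(self):
        flags = [0] * 40 + [1, 1] + [0] * 30
        s = series_from_flags(flags, meal_indices=[0, 30])
        (ev,) = extract_hypo_events(s, [meal(0, 1), meal(30, 2)])
        assert ev.meal_index == 2

    def test_severe_and_immediate_flags(self):
        g = np.full(60, 120.0)
        g[2:5] = 50.0   # starts 10 min post-meal -> excluded, severe
        s = make_series(g, raw_meal_times=[0])
        (ev,) = extract_hypo_events(s, [meal(0)])
        assert ev.severe and ev.excluded_immediate

    def test_random_traces_match_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            n = int(rng.integers(5, 50))
            flags = rng.random(n) < 0.3
            meal_at = int(rng.integers(0, max(1, n - 2)))
            s = series_from_flags(flags, meal_indices=[meal_at])
            got = [
                (e.start_minute, e.end_minute, GRID_MINUTES * meal_at)
                for e in extract_hypo_events(s, [meal(meal_at)])
            ]
            assert got == brute_events(s.glucose, [meal_at])


class TestDetectAlarms:
    def test_single_run_rule(self):
        preds = {1: 0, 2: 1, 3: 1, 4: 0}
        (a,) = detect_alarms(preds, "S0", meal(0))
        assert a.alarm_minute == 10

    def test_isolated_positives_no_alarm(self):
        assert detect_alarms({1: 0, 2: 1, 3: 0, 4: 1, 5: 0}, "S0", meal(0)) == []

    def test_all_positive_single_alarm(self):
        (a,) = detect_alarms({t: 1 for t in range(1, 5)}, "S0", meal(0))
        assert a.alarm_minute == 5

    def test_skipped_steps_break_runs(self):
        # t=3 missing (sample skipped): 2 and 4 are not consecutive
        assert detect_alarms({2: 1, 4: 1, 5: 0}, "S0", meal(0)) == []

    def test_run_inside_event_discarded(self):
        ev = HypoEvent("S0", start_minute=10, end_minute=40, meal_index=1,
                       severe=False, excluded_immediate=False)
        preds = {3: 1, 4: 1}   # minutes 15..20, inside the event
        assert detect_alarms(preds, "S0", meal(0), events=[ev]) == []
        preds2 = {1: 1, 2: 1}  # minutes 5..10, straddles the event start
        assert len(detect_alarms(preds2, "S0", meal(0), events=[ev])) == 1

    def test_random_sequences_match_brute_force(self):
        rng = np.random.default_rng(13)
        for _ in range(300):
            n = int(rng.integers(1, 43))
            preds = {t: int(rng.random() < 0.4) for t in range(1, n + 1)}
            got = [a.alarm_minute for a in detect_alarms(preds, "S0", meal(0))]
            assert got == brute_alarms(preds)


def ev(start, end=None, series="S0", severe=False, excluded=False):
    return HypoEvent(series, start, end if end is not None else start + 10,
                     meal_index=1, severe=severe, excluded_immediate=excluded)


def al(minute, series="S0"):
    return AlarmRecord(series_id=series, alarm_minute=minute, meal_index=1)


class TestMatching:
    def test_single_true_alarm(self):
        m = match_alarms_events([al(70)], [ev(100)])
        assert (m.tp_e, m.fp_e, m.far, m.dt) == (1, 0, 0.0, 30.0)

    def test_far_arithmetic(self):
        alarms = [al(70), al(170), al(270), al(500)]
        events = [ev(100), ev(200), ev(300)]
        m = match_alarms_events(alarms, events)
        assert (m.tp_e, m.fp_e) == (3, 1)
        assert m.far == pytest.approx(0.25)

    def test_sixty_minute_horizon_excludes_early_alarm(self):
        m = match_alarms_events([al(30)], [ev(100)])
        assert (m.tp_e, m.fp_e) == (0, 1)
        assert m.far == 1.0
        assert len(m.missed_events) == 1

    def test_earliest_alarm_defines_dt(self):
        m = match_alarms_events([al(45), al(80)], [ev(100)])
        assert m.tp_e == 1
        assert m.dt == 55.0

    def test_excluded_event_in_nh_but_not_denominators(self):
        m = match_alarms_events([al(70)], [ev(100, excluded=True)])
        assert m.nh == 1
        assert (m.tp_e, m.fp_e) == (0, 0)
        assert math.isnan(m.far)

    def test_all_negative_predictor(self):
        m = match_alarms_events([], [ev(100)])
        assert (m.tp_e, m.fp_e) == (0, 0)
        assert math.isnan(m.far) and math.isnan(m.dt)

    def test_alarms_and_events_matched_within_series_only(self):
        m = match_alarms_events([al(70, series="S1")], [ev(100, series="S2")])
        assert (m.tp_e, m.fp_e) == (0, 1)

    def test_dt_bounded_by_matching_window(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            alarms = [al(int(m)) for m in rng.integers(0, 400, size=4)]
            events = [ev(int(s)) for s in rng.integers(50, 450, size=3)]
            m = match_alarms_events(alarms, events)
            for e, a in m.matched:
                assert 0 < e.start_minute - a.alarm_minute <= 60


class TestSeverityStrata:
    def test_severe_partition(self):
        events = [ev(100, severe=True), ev(300, severe=True), ev(500)]
        alarmed, missed = severe_event_stats(events, {100})
        assert (alarmed, missed) == (1, 1)

    def test_no_severe_events(self):
        assert severe_event_stats([ev(100)], {100}) == (0, 0)

    def test_matching_populates_severe_counts(self):
        m = match_alarms_events([al(70)], [ev(100, severe=True), ev(400, severe=True)])
        assert (m.severe_alarmed, m.severe_missed) == (1, 1)


class TestNearHypoFalseAlarms:
    def _series(self, glucose):
        return {"S0": make_series(glucose)}

    def test_qualifying_false_alarm(self):
        g = np.full(40, 120.0)
        g[10:12] = 78.0   # near-hypo stretch starting at minute 50
        frac = near_hypo_false_alarm_fraction([al(30)], self._series(g))
        assert frac == 1.0

    def test_single_point_does_not_qualify(self):
        g = np.full(40, 120.0)
        g[10] = 78.0
        assert near_hypo_false_alarm_fraction([al(30)], self._series(g)) == 0.0

    def test_fraction_arithmetic(self):
        g = np.full(100, 120.0)
        g[20:22] = 80.0   # stretch at minute 100 (<= is inclusive)
        alarms = [al(50), al(60), al(400), al(420), al(440)]
        frac = near_hypo_false_alarm_fraction(alarms, self._series(g))
        assert frac == pytest.approx(2 / 5)

    def test_no_false_alarms_is_nan(self):
        assert math.isnan(near_hypo_false_alarm_fraction([], self._series(np.full(10, 120.0))))
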