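"""Synthetic CGM cohort generator.

Emulates retrospective 5-min CGM traces over ~3 days with ~3 announced
daytime meals per day, reproducing the four qualitative postprandial
archetypes seen in clinical traces:

* ``NO_PEAK`` — little or no post-meal rise (small carbohydrate load), a
  slow insulin-driven fall that may reach hypoglycemia;
* ``LOW_PEAK_FALL`` — a modest peak then a fall;
* ``STEEP_PEAK_FALL`` — a steep high peak then a rapid fall (high-glycemic
  meal or late rapid-acting insulin);
* ``IOB_FALL`` — glucose falls from the meal onward (insulin on board from
  the previous meal), i.e. the insulin drop dominates any rise.

A meal response is a gamma-shaped rise minus a saturating insulin drop:

    g(tau) = baseline + amplitude * (tau/tp) * exp(1 - tau/tp)
             - insulin_drop * (1 - 2**(-tau/decay_halflife))

on the 5-min grid, floored at 40 mg/dL.  Beyond 4 h post-meal the drop
term decays back toward zero (recovery half-life 90 min) so multi-day
traces return to baseline instead of drifting.  Each meal draws its
archetype from a mixture; with probability ``hypo_probability`` the
insulin drop is scaled up so the trough crosses the 70 mg/dL alert
threshold (a planted postprandial hypoglycemic excursion), otherwise it is
scaled down to stay clear of it.  The evening meal may additionally carry
a delayed nocturnal dip (slow insulin tail, trough 6.5-8.5 h post-meal) which
adds sub-70 readings outside the 4-h labeled window — as in clinical
cohorts, where a sizable share of hypoglycemia is nocturnal.

Sensor noise is AR(1) (retrospective traces are smooth), samples are
deleted independently at a small rate, and readings are rounded to
1 mg/dL.  Ground-truth postprandial events are extracted from the
noiseless curve, so label noise is attributable to the sensor model.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .cgm_io import CGMSeries, GRID_MINUTES, filter_meal_announcements
from .event_metrics import HypoEvent, extract_hypo_events

GLUCOSE_FLOOR = 40.0
GLUCOSE_CAP = 400.0
POINTS_PER_DAY = 1440 // GRID_MINUTES
#: minutes after the meal at which the insulin-drop term starts recovering
RECOVERY_ONSET_MIN = 240
RECOVERY_HALFLIFE_MIN = 90.0


class Pattern(enum.Enum):
    NO_PEAK = "NO_PEAK"
    LOW_PEAK_FALL = "LOW_PEAK_FALL"
    STEEP_PEAK_FALL = "STEEP_PEAK_FALL"
    IOB_FALL = "IOB_FALL"


@dataclass(frozen=True)
class MealScenario:
    """Parameters of one postprandial archetype (all glucose in mg/dL)."""

    pattern: Pattern
    baseline: float = 135.0
    amplitude: float = 60.0
    time_to_peak: float = 35.0       # minutes
    decay_halflife: float = 75.0     # minutes
    insulin_drop: float = 90.0
    hypo_probability: float = 0.2

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0 <= self.hypo_probability <= 1:
            raise ValueError("hypo_probability must be in [0, 1]")
        if self.pattern is Pattern.IOB_FALL and self.insulin_drop <= self.amplitude:
            raise ValueError("IOB_FALL requires insulin_drop > amplitude")


def default_scenarios() -> dict[Pattern, MealScenario]:
    """Archetype defaults, calibrated once to the cohort-level statistics
    (sub-70 point fraction in [5, 15]%, negative:positive imbalance > 5)."""
    return {
        Pattern.NO_PEAK: MealScenario(
            Pattern.NO_PEAK, amplitude=6.0, time_to_peak=40.0,
            decay_halflife=95.0, insulin_drop=88.0, hypo_probability=0.05,
        ),
        Pattern.LOW_PEAK_FALL: MealScenario(
            Pattern.LOW_PEAK_FALL, amplitude=45.0, time_to_peak=40.0,
            decay_halflife=80.0, insulin_drop=96.0, hypo_probability=0.05,
        ),
        Pattern.STEEP_PEAK_FALL: MealScenario(
            Pattern.STEEP_PEAK_FALL, amplitude=120.0, time_to_peak=30.0,
            decay_halflife=45.0, insulin_drop=145.0, hypo_probability=0.15,
        ),
        Pattern.IOB_FALL: MealScenario(
            Pattern.IOB_FALL, amplitude=10.0, time_to_peak=30.0,
            decay_halflife=55.0, insulin_drop=105.0, hypo_probability=0.10,
        ),
    }


@dataclass
class CohortConfig:
    """Cohort-level knobs.  Defaults emulate the study conditions: 3-day
    series, 3 daytime meals/day, 5-min sampling, smooth AR(1) sensor noise,
    ~2% missing samples."""

    n_series: int = 100
    days: int = 3
    meals_per_day: int = 3
    scenarios: dict[Pattern, MealScenario] = field(default_factory=default_scenarios)
    mixture_weights: dict[Pattern, float] = field(
        default_factory=lambda: {
            Pattern.NO_PEAK: 0.25,
            Pattern.LOW_PEAK_FALL: 0.30,
            Pattern.STEEP_PEAK_FALL: 0.25,
            Pattern.IOB_FALL: 0.20,
        }
    )
    noise_sd: float = 5.0
    ar_coefficient: float = 0.7
    missing_rate: float = 0.02
    #: probability that an evening meal carries a delayed nocturnal dip
    nocturnal_dip_probability: float = 0.5
    #: probability of a redundant finger-stick 30-90 min before a meal
    extra_stick_probability: float = 0.10
    #: probability per day of a nocturnal (~02:00-03:00) finger-stick
    nocturnal_stick_probability: float = 0.10
    baseline_mean: float = 135.0
    baseline_sd: float = 12.0
    #: fraction of series with a second session from the same patient
    dual_session_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.mixture_weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"mixture weights sum to {total}, not 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must be in [0, 1)")


def simulate_meal_response(
    scenario: MealScenario, duration: float, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Noiseless single-meal glucose curve on the 5-min grid over [0, duration].

    Deterministic given the scenario; ``rng`` is accepted for interface
    symmetry but unused (per-meal randomization happens at series assembly).
    """
    if duration < 240:
        raise ValueError("duration must be >= 240 min")
    tau = np.arange(0.0, duration + GRID_MINUTES / 2, GRID_MINUTES)
    curve = scenario.baseline + _meal_contribution(
        tau,
        scenario.amplitude,
        scenario.time_to_peak,
        scenario.insulin_drop,
        scenario.decay_halflife,
    )
    return np.maximum(curve, GLUCOSE_FLOOR)


def _meal_contribution(
    tau: np.ndarray, amplitude: float, tp: float, drop: float, halflife: float
) -> np.ndarray:
    """Deviation from baseline caused by one meal, for tau >= 0 (minutes)."""
    rise = amplitude * (tau / tp) * np.exp(1.0 - tau / tp)
    fall = drop * (1.0 - np.power(2.0, -tau / halflife))
    recovery = np.power(
        2.0, -np.maximum(0.0, tau - RECOVERY_ONSET_MIN) / RECOVERY_HALFLIFE_MIN
    )
    return rise - fall * recovery


def _nocturnal_dip(tau: np.ndarray, depth: float, center: float, width: float) -> np.ndarray:
    return -depth * np.exp(-0.5 * ((tau - center) / width) ** 2)


def _meal_clocks(meals_per_day: int) -> list[int]:
    if meals_per_day == 3:
        return [8 * 60, 13 * 60, 19 * 60]
    # evenly spaced between 08:00 and 19:00
    return [
        int(8 * 60 + k * (11 * 60) / max(1, meals_per_day - 1))
        for k in range(meals_per_day)
    ]


def simulate_series(
    config: CohortConfig,
    rng: np.random.Generator,
    series_id: str = "S0",
    patient_id: str = "P0",
) -> tuple[CGMSeries, np.ndarray]:
    """One synthetic trace; returns the series and its noiseless curve.

    The series starts at midnight (``start_clock = 0``).  Meals fall near
    08:00/13:00/19:00 with +/-20 min jitter; overlapping meal responses are
    summed on a per-series baseline.  AR(1) noise, independent sample
    deletion and rounding to 1 mg/dL model the sensor.
    """
    n = POINTS_PER_DAY * config.days
    minutes = np.arange(n, dtype=float) * GRID_MINUTES
    baseline = float(
        np.clip(rng.normal(config.baseline_mean, config.baseline_sd), 100.0, 180.0)
    )
    noiseless = np.full(n, baseline)

    patterns = list(config.mixture_weights)
    weights = np.array([config.mixture_weights[p] for p in patterns])
    clocks = _meal_clocks(config.meals_per_day)

    meal_grid: list[int] = []
    stick_grid: list[int] = []
    for day in range(config.days):
        for mi, clock in enumerate(clocks):
            jitter = int(rng.integers(-4, 5)) * GRID_MINUTES
            minute = day * 1440 + clock + jitter
            k = minute // GRID_MINUTES
            if not 0 <= k < n - 1:
                continue
            meal_grid.append(k)
            scenario = config.scenarios[patterns[rng.choice(len(patterns), p=weights)]]
            amp = scenario.amplitude * rng.uniform(0.8, 1.2)
            tp = scenario.time_to_peak * rng.uniform(0.85, 1.15)
            planted = rng.random() < scenario.hypo_probability
            if planted:
                drop = scenario.insulin_drop * rng.uniform(1.0, 1.25)
            else:
                # cap so a non-planted trough stays clear of the 70 mg/dL
                # threshold even with modest residual from the prior meal
                drop = min(
                    scenario.insulin_drop * rng.uniform(0.25, 0.55),
                    baseline - 88.0,
                )
            tau = minutes - minute * 1.0
            after = tau >= 0
            noiseless[after] += _meal_contribution(
                tau[after], amp, tp, drop, scenario.decay_halflife
            )
            # delayed insulin tail after the evening meal -> nocturnal dip
            if mi == len(clocks) - 1 and rng.random() < config.nocturnal_dip_probability:
                depth = rng.uniform(65.0, 95.0)
                center = rng.uniform(390.0, 510.0)
                noiseless[after] += _nocturnal_dip(
                    tau[after], depth, center, rng.uniform(45.0, 75.0)
                )
            if rng.random() < config.extra_stick_probability:
                lead = int(rng.integers(6, 19))  # 30-90 min before the meal
                if k - lead > 0:
                    stick_grid.append(k - lead)
        if rng.random() < config.nocturnal_stick_probability:
            stick_grid.append((day * 1440 + int(rng.integers(120, 200)) ) // GRID_MINUTES)

    noiseless = np.clip(noiseless, GLUCOSE_FLOOR, GLUCOSE_CAP)

    noise = np.zeros(n)
    if config.noise_sd > 0:
        innov_sd = config.noise_sd * np.sqrt(1.0 - config.ar_coefficient**2)
        eps = rng.normal(0.0, innov_sd, size=n)
        noise[0] = rng.normal(0.0, config.noise_sd)
        for k in range(1, n):
            noise[k] = config.ar_coefficient * noise[k - 1] + eps[k]

    glucose = np.rint(np.clip(noiseless + noise, GLUCOSE_FLOOR, GLUCOSE_CAP))
    if config.missing_rate > 0:
        drop_mask = rng.random(n) < config.missing_rate
        glucose = glucose.copy()
        glucose[drop_mask] = np.nan

    raw = sorted(set(meal_grid) | set(g for g in stick_grid if 0 <= g < n))
    series = CGMSeries(
        series_id=series_id,
        patient_id=patient_id,
        start_clock=0,
        glucose=glucose,
        raw_meal_times=raw,
    )
    return series, noiseless


def ground_truth_events(
    series: CGMSeries, noiseless: np.ndarray
) -> list[HypoEvent]:
    """Planted postprandial events, extracted from the noiseless curve with
    the same run/merge/postprandial rules the evaluator applies."""
    meals = filter_meal_announcements(series)
    return extract_hypo_events(series, meals, glucose=noiseless)


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[CGMSeries], list[HypoEvent]]:
    """Simulate ``n_series`` traces plus the ground-truth event list.

    A small fraction of patients contribute two sessions (two series with
    one ``patient_id``), exercising the cross-subject grouping.  Fully
    reproducible from ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_series + 1)
    meta_rng = np.random.default_rng(children[-1])

    n_dual = int(round(config.dual_session_fraction * config.n_series))
    # patients owning two series: pair series (i, i+1) for the first 2*n_dual
    patient_ids: list[str] = []
    pi = 0
    i = 0
    while i < config.n_series:
        if pi < n_dual and i + 1 < config.n_series:
            patient_ids += [f"P{pi:03d}", f"P{pi:03d}"]
            i += 2
        else:
            patient_ids.append(f"P{pi:03d}")
            i += 1
        pi += 1
    meta_rng.shuffle(patient_ids)  # decouple patient order from series order

    series_list: list[CGMSeries] = []
    truth: list[HypoEvent] = []
    for idx in range(config.n_series):
        rng = np.random.default_rng(children[idx])
        series, noiseless = simulate_series(
            config, rng, series_id=f"S{idx:03d}", patient_id=patient_ids[idx]
        )
        series_list.append(series)
        truth.extend(ground_truth_events(series, noiseless))
    return series_list, truth
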