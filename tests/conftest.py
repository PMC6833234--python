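import numpy as np
import pytest

from pphypo.cgm_io import CGMSeries, MealAnnouncement


def make_series(
    glucose,
    series_id="S0",
    patient_id="P0",
    start_clock=0,
    raw_meal_times=(),
):
    return CGMSeries(
        series_id=series_id,
        patient_id=patient_id,
        start_clock=start_clock,
        glucose=np.asarray(glucose, dtype=float),
        raw_meal_times=list(raw_meal_times),
    )


def meal(grid_index, meal_index=1, series_id="S0"):
    return MealAnnouncement(
        series_id=series_id, meal_index=meal_index, grid_index=grid_index
    )


@pytest.fixture
def flat_series():
    """3-day flat trace at 120 mg/dL with meals at 08:00/13:00/19:00 daily."""
    n = 288 * 3
    meals = [
        d * 288 + c // 5 for d in range(3) for c in (8 * 60, 13 * 60, 19 * 60)
    ]
    return make_series(np.full(n, 120.0), raw_meal_times=meals)


@pytest.fixture(scope="session")
def small_cohort():
    from pphypo.synthetic import CohortConfig, simulate_cohort

    return simulate_cohort(CohortConfig(n_series=12, seed=11))
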