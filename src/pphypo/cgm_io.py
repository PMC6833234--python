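"""CGM trace data model and preprocessing.

A continuous glucose monitoring (CGM) trace is a glucose time series on a
strict 5-minute grid, in mg/dL, with occasional missing samples (sensor
calibration failures) and a list of meal announcements (in the source data,
the pre-meal finger-stick calibration timestamps).

Preprocessing follows the study protocol for retrospective CGM review:

* short sensor gaps (1-2 consecutive missing points) are filled with a
  natural cubic spline fitted on all present points of the series; gaps of
  3 or more points are left missing,
* announcements falling in the nocturnal interval [23:00, 07:00) are
  discarded,
* of any chain of announcements pairwise closer than 2 h, only the last is
  kept (repeat finger-sticks before one meal collapse to the final stick).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

GRID_MINUTES = 5
#: glucose thresholds in mg/dL (3.9 / 3.0 / 4.4 mmol/L)
HYPO_ALERT_MGDL = 70.0
SEVERE_HYPO_MGDL = 54.0
NEAR_HYPO_MGDL = 80.0
MGDL_PER_MMOL = 18.016

GLUCOSE_MIN_MGDL = 20.0
GLUCOSE_MAX_MGDL = 600.0

NOCTURNAL_START_MIN = 23 * 60   # 23:00
NOCTURNAL_END_MIN = 7 * 60      # 07:00 (exclusive)
MEAL_MERGE_MINUTES = 120

#: default postprandial window length in grid steps (42 steps = 3.5 h);
#: the window sequence is indexed t = 0..W with t = 0 the meal-time point.
WINDOW_STEPS = 42


class CGMFormatError(ValueError):
    """Input rows violate the 5-min grid or the CSV contract."""


class CGMValidationError(ValueError):
    """Glucose values outside the physiologically plausible range."""


class PreprocessingError(ValueError):
    """A preprocessing step cannot be applied (e.g. spline underdetermined)."""


@dataclass
class CGMSeries:
    """One subject-session glucose trace on a 5-minute grid.

    ``glucose[k]`` is the reading at minute ``5*k`` from the series start;
    missing readings are NaN.  ``start_clock`` is the clock time of the first
    sample in minutes-of-day (0-1439), used to recover clock times for the
    nocturnal filter.  Several series may share one ``patient_id``.
    """

    series_id: str
    patient_id: str
    start_clock: int
    glucose: np.ndarray
    raw_meal_times: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.glucose = np.asarray(self.glucose, dtype=float)
        present = self.glucose[~np.isnan(self.glucose)]
        if present.size and (
            present.min() < GLUCOSE_MIN_MGDL or present.max() > GLUCOSE_MAX_MGDL
        ):
            raise CGMValidationError(
                f"series {self.series_id!r}: glucose outside "
                f"[{GLUCOSE_MIN_MGDL:g}, {GLUCOSE_MAX_MGDL:g}] mg/dL"
            )
        if list(self.raw_meal_times) != sorted(set(self.raw_meal_times)):
            raise CGMValidationError(
                f"series {self.series_id!r}: raw_meal_times must be strictly increasing"
            )
        if self.raw_meal_times and self.raw_meal_times[-1] >= len(self.glucose):
            raise CGMValidationError(
                f"series {self.series_id!r}: meal time beyond series end"
            )

    def __len__(self) -> int:
        return len(self.glucose)

    def clock_minute(self, grid_index: int) -> int:
        """Clock time (minutes-of-day) of the sample at ``grid_index``."""
        return (self.start_clock + GRID_MINUTES * grid_index) % 1440


@dataclass(frozen=True)
class MealAnnouncement:
    """A surviving meal announcement: ``meal_index`` is 1-based within series."""

    series_id: str
    meal_index: int
    grid_index: int


def read_cgm_csv(path: str | Path, units: str = "mgdl") -> list[CGMSeries]:
    """Read CGM traces from the package CSV dialect.

    Columns: ``series_id, patient_id, minute, glucose, is_meal`` (header
    required).  ``minute`` is the offset from series start in multiples of 5;
    an empty ``glucose`` cell marks a missing sample.  An optional
    ``start_clock`` column gives the clock minute-of-day of the first sample
    (default 0).  ``units="mmol"`` converts glucose to mg/dL on read.
    """
    df = pd.read_csv(path, dtype={"series_id": str, "patient_id": str})
    required = {"series_id", "patient_id", "minute", "glucose", "is_meal"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise CGMFormatError(f"missing columns: {sorted(missing_cols)}")

    out: list[CGMSeries] = []
    for sid, grp in df.groupby("series_id", sort=False):
        minutes = grp["minute"].to_numpy(dtype=int)
        if np.any(minutes % GRID_MINUTES != 0) or np.any(
            np.diff(minutes) != GRID_MINUTES
        ):
            bad = int(np.flatnonzero(np.diff(minutes) != GRID_MINUTES)[0]) + 1 \
                if len(minutes) > 1 else 0
            raise CGMFormatError(
                f"series {sid!r}: rows not on a contiguous 5-min grid "
                f"(first violation near row {bad})"
            )
        glucose = grp["glucose"].to_numpy(dtype=float)
        if units == "mmol":
            glucose = glucose * MGDL_PER_MMOL
        elif units != "mgdl":
            raise ValueError(f"unknown units {units!r}")
        meal_idx = np.flatnonzero(grp["is_meal"].to_numpy(dtype=int) != 0)
        start_clock = int(grp["start_clock"].iloc[0]) if "start_clock" in grp else 0
        out.append(
            CGMSeries(
                series_id=str(sid),
                patient_id=str(grp["patient_id"].iloc[0]),
                start_clock=start_clock,
                glucose=glucose,
                raw_meal_times=[int(k) for k in meal_idx],
            )
        )
    return out


def write_cgm_csv(series_list: Sequence[CGMSeries], path: str | Path) -> None:
    """Write traces in the dialect accepted by :func:`read_cgm_csv`."""
    rows = []
    for s in series_list:
        meals = set(s.raw_meal_times)
        for k, g in enumerate(s.glucose):
            rows.append(
                {
                    "series_id": s.series_id,
                    "patient_id": s.patient_id,
                    "minute": GRID_MINUTES * k,
                    "glucose": "" if np.isnan(g) else g,
                    "is_meal": int(k in meals),
                    "start_clock": s.start_clock,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in ``mask`` as (start, stop) half-open pairs."""
    runs = []
    k = 0
    n = len(mask)
    while k < n:
        if mask[k]:
            j = k
            while j < n and mask[j]:
                j += 1
            runs.append((k, j))
            k = j
        else:
            k += 1
    return runs


def interpolate_gaps(series: CGMSeries) -> CGMSeries:
    """Fill 1-2 point sensor gaps with a natural cubic spline.

    The spline is fitted once on all present points of the series; only
    maximal missing runs of length 1 or 2 are filled ("less than 3
    consecutive missing").  Longer gaps and all present values are untouched,
    which makes the operation idempotent.
    """
    g = series.glucose
    nan_mask = np.isnan(g)
    if not nan_mask.any():
        return replace(series, glucose=g.copy())
    present = np.flatnonzero(~nan_mask)
    if present.size < 4:
        raise PreprocessingError(
            f"series {series.series_id!r}: fewer than 4 present points; "
            "spline interpolation underdetermined"
        )
    spline = CubicSpline(present.astype(float), g[present], bc_type="natural")
    filled = g.copy()
    for start, stop in _missing_runs(nan_mask):
        if stop - start <= 2:
            idx = np.arange(start, stop, dtype=float)
            filled[start:stop] = spline(idx)
    return replace(series, glucose=filled)


def _is_nocturnal(clock_minute: int) -> bool:
    # half-open [23:00, 07:00): an announcement at exactly 07:00 survives
    return clock_minute >= NOCTURNAL_START_MIN or clock_minute < NOCTURNAL_END_MIN


def filter_meal_announcements(
    series: CGMSeries,
    merge_minutes: int = MEAL_MERGE_MINUTES,
) -> list[MealAnnouncement]:
    """Apply the nocturnal and <2 h merge rules to raw announcements.

    Announcements whose clock time lies in [23:00, 07:00) are removed.  Then
    an announcement survives iff the nearest *later surviving* announcement
    is at least ``merge_minutes`` away (strictly less than 2 h triggers the
    drop): repeat finger-sticks before one meal collapse to the final stick,
    and of any chain of announcements pairwise closer than 2 h only the last
    survives.  Dropping an announcement that would be dropped anyway never
    changes the result.  Survivors are re-indexed 1..M.
    """
    daytime = [
        k for k in series.raw_meal_times if not _is_nocturnal(series.clock_minute(k))
    ]
    kept: list[int] = []
    for k in reversed(daytime):
        if not kept or GRID_MINUTES * (kept[-1] - k) >= merge_minutes:
            kept.append(k)
    kept.reverse()
    return [
        MealAnnouncement(series_id=series.series_id, meal_index=j, grid_index=k)
        for j, k in enumerate(kept, start=1)
    ]


def postprandial_window(
    series: CGMSeries, meal: MealAnnouncement, window_steps: int = WINDOW_STEPS
) -> np.ndarray:
    """Glucose sequence indexed t = 0..window_steps after a meal.

    Element ``t`` is the reading at ``meal.grid_index + t`` (t = 0 is the
    meal-time point).  Truncated at the series end; windows of different
    meals may overlap in underlying series time.  NaN propagates.
    """
    start = meal.grid_index
    if start >= len(series) - 1:
        raise PreprocessingError(
            f"series {series.series_id!r}: meal at the last index yields an "
            "empty postprandial window"
        )
    stop = min(start + window_steps + 1, len(series))
    return series.glucose[start:stop].copy()
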