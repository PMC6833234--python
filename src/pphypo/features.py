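"""Postprandial feature extraction: CGM, RIG, GRC and the hypoglycemia label.

For each meal and each prediction step t = 1..42 (5*t minutes post-meal)
three features are computed from the postprandial window:

* **CGM** — the glucose reading at the prediction time, mg/dL;
* **RIG** (rate of increase in glucose) — (running-peak glucose over steps
  0..t minus the meal-time glucose) divided by the minutes from meal to
  peak; 0 when there has been no rise above the meal-time value.  Because
  the running maximum freezes once the true post-meal peak has passed, RIG
  stops changing after the peak;
* **GRC** (glucose rate of change) — the 5-min first difference at t
  divided by 5, mg/dL per minute.

The label is 1 iff the reading a 30-min horizon ahead (step t+6) is below
the 70 mg/dL hypoglycemia alert threshold.  Samples whose required window
points are missing are skipped (and counted), never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cgm_io import (
    CGMSeries,
    GRID_MINUTES,
    HYPO_ALERT_MGDL,
    MealAnnouncement,
    WINDOW_STEPS,
    postprandial_window,
)

#: prediction horizon in grid steps (6 steps = 30 min)
HORIZON_STEPS = 6

FEATURE_COLUMNS = {"all": ["cgm", "rig", "grc"], "cgm_grc": ["cgm", "grc"]}

SAMPLE_COLUMNS = ["series_id", "meal_index", "t", "cgm", "rig", "grc", "label"]


class SampleSkip(Exception):
    """Raised when a required window point is missing; the sample is skipped."""


@dataclass(frozen=True)
class PeakState:
    """Running post-meal maximum at prediction step t."""

    peak_index: int
    peak_value: float
    td_meal_to_peak: float  # minutes


def compute_rig(window: Sequence[float], t: int) -> tuple[float, PeakState]:
    """Rate of increase in glucose over window steps 0..t, mg/dL per minute.

    The peak is the smallest argmax of ``window[0..t]``; if it is the
    meal-time point itself there has been no rise and RIG is 0 (which also
    sidesteps the zero time-difference).
    """
    w = np.asarray(window, dtype=float)
    seg = w[: t + 1]
    if np.isnan(seg).any():
        raise SampleSkip(f"missing point in window[0..{t}]")
    peak_index = int(np.argmax(seg))  # first index at ties
    peak_value = float(seg[peak_index])
    td = float(GRID_MINUTES * peak_index)
    rig = 0.0 if peak_index == 0 else (peak_value - float(w[0])) / td
    return rig, PeakState(peak_index=peak_index, peak_value=peak_value, td_meal_to_peak=td)


def compute_grc(window: Sequence[float], t: int) -> float:
    """Glucose rate of change at step t: 5-min first difference / 5."""
    if t < 1:
        raise ValueError("GRC needs t >= 1")
    w = np.asarray(window, dtype=float)
    if np.isnan(w[t]) or np.isnan(w[t - 1]):
        raise SampleSkip(f"missing operand for GRC at t={t}")
    return (float(w[t]) - float(w[t - 1])) / GRID_MINUTES


def compute_label(
    window: Sequence[float], t: int, horizon: int = HORIZON_STEPS
) -> int:
    """1 iff the reading at step t+horizon is strictly below 70 mg/dL."""
    w = np.asarray(window, dtype=float)
    k = t + horizon
    if k >= len(w) or np.isnan(w[k]):
        raise SampleSkip(f"missing label point at t+{horizon}={k}")
    return int(w[k] < HYPO_ALERT_MGDL)


def build_dataset(
    series_list: Iterable[CGMSeries],
    meals: Mapping[str, Sequence[MealAnnouncement]],
    feature_subset: str = "all",
    window_steps: int = WINDOW_STEPS,
    horizon: int = HORIZON_STEPS,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Emit one (CGM, RIG, GRC, label) sample per meal and step t = 1..42.

    A sample at step t is emitted iff every point it needs is present:
    window steps 0..t (RIG; this subsumes GRC's t-1..t) and step t+horizon
    (label).  Returns the sample table in deterministic (series, meal, t)
    order together with a skip log.  ``feature_subset`` ("all" or
    "cgm_grc") is recorded in ``df.attrs`` and applied downstream at model
    -matrix time so labels and events are identical across ablations.
    """
    if feature_subset not in FEATURE_COLUMNS:
        raise ValueError(f"unknown feature_subset {feature_subset!r}")
    rows: list[tuple] = []
    skips = {"missing_feature_point": 0, "missing_label_point": 0}
    for series in series_list:
        for meal in meals.get(series.series_id, ()):
            # the window must reach horizon steps past the last prediction
            # step so t = window_steps still has a label point
            window = postprandial_window(series, meal, window_steps + horizon)
            for t in range(1, window_steps + 1):
                if t + horizon >= len(window) or np.isnan(window[t + horizon]):
                    skips["missing_label_point"] += 1
                    continue
                if np.isnan(window[: t + 1]).any():
                    skips["missing_feature_point"] += 1
                    continue
                rig, _ = compute_rig(window, t)
                grc = compute_grc(window, t)
                label = compute_label(window, t, horizon)
                rows.append(
                    (series.series_id, meal.meal_index, t, float(window[t]), rig, grc, label)
                )
    df = pd.DataFrame(rows, columns=SAMPLE_COLUMNS)
    df.attrs["feature_subset"] = feature_subset
    return df, skips


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature min/max learned on training folds only."""

    minima: dict[str, float]
    maxima: dict[str, float]

    @property
    def features(self) -> list[str]:
        return list(self.minima)


def fit_scaler(train: pd.DataFrame, features: Sequence[str]) -> ScalerParams:
    """Learn MinMax extrema per feature on the training samples."""
    if len(train) == 0:
        raise ValueError("cannot fit a scaler on an empty training set")
    return ScalerParams(
        minima={f: float(train[f].min()) for f in features},
        maxima={f: float(train[f].max()) for f in features},
    )


def apply_scaler(params: ScalerParams, samples: pd.DataFrame) -> np.ndarray:
    """Map samples to the unit scale of the training extrema.

    Values outside the training range map outside [0, 1] (no clipping);
    a degenerate feature (max == min on train) maps to 0 everywhere.
    """
    cols = []
    for f in params.features:
        lo, hi = params.minima[f], params.maxima[f]
        x = samples[f].to_numpy(dtype=float)
        cols.append(np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo))
    return np.column_stack(cols)
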