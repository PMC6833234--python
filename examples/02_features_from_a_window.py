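"""Extract the three predictive features from one postprandial window.

A meal announcement opens a 3.5-h observation window on the 5-min grid.
At each prediction step t the model sees: the current glucose (CGM), the
rate of increase from the meal to the running peak (RIG, mg/dL per min),
and the local 5-min rate of change (GRC).  The label marks whether the
reading 30 min ahead falls below 70 mg/dL.  Note how RIG freezes once the
post-meal peak has passed while GRC keeps tracking the local slope.
"""

import numpy as np

from pphypo import (
    CohortConfig, build_dataset, compute_rig,
    filter_meal_announcements, interpolate_gaps, simulate_series,
)

cfg = CohortConfig(n_series=1, seed=3)
series, _ = simulate_series(cfg, np.random.default_rng(3))
series = interpolate_gaps(series)
meals = filter_meal_announcements(series)

df, skips = build_dataset([series], {series.series_id: meals})
print(f"{len(meals)} meals -> {len(df)} samples "
      f"({int(df.label.sum())} positive), skipped: {skips}")

one_meal = df[df.meal_index == df.loc[df.label.eq(1).idxmax(), "meal_index"]] \
    if df.label.any() else df[df.meal_index == 1]
print("\n  t  min_post_meal   cgm     rig     grc  label")
for _, r in one_meal.iloc[::6].iterrows():
    print(f" {int(r.t):3d}   {5 * int(r.t):5d}       {r.cgm:6.1f} {r.rig:7.3f} "
          f"{r.grc:7.2f}   {int(r.label)}")

window = series.glucose[meals[0].grid_index: meals[0].grid_index + 43]
rig, peak = compute_rig(window, 42)
print(f"\nmeal #1: peak {peak.peak_value:.0f} mg/dL at {peak.td_meal_to_peak:.0f} min "
      f"post-meal -> RIG fixed at {rig:.3f} mg/dL/min from then on")
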