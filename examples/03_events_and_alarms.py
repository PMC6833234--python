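"""The event/alarm calculus on a hand-built trace.

A hypoglycemic *event* is a merged run of >= 2 consecutive readings below
70 mg/dL starting 5 min-4 h post-meal.  An *alarm* is >= 2 consecutive
positive predictions; it truly detects an event when it fires within the
60 min before the event starts.  The detection time (DT) is that lead
time; unmatched alarms are false, and FAR = FP_e / (TP_e + FP_e).
"""

import numpy as np

from pphypo import (
    CGMSeries, MealAnnouncement, detect_alarms, extract_hypo_events,
    match_alarms_events,
)

# trace: normal for 2 h post-meal, then a 40-min hypo excursion at minute 130
glucose = np.full(60, 110.0)
glucose[26:34] = [68, 65, 60, 58, 57, 62, 66, 69]
series = CGMSeries("demo", "P1", start_clock=480, glucose=glucose,
                   raw_meal_times=[0])
meal = MealAnnouncement("demo", meal_index=1, grid_index=0)

events = extract_hypo_events(series, [meal])
print(f"events: {[(e.start_minute, e.end_minute, e.severe) for e in events]}")

# predictions: positive run at steps 20-23 (minutes 100-115), one stray positive
predictions = {t: 0 for t in range(1, 43)}
for t in (20, 21, 22, 23):
    predictions[t] = 1
predictions[40] = 1  # isolated -> no alarm

alarms = detect_alarms(predictions, "demo", meal, events=events)
print(f"alarms at minutes: {[a.alarm_minute for a in alarms]}")

m = match_alarms_events(alarms, events)
print(f"NH={m.nh}  TP_e={m.tp_e}  FP_e={m.fp_e}  FAR={m.far:.2f}  DT={m.dt:.0f} min")
print("-> the alarm at minute 100 precedes the event at minute 130 by 30 min")
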