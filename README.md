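# wristpa

Raw wrist-accelerometry analysis of physical activity after percutaneous
coronary intervention (PCI): from tri-axial acceleration at 50 Hz (±8 g)
to daily activity metrics and adherence to four physical-activity
criteria —

* **2010 WHO guideline**: ≥ 30 min/day of moderate-to-vigorous physical
  activity (MVPA) accumulated in bouts of ≥ 10 min (80% of 5-s epochs
  above threshold),
* **2020 WHO guideline**: ≥ 30 min/day of MVPA, any bout length,
* **≥ 7,500** and **≥ 10,000 steps/day**.

The distinction matters clinically: patients who accumulate MVPA in many
short bursts satisfy the 2020 criterion but not the 2010 one, producing a
severalfold gap in adherence prevalence from identical behaviour.  This
package makes every stage of that measurement chain explicit, testable,
and reproducible.

## What it computes

For each participant (metadata: age, sex, ACS/CCS presentation, PCI date
= day 0) and each midnight-to-midnight day:

| stage | module | method |
|---|---|---|
| raw I/O, day slicing | `signal_io` | CSV dialect `time,x,y,z` (g), uniform grid |
| autocalibration | `autocalibration` | sphere fit on still windows, `a' = (a−offset)/gain` |
| epoch features | `epoching` | 5-s ENMO = max(0, ‖a‖−1)·1000 mg; z-angle; non-wear (60-min windows, 15-min slide); nightly sleep period |
| intensity & bouts | `activity_metrics` | <25 / 25–99 / ≥100 mg bands; ≥10-min 80% bouts; M2/M30/M60; 24-h mean acceleration |
| steps & cadence | `step_cadence` | windowed peak detection on the 15 Hz magnitude; minute cadence; peak-1/30/60 cadence; minutes ≥100 and =0 steps/min |
| adherence & cohort | `adherence_report` | valid days (≥12 h wear, day ≥2), ≥7-day inclusion, participant means, four flags, medians (Q1, Q3), subgroup χ²/Fisher, OLS of MVPA on steps/cadence |
| synthetic truth | `synthetic_wear` | schedule-driven signal generator with exact per-day ground truth |

## Worked example

Generate one "sporadic accumulator" participant (ten 4-min brisk walks a
day, sub-MVPA strolls for extra steps), run the pipeline, and classify:

```python
import pandas as pd
from wristpa.synthetic_wear import CohortSpec, cohort_plans, generate_participant
from wristpa.pipeline import process_recording, day_summaries_frame
from wristpa import adherence_report as ar

spec = CohortSpec()
plan = cohort_plans(spec)[4]          # an accumulator, 6,200 steps/day tier
rec, truth = generate_participant(plan, spec, participant_seed=12345)
es, days, model = process_recording(rec, plan.meta)
df = day_summaries_frame(days)
print(df[["day_index", "wear_hours", "mvpa_min", "mvpa_bout10_min", "steps"]].head(3))

valid = ar.select_valid_days(df)
ps = ar.summarize_participant(valid, plan.meta)
print(ps.flags)
```

prints

```
   day_index  wear_hours  mvpa_min  mvpa_bout10_min  steps
0          2        16.0      40.0              0.0   6200
1          3        16.0      40.0              0.0   6200
2          4        16.0      40.0              0.0   6200
{'who2020': True, 'who2010': False, 'steps7500': False, 'steps10000': False}
```

Forty minutes of daily MVPA — but zero of it in ≥10-min bouts, so this
participant meets the 2020 guideline and fails the 2010 one: the
bout-definition gap in a single row.

A command-line interface wraps the same functions:

```bash
wristpa simulate --out cohort/ --seed 1        # synthetic cohort + truth tables
wristpa process  --raw p01.csv --out out/      # one recording -> epochs + days
wristpa report   --days days.csv --meta meta.csv --out report/
```

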