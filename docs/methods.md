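# Methods

`wristpa` re-implements, as a tested library, the raw-accelerometry
processing chain used to assess physical-activity (PA) guideline adherence
in cardiac patients wearing a wrist device (±8 g, 50 Hz): per-sample ENMO,
5-s epochs, autocalibration, non-wear and sleep detection, MVPA bout
detection, windowed-peak step counting, cadence and "most active X minutes"
(MX) metrics, and classification against four criteria — the 2010 WHO
guideline (≥30 min/day MVPA in ≥10-min bouts), the 2020 WHO guideline
(≥30 min/day MVPA, any bout length), and ≥7,500 / ≥10,000 steps/day.

Because the study cohort's raw recordings are not publicly deposited, the
package is verified against its own synthetic-signal generator, whose
ground truth is exact by construction.  This note records the model, the
constants, and the design decisions.

## Signal model and epoch features

Raw input is timezone-naive local time, tri-axial acceleration in g on a
strict uniform grid (CSV dialect `time,x,y,z`).  Gaps ≤ 1 s are filled by
holding the last sample; longer gaps are an error (the source device's gap
behaviour is undocumented, so this policy is ours).  Days run midnight to
midnight; the day index is counted from the date of the coronary
intervention (day 0).

ENMO (Euclidean norm minus one, negatives truncated) is computed per
sample and averaged over 5-s epochs aligned to midnight; partial edge
epochs are dropped so a full day is always exactly 17,280 epochs.  The
z-angle is `atan(z̄/√(x̄²+ȳ²))` of the epoch-mean axes (computing it from
epoch means rather than a median-of-medians cascade changes nothing
observable at 5-s resolution).  Intensity bands: inactive < 25 mg ≤ light
< 100 mg ≤ MVPA, with a vigorous sub-flag at ≥ 400 mg (the 400 mg value is
toolchain convention; the source study prints VPA minutes without its
threshold).

## Autocalibration

Still windows (non-overlapping 10 s, all three per-axis SDs < 13 mg)
provide points that should lie on the unit gravity sphere.  A per-axis
linear map `a' = (a − offset)/gain` is fitted by iterating ordinary
least-squares regressions of each point's unit-sphere projection on the
point, until the mean absolute norm error changes by < 0.001 mg (cap
1,000 iterations).  If the still points span < 0.3 g of range on any axis
the geometry is declared ill-posed and the identity model is returned
un-converged.  Note the range guard is necessary, not sufficient: points
whose per-axis magnitudes are all equal (e.g. only cube-corner
orientations) leave the gains unidentifiable even though the ranges look
fine; recovery is therefore verified on a mixed orientation set.
Calibration is estimated once per participant over the whole recording.

## Non-wear and sleep

Non-wear is voted over 60-min windows advanced in 15-min steps: a window
votes non-wear when ≥ 2 of 3 axes are still (per-axis SD < 13 mg *or*
range < 50 mg); an epoch is non-wear if any covering window votes so.  The
window geometry is from the source study; the axis-vote constants follow
the non-wear literature it cites.

Sleep uses a sustained-inactivity heuristic on the z-angle: per 5-min
block, the mean absolute successive epoch difference; blocks below an
adaptive threshold (15 × the 10th percentile of the noon-to-noon window's
block values, floored at 0.1° and capped at 15°) are sustained
inactivity; runs separated by < 60 min merge, and the longest merged run
≥ 30 min between noon and next noon is the night's sleep period.  A
perfectly constant (shelved-device) signal is *also* detected as sleep —
the heuristic is angle-only by design.  Sleep feeds only the day summary;
it never enters adherence classification.

## Bout detection

The 2010-guideline criterion needs MVPA bouts: intervals of ≥ 120 epochs
(10 min) with ≥ 80% of epochs at ≥ 100 mg.  The criterion alone does not
pin down an algorithm, so the package fixes one reference semantics:

* a qualifying interval has length ≥ 120, above-threshold fraction ≥ 0.8
  (compared in exact integer arithmetic — float 0.8 would misclassify
  exact-boundary intervals), above-threshold first and last epochs, and no
  internal below-threshold run longer than 12 epochs (1 min);
* bouts are chosen left to right: the leftmost qualifying start is
  extended to its *maximal* qualifying end, committed, and the scan
  resumes after it, so bouts never overlap.

Non-overlap plus the per-interval fraction bound make
`bouted ≤ mvpa/0.8` provable (a plain union of qualifying intervals would
violate it: two overlapping 80% intervals can union to < 80%).  The
production detector decomposes the day at below-runs > 12 epochs and uses
a suffix-maximum plus binary search per segment (O(n log n)); the test
suite re-derives the same semantics by brute-force enumeration of every
candidate end and requires exact interval agreement on 1,000 random
sequences.  Non-wear epochs count as below threshold for bouts and as
0 mg for the MX metrics (conservative: no phantom activity).

Time-in-intensity accrual is epoch-level by default (minutes =
epochs/12), matching the cited toolchain's behaviour; a `minute80`
alternative (a minute counts as MVPA iff ≥ 80% of its 12 epochs qualify)
is config-selectable.  This is the single most consequential ambiguity in
the source description ("accrued in 1-min bouts") and both readings are
implemented; nothing in the test suite depends on which is chosen except
the accrual tests themselves.

## Step counting and cadence

The magnitude signal is resampled to 15 Hz (linear interpolation; the
cited implementation convention — halves compute and stabilises peak
windows at gait frequencies).  Candidate peaks are maxima of a centred
3-sample window with magnitude ≥ 1.2 g; then inter-peak period must fall
in [5, 15] samples (0.33–1.0 s, i.e. 60–180 steps/min), peak-to-peak
amplitude must agree within 0.5 g, and only *trains* of ≥ 4 peaks with
in-range spacing and local variance ≥ 0.001 g² survive.  One surviving
peak = one step.  A peak arriving after a longer-than-period pause
re-seeds a new candidate train rather than being dropped — a literal
"drop out-of-range intervals" rule would never recover after any pause.
The eight parameters are config-exposed defaults in the lineage of the
open-source windowed-peak detector; the study's own tuned values are
unpublished, so results are parameter-dependent by nature.

Steps land in 5-s epochs (half-open intervals; boundary steps go to the
later epoch); minute cadence is the 12-epoch sum.  The daily summary uses
fixed 1,440-minute denominators for mean cadence and %-zero-cadence, and
peak-1/30/60 cadence is the mean of the highest (not necessarily
consecutive) minutes.

## Valid days, participants, adherence, cohort outputs

A valid day has ≥ 12 h wear and day index ≥ 2; participants need ≥ 7
valid days.  Participant metrics are arithmetic means over valid days;
all four adherence boundaries are inclusive (the criteria are written
"≥").  The 24-h mean acceleration imputes non-wear epochs from the
participant's mean worn ENMO at the same clock epoch over the *other*
valid days (0 without a donor).  Cohort outputs are CSV tables: medians
with linear-interpolation quartiles, subgroup prevalences (sex, median
age split of the included cohort, clinical presentation) tested with
Pearson chi-square (Fisher's exact when any expected cell < 5 — the
source flags significance without naming a test), per-day fulfilment
curves (conditioned on the day being valid — an assumption, not stated in
the source), the MVPA-on-steps and MVPA-on-cadence OLS table with the
predictor value at the 30-min crossing, and criterion set counts.

## The synthetic generator

The generator is the package's oracle; its defaults define the study
conditions for verification.

**Walking** modulates the magnitude of gravity along a slowly wandering
unit orientation: `|a|(t) = 1 + A·w(θ)` with
`w(θ) = sin θ + 0.3 sin 2θ`, one gait cycle per counted step, and
`A = 1.15 × peak_amp_g`.  Because the positive part of `w` integrates to
exactly 1/π per cycle, the noiseless epoch ENMO is `A/π` in closed form —
truth for "MVPA seconds" comes from this expression, never from
re-running the pipeline.  `peak_amp_g = 0.3` gives ≈ 110 mg (so brisk
walking is MVPA by construction with ~10% margin); 0.24 at 80 steps/min
gives ≈ 88 mg, a "stroll" that contributes steps but not MVPA.  The
orientation is tilted (all components ≥ 0.4) so gait excites all three
axes, and wanders by tens of degrees at ~0.3 Hz so walking is
unmistakably awake to the angle-based sleep heuristic.

**Sleep** is nonstationary noise around a posture that shifts every
~28 min: quiet spells (4 mg SD, the calibration's still points) alternate
with restless spells (35 mg SD) so the hourly per-axis SD stays above the
13 mg non-wear vote while epoch ENMO stays in the inactive band.
**Sedentary** is 25 mg white noise with small angular wander;
**light** is a bounded slow arm-swing (magnitude `1 + A sin`, A ∈
[0.10, 0.19] redrawn every 30 s, 0.35–0.55 Hz) whose epoch ENMO `A/π`
is deterministically inside the light band and whose sub-gait frequency
can never chain into a step train; **non-wear** is a constant gravity
vector with < 1 mg quantisation-scale noise.  Device miscalibration
(per-axis gain/offset) is applied *after* truth is recorded.

What the generator does **not** emulate: free-living behavioural
variety, non-walking MVPA (cycling, swimming), device temperature drift,
daylight-saving transitions, irregular gait.  Passing tests therefore
demonstrate the correctness of the processing chain under its stated
semantics, not field accuracy of, say, the step detector on real wrists.

**The designed verification cohort** (defaults of `CohortSpec`): 20
participants over 8 recorded days (days 2–9 after the intervention), worn
06:00–22:00 (16 h) with constant-orientation non-wear overnight.  20% are
"bout exercisers" (one 40-min walk/day at 110 steps/min, amplitude
0.5 g); 80% are "sporadic accumulators" (ten 4-min walks at the same
intensity) — the mechanism behind the 2010-vs-2020 divergence.  Daily
steps are tiered by sub-MVPA strolls to 6,200 / 8,700 / 11,500 in counts
6/5/9 (interleaved over both archetypes), so the designed prevalences are
2020 = 100%, 7,500 = 70%, 10,000 = 45%, 2010 = 20%, with every
participant ≥ 15% away from the step thresholds — comfortably outside the
detector's ±5% tolerance.  "Noiseless" means deterministic seeding, zero
gait jitter, and identity device calibration; the rest/sleep textures keep
their stochastic character because that is what defines those classes.

## Numerical and performance choices

* Bout fractions and MX ranks use integer/exact arithmetic; ENMO and all
  window statistics accumulate in float64 even when the raw signal is
  stored float32 (large synthetic cohorts use float32 storage, ~0.01 mg
  epoch error, three orders of magnitude below any threshold).
* The verification cohort is 20 participants × 8 days at the full 50 Hz
  (≈ 35M samples each); one participant takes roughly 15 s to generate
  and process, the full cohort a few minutes on one core.
* Degenerate inputs: empty still-point sets raise; unconverged or
  out-of-bound calibrations fall back to the identity model; days without
  12 h wear have undefined (NaN) 24-h mean acceleration; excluded
  participants have no adherence flags.

## Known limitations

* The bout algorithm is one concrete reading of the 80% criterion; other
  toolchains differ at interval boundaries.  The brute-force oracle, not
  any external software, defines this package's semantics.
* The sleep heuristic is a simplified member of the z-angle family: no
  nap detection, and constant signals (shelved devices) read as sleep.
* Step-detector parameters are lineage defaults, not the study's
  unpublished tuned values; absolute step counts on real data are
  parameter-dependent.
* Timezones and DST are out of scope; timestamps are naive local time.
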