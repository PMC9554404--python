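"""Synthetic raw wrist recordings with exact ground truth.

Multi-day recordings are tiled from declarative activity blocks (sleep,
sedentary, light, walk, non-wear).  Walking is a two-harmonic periodic
modulation of the gravity magnitude — one gait cycle per counted step —
whose noiseless epoch ENMO has the closed form A/π (A = amplitude scale ×
peak amplitude), so the MVPA band membership of every block is known by
construction and never derived by re-running the pipeline.  Ground truth
(steps, MVPA seconds, bouted MVPA, wear, sleep) is recorded per calendar
day *before* any simulated device miscalibration is applied.

Cohorts mix two behavioural archetypes: "bout exercisers" (one long daily
walk) and "sporadic accumulators" (many short walks), the mechanism behind
the divergence between bout-based (2010) and bout-free (2020) MVPA
guidelines.  Low-cadence strolls below the MVPA band tier the daily step
counts so the four adherence criteria separate by design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    GAIT_AMP_SCALE,
    GAIT_HARMONIC,
    MG_PER_G,
    expected_walk_enmo_mg,
)
from .signal_io import ParticipantMeta, RawRecording

__all__ = [
    "ActivityBlock",
    "BlockTruth",
    "CohortSpec",
    "simulate_block",
    "generate_recording",
    "apply_device_distortion",
    "daily_schedule",
    "cohort_plans",
    "designed_prevalence",
    "generate_participant",
    "generate_cohort",
]

BLOCK_KINDS = ("sleep", "sedentary", "light", "walk", "nonwear")

#: Default device orientations (unit vectors).  Walking uses a tilted vector
#: so the gait oscillation excites all three axes — an axis-aligned walk
#: would leave two axes still and trip the 2-of-3-axes non-wear vote.
ORIENT_WALK = np.array([3.0, 4.0, 5.0]) / math.sqrt(50.0)
ORIENT_REST = np.array([0.20, -0.45, 0.87])
ORIENT_REST = ORIENT_REST / np.linalg.norm(ORIENT_REST)
ORIENT_NONWEAR = np.array([0.0, 0.0, 1.0])

# Posture-shift rotation: ~50 deg about a skew axis; iterating it moves every
# component of any (non-axis) orientation by well over the 50 mg non-wear
# range criterion, so worn rest periods never mimic a shelved device.
_axis = np.array([1.0, 2.0, 2.0]) / 3.0
_ang = math.radians(50.0)
_K = np.array([[0, -_axis[2], _axis[1]], [_axis[2], 0, -_axis[0]], [-_axis[1], _axis[0], 0]])
POSTURE_ROT = np.eye(3) + math.sin(_ang) * _K + (1 - math.cos(_ang)) * (_K @ _K)

# Sleep is nonstationary: quiet spells (the calibration's still points)
# interleaved with restless spells that keep the 60-min per-axis SD above the
# non-wear vote.  Both levels stay well inside the inactive ENMO band.
SLEEP_QUIET_SD_G = 0.004
SLEEP_RESTLESS_SD_G = 0.035
SEDENTARY_NOISE_SD_G = 0.025  # epoch ENMO ~11 mg, inactive band
LIGHT_AMP_RANGE_G = (0.10, 0.19)  # slow arm-swing amplitude; epoch ENMO = A/pi in 32-60 mg
LIGHT_FREQ_RANGE_HZ = (0.35, 0.55)  # below the gait band, so no valid step trains
LIGHT_WHITE_SD_G = 0.01
NONWEAR_NOISE_SD_G = 0.0003   # quantisation-scale


@dataclass
class ActivityBlock:
    """One scheduled behaviour block."""

    kind: str
    start: pd.Timestamp
    duration_s: float
    cadence_spm: float | None = None
    peak_amp_g: float | None = None
    jitter: float = 0.0
    orientation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in BLOCK_KINDS:
            raise ValueError(f"unsupported block kind {self.kind!r}")
        self.start = pd.Timestamp(self.start)
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not 0 <= self.jitter <= 0.5:
            raise ValueError("jitter must be in [0, 0.5]")
        if self.kind == "walk":
            if self.cadence_spm is None or not 40 <= self.cadence_spm <= 160:
                raise ValueError("walk blocks need cadence_spm in [40, 160]")
            if self.peak_amp_g is None or self.peak_amp_g <= 0:
                raise ValueError("walk blocks need a positive peak_amp_g")
        if self.orientation is not None:
            o = np.asarray(self.orientation, float)
            self.orientation = o / np.linalg.norm(o)

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(seconds=self.duration_s)


@dataclass
class BlockTruth:
    """Ground truth contributed by one block (before day attribution)."""

    step_times_s: np.ndarray          # seconds from block start
    mvpa: bool                        # generated in the >=100 mg ENMO band
    bout_eligible: bool               # continuous walk block of >= 600 s in band
    wear: bool
    sleep: bool


def _orient_series(n: int, rate_hz: float, base: np.ndarray, rng: np.random.Generator,
                   mean_interval_s: float) -> np.ndarray:
    """Piecewise-constant orientation with posture shifts at random intervals."""
    out = np.empty((n, 3))
    u = base.copy()
    pos = 0
    while pos < n:
        hold = int(rng.uniform(0.7, 1.3) * mean_interval_s * rate_hz)
        hold = max(hold, 1)
        out[pos : pos + hold] = u
        pos += hold
        u = POSTURE_ROT @ u
    return out


def _smooth_knots(n: int, rate_hz: float, freq_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-scale smooth random signal (linear interpolation of slow knots)."""
    n_knots = int(np.ceil(n / rate_hz * freq_hz)) + 2
    knots = rng.uniform(-1.0, 1.0, n_knots)
    pos = np.arange(n) * (freq_hz / rate_hz)
    i = pos.astype(np.int64)
    frac = pos - i
    return knots[i] * (1.0 - frac) + knots[i + 1] * frac


def _wandering_orientation(
    orient: np.ndarray, rate_hz: float, rng: np.random.Generator,
    amp_deg: float, freq_hz: float,
) -> np.ndarray:
    """Add slow angular wander to an orientation series, keeping unit norm.

    Worn limbs are never perfectly rigid: the arm angle drifts by a few
    degrees on a multi-second timescale.  The wandered orientation is
    re-normalised, so magnitude-modulated signals built on it keep their
    exact acceleration-norm (and hence ENMO) closed form.
    """
    n = len(orient)
    base = orient[0]
    p = np.cross(base, [0.0, 0.0, 1.0] if abs(base[2]) < 0.9 else [1.0, 0.0, 0.0])
    p /= np.linalg.norm(p)
    q = np.cross(base, p)
    amp = math.radians(amp_deg)
    a = _smooth_knots(n, rate_hz, freq_hz, rng) * amp
    b = _smooth_knots(n, rate_hz, freq_hz, rng) * amp
    u = orient + a[:, None] * p[None, :] + b[:, None] * q[None, :]
    return u / np.linalg.norm(u, axis=1, keepdims=True)


def simulate_block(
    block: ActivityBlock, rate_hz: float, rng: np.random.Generator, dtype=np.float64
) -> tuple[np.ndarray, BlockTruth]:
    """Generate the (n, 3) sample array and truth for one block."""
    n = int(round(block.duration_s * rate_hz))
    kind = block.kind
    noise_dtype = np.float32 if dtype == np.float32 else np.float64

    def noise(sd: float) -> np.ndarray:
        return rng.standard_normal((n, 3), dtype=noise_dtype) * noise_dtype(sd)

    if kind == "nonwear":
        u = block.orientation if block.orientation is not None else ORIENT_NONWEAR
        samples = u[None, :].astype(dtype) + noise(NONWEAR_NOISE_SD_G)
        return samples, BlockTruth(np.empty(0), False, False, False, False)

    if kind == "sleep":
        base = block.orientation if block.orientation is not None else ORIENT_REST
        orient = _orient_series(n, rate_hz, base, rng, mean_interval_s=28 * 60)
        sd = np.empty(n, dtype=noise_dtype)
        pos = 0
        while pos < n:  # quiet 5-10 min, restless 1-4 min
            quiet = int(rng.uniform(5, 10) * 60 * rate_hz)
            sd[pos : pos + quiet] = SLEEP_QUIET_SD_G
            pos += quiet
            restless = int(rng.uniform(1, 4) * 60 * rate_hz)
            sd[pos : pos + restless] = SLEEP_RESTLESS_SD_G
            pos += restless
        samples = orient.astype(dtype) + rng.standard_normal((n, 3), dtype=noise_dtype) * sd[:, None]
        return samples, BlockTruth(np.empty(0), False, False, True, True)

    if kind == "sedentary":
        base = block.orientation if block.orientation is not None else ORIENT_REST
        orient = _orient_series(n, rate_hz, base, rng, mean_interval_s=7 * 60)
        orient = _wandering_orientation(orient, rate_hz, rng, amp_deg=10.0, freq_hz=0.12)
        samples = orient.astype(dtype) + noise(SEDENTARY_NOISE_SD_G)
        return samples, BlockTruth(np.empty(0), False, False, True, False)

    if kind == "light":
        base = block.orientation if block.orientation is not None else ORIENT_REST
        orient = _orient_series(n, rate_hz, base, rng, mean_interval_s=10 * 60)
        orient = _wandering_orientation(orient, rate_hz, rng, amp_deg=10.0, freq_hz=0.15)
        # slow arm-swing oscillation: magnitude = 1 + A sin(2π f t), with A
        # and f redrawn every 30 s.  Epoch ENMO is exactly A/π (bounded
        # inside the light band) and f sits below the gait band, so the
        # step detector can never chain these peaks into a train.
        seg = int(30 * rate_hz)
        t = np.arange(n, dtype=noise_dtype) / noise_dtype(rate_hz)
        magnitude = np.ones(n, dtype=noise_dtype)
        lo_a, hi_a = LIGHT_AMP_RANGE_G
        lo_f, hi_f = LIGHT_FREQ_RANGE_HZ
        for p in range(0, n, seg):
            q = min(p + seg, n)
            a = rng.uniform(lo_a, hi_a)
            f = rng.uniform(lo_f, hi_f)
            phase = rng.uniform(0, 2 * np.pi)
            magnitude[p:q] += noise_dtype(a) * np.sin(
                2 * np.pi * noise_dtype(f) * t[p:q] + noise_dtype(phase)
            )
        samples = orient.astype(dtype) * magnitude[:, None] + noise(LIGHT_WHITE_SD_G)
        return samples, BlockTruth(np.empty(0), False, False, True, False)

    # walk
    u = block.orientation if block.orientation is not None else ORIENT_WALK
    orient = _wandering_orientation(
        np.broadcast_to(u, (n, 3)), rate_hz, rng, amp_deg=75.0, freq_hz=0.40
    )
    cadence = float(block.cadence_spm)
    n_cycles = int(round(block.duration_s * cadence / 60.0))
    freq = n_cycles / block.duration_s
    t = np.arange(n) / rate_hz
    theta = 2.0 * math.pi * freq * t
    wave = np.sin(theta) + GAIT_HARMONIC * np.sin(2.0 * theta)
    amp = GAIT_AMP_SCALE * float(block.peak_amp_g)
    if block.jitter > 0:
        cyc = np.minimum((t * freq).astype(int), n_cycles - 1)
        per_cycle = 1.0 + block.jitter * np.clip(rng.normal(0.0, 0.5, n_cycles), -1.5, 1.5)
        amp = amp * per_cycle[cyc]
    magnitude = 1.0 + amp * wave
    samples = orient * magnitude[:, None]
    if block.jitter > 0:
        samples = samples + rng.normal(0.0, 0.05 * block.jitter, (n, 3))
    # one step per gait cycle, timed at the waveform peak (theta ~ 1.155 rad)
    peak_phase = 1.1547 / (2.0 * math.pi)
    step_times = (np.arange(n_cycles) + peak_phase) / freq
    mvpa = expected_walk_enmo_mg(block.peak_amp_g) >= 100.0
    bout_eligible = mvpa and block.duration_s >= 600.0
    return samples, BlockTruth(step_times, mvpa, bout_eligible, True, False)


TRUTH_COLUMNS = ["true_steps", "true_mvpa_s", "true_bouted_mvpa_s", "true_wear_s", "true_sleep_s"]


def _attribute_to_days(
    block: ActivityBlock, truth: BlockTruth, ref: pd.Timestamp, acc: dict[int, np.ndarray]
) -> None:
    """Add one block's truth to the per-day accumulator (midnight splits honoured)."""
    def day_of(ts: pd.Timestamp) -> int:
        return int((ts.normalize() - ref).days)

    if len(truth.step_times_s):
        block_off_s = (block.start - ref).total_seconds()
        step_days = np.floor((block_off_s + truth.step_times_s) / 86400.0).astype(int)
        for d, cnt in zip(*np.unique(step_days, return_counts=True)):
            acc.setdefault(int(d), np.zeros(5))[0] += cnt
    cur = block.start
    while cur < block.end:
        nxt = min(block.end, cur.normalize() + pd.Timedelta(days=1))
        overlap = (nxt - cur).total_seconds()
        row = acc.setdefault(day_of(cur), np.zeros(5))
        if truth.mvpa:
            row[1] += overlap
        if truth.bout_eligible:
            row[2] += overlap
        if truth.wear:
            row[3] += overlap
        if truth.sleep:
            row[4] += overlap
        cur = nxt


def generate_recording(
    schedule: list[ActivityBlock],
    meta: ParticipantMeta | None = None,
    rate_hz: float = 50.0,
    miscalibration: tuple[np.ndarray, np.ndarray] | None = None,
    seed: int = 0,
    dtype=np.float64,
) -> tuple[RawRecording, pd.DataFrame]:
    """Render a gap-free schedule to a recording plus per-day ground truth.

    ``miscalibration`` is an optional (offset_g, gain) pair applied after
    the truth is recorded, so truth always reflects the physical signal.
    Deterministic for a fixed seed.
    """
    if not schedule:
        raise ValueError("schedule is empty")
    blocks = sorted(schedule, key=lambda b: b.start)
    for prev, nxt in zip(blocks, blocks[1:]):
        delta = (nxt.start - prev.end).total_seconds()
        if delta < -1e-6:
            raise ValueError(f"overlapping blocks at {nxt.start}")
        if delta > 1e-6:
            raise ValueError(f"uncovered time before {nxt.start}")
    rng = np.random.default_rng(seed)
    ref = (pd.Timestamp(meta.pci_date) if meta is not None
           else blocks[0].start).normalize()

    parts: list[np.ndarray] = []
    acc: dict[int, np.ndarray] = {}
    for block in blocks:
        samples, truth = simulate_block(block, rate_hz, rng, dtype=dtype)
        parts.append(samples.astype(dtype, copy=False))
        _attribute_to_days(block, truth, ref, acc)
    samples = np.concatenate(parts)

    days = sorted(acc)
    truth_df = pd.DataFrame(
        [acc[d] for d in days], index=pd.Index(days, name="day_index"), columns=TRUTH_COLUMNS
    )
    truth_df["true_steps"] = truth_df["true_steps"].astype(int)

    pid = meta.participant_id if meta is not None else "synthetic"
    rec = RawRecording(pid, blocks[0].start, rate_hz, samples)
    if miscalibration is not None:
        rec = apply_device_distortion(rec, *miscalibration)
    return rec, truth_df


def apply_device_distortion(
    rec: RawRecording, offset_g: np.ndarray, gain: np.ndarray
) -> RawRecording:
    """sample' = gain ⊙ sample + offset, clipped to the dynamic range."""
    offset_g = np.asarray(offset_g, float)
    gain = np.asarray(gain, float)
    if np.any((gain <= 0.9) | (gain >= 1.1)):
        raise ValueError("gains must lie in (0.9, 1.1)")
    if np.any(np.abs(offset_g) > 0.1):
        raise ValueError("offsets must satisfy |offset| <= 0.1 g")
    dtype = rec.samples.dtype
    distorted = (rec.samples.astype(np.float64, copy=False) * gain + offset_g).astype(dtype)
    np.clip(distorted, -rec.dynamic_range_g, rec.dynamic_range_g, out=distorted)
    return RawRecording(rec.participant_id, rec.start_time, rec.sample_rate_hz,
                        distorted, rec.dynamic_range_g)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Designed cohort: archetype mixture, schedules, and step tiers.

    Defaults describe the reference verification cohort: 20 participants,
    20% bout exercisers (one 40-min brisk walk per day) and 80% sporadic
    accumulators (ten 4-min brisk walks), eight recorded days starting on
    day 2 after the intervention, worn 06:00–22:00.  Sub-MVPA strolls tier
    total daily steps to 6,200 / 8,700 / 11,500 so the four adherence
    criteria have designed prevalences 2020=100%, 7,500=70%, 10,000=45%,
    2010=20%.
    """

    n_participants: int = 20
    fraction_bout_exercisers: float = 0.2
    n_days: int = 8
    first_day_index: int = 2
    wear_start_h: int = 6
    wear_end_h: int = 22
    walk_cadence_spm: float = 110.0
    walk_peak_amp_g: float = 0.5
    exerciser_walk_min: float = 40.0
    accumulator_walk_min: float = 4.0
    accumulator_n_walks: int = 10
    stroll_cadence_spm: float = 80.0
    stroll_peak_amp_g: float = 0.24
    step_tiers: tuple[float, ...] = (6200.0, 8700.0, 11500.0)
    step_tier_counts: tuple[int, ...] = (6, 5, 9)
    jitter: float = 0.0
    offset_range_g: float = 0.0
    gain_range: float = 0.0
    sample_rate_hz: float = 50.0
    pci_date: str = "2021-03-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if not 0 <= self.fraction_bout_exercisers <= 1:
            raise ValueError("fraction_bout_exercisers must be in [0, 1]")
        if sum(self.step_tier_counts) != self.n_participants:
            raise ValueError("step tier counts must sum to n_participants")


@dataclass
class ParticipantPlan:
    meta: ParticipantMeta
    archetype: str                 # "exerciser" | "accumulator"
    target_steps: float
    stroll_s: float
    walk_steps_per_day: int


def cohort_plans(spec: CohortSpec) -> list[ParticipantPlan]:
    """Deterministic archetype + step-tier assignment for every participant."""
    n_ex = int(round(spec.n_participants * spec.fraction_bout_exercisers))
    # interleave tiers (largest pool first) so both archetypes span all tiers
    order = np.argsort(spec.step_tier_counts)[::-1]
    remaining = list(spec.step_tier_counts)
    tier_seq: list[int] = []
    while len(tier_seq) < spec.n_participants:
        for t in order:
            if remaining[t] > 0:
                remaining[t] -= 1
                tier_seq.append(int(t))
    plans = []
    for i in range(spec.n_participants):
        archetype = "exerciser" if i < n_ex else "accumulator"
        if archetype == "exerciser":
            walk_steps = int(round(spec.exerciser_walk_min * spec.walk_cadence_spm))
        else:
            walk_steps = int(round(
                spec.accumulator_n_walks * spec.accumulator_walk_min * spec.walk_cadence_spm))
        target = spec.step_tiers[tier_seq[i]]
        stroll_steps = max(target - walk_steps, 0.0)
        stroll_s = stroll_steps * 60.0 / spec.stroll_cadence_spm
        stroll_s = round(stroll_s / 5.0) * 5.0  # keep the 5-s epoch grid
        meta = ParticipantMeta(
            participant_id=f"P{i:03d}",
            age_years=float(48 + (i * 7) % 28),
            sex="female" if i % 6 == 0 else "male",
            presentation="CCS" if i % 5 == 0 else "ACS",
            pci_date=pd.Timestamp(spec.pci_date),
        )
        plans.append(ParticipantPlan(meta, archetype, target, stroll_s, walk_steps))
    return plans


def daily_schedule(plan: ParticipantPlan, spec: CohortSpec, date: pd.Timestamp) -> list[ActivityBlock]:
    """One midnight-to-midnight day of blocks for a participant plan."""
    day = pd.Timestamp(date).normalize()
    wear_start = day + pd.Timedelta(hours=spec.wear_start_h)
    wear_end = day + pd.Timedelta(hours=spec.wear_end_h)
    blocks: list[ActivityBlock] = [
        ActivityBlock("nonwear", day, spec.wear_start_h * 3600.0)
    ]
    cursor = wear_start

    def add(kind: str, dur_s: float, **kw) -> None:
        nonlocal cursor
        blocks.append(ActivityBlock(kind, cursor, dur_s, jitter=spec.jitter
                                    if kind == "walk" else 0.0, **kw))
        cursor += pd.Timedelta(seconds=dur_s)

    add("light", 1800)
    if plan.archetype == "exerciser":
        add("sedentary", 1800)
        add("walk", spec.exerciser_walk_min * 60.0,
            cadence_spm=spec.walk_cadence_spm, peak_amp_g=spec.walk_peak_amp_g)
        add("sedentary", 1200)
    else:
        for _ in range(spec.accumulator_n_walks):
            add("walk", spec.accumulator_walk_min * 60.0,
                cadence_spm=spec.walk_cadence_spm, peak_amp_g=spec.walk_peak_amp_g)
            add("sedentary", 480)
    if plan.stroll_s > 0:
        add("walk", plan.stroll_s,
            cadence_spm=spec.stroll_cadence_spm, peak_amp_g=spec.stroll_peak_amp_g)
    # fill to one hour before wear end with alternating rest, then a light hour
    tail_start = wear_end - pd.Timedelta(hours=1)
    toggle = 0
    while cursor < tail_start:
        dur = min(1500 if toggle == 0 else 1200, (tail_start - cursor).total_seconds())
        add("sedentary" if toggle == 0 else "light", dur)
        toggle ^= 1
    add("light", (wear_end - cursor).total_seconds())
    blocks.append(ActivityBlock("nonwear", wear_end,
                                (day + pd.Timedelta(days=1) - wear_end).total_seconds()))
    return blocks


def designed_prevalence(spec: CohortSpec) -> pd.DataFrame:
    """Expected adherence flags per participant, from schedule arithmetic alone."""
    rows = []
    for plan in cohort_plans(spec):
        if plan.archetype == "exerciser":
            mvpa_min = spec.exerciser_walk_min
            bouted_min = spec.exerciser_walk_min if spec.exerciser_walk_min >= 10 else 0.0
        else:
            mvpa_min = spec.accumulator_n_walks * spec.accumulator_walk_min
            bouted_min = (mvpa_min if spec.accumulator_walk_min >= 10 else 0.0)
        if expected_walk_enmo_mg(spec.walk_peak_amp_g) < 100.0:
            mvpa_min = bouted_min = 0.0
        steps = plan.walk_steps_per_day + plan.stroll_s * spec.stroll_cadence_spm / 60.0
        rows.append(
            {
                "participant_id": plan.meta.participant_id,
                "archetype": plan.archetype,
                "designed_steps": steps,
                "designed_mvpa_min": mvpa_min,
                "designed_bouted_min": bouted_min,
                "who2020": mvpa_min >= 30.0,
                "who2010": bouted_min >= 30.0,
                "steps7500": steps >= 7500.0,
                "steps10000": steps >= 10000.0,
            }
        )
    return pd.DataFrame(rows).set_index("participant_id")


def generate_participant(
    plan: ParticipantPlan, spec: CohortSpec, participant_seed: int, dtype=np.float32
) -> tuple[RawRecording, pd.DataFrame]:
    """Render all recorded days of one participant."""
    start_day = pd.Timestamp(spec.pci_date) + pd.Timedelta(days=spec.first_day_index)
    schedule: list[ActivityBlock] = []
    for d in range(spec.n_days):
        schedule.extend(daily_schedule(plan, spec, start_day + pd.Timedelta(days=d)))
    rng = np.random.default_rng(participant_seed)
    miscal = None
    if spec.offset_range_g > 0 or spec.gain_range > 0:
        miscal = (
            rng.uniform(-spec.offset_range_g, spec.offset_range_g, 3),
            1.0 + rng.uniform(-spec.gain_range, spec.gain_range, 3),
        )
    return generate_recording(
        schedule, plan.meta, spec.sample_rate_hz, miscal,
        seed=int(participant_seed), dtype=dtype,
    )


def generate_cohort(spec: CohortSpec, dtype=np.float32):
    """Yield (plan, recording, truth) per participant; deterministic in spec.seed."""
    ss = np.random.SeedSequence(spec.seed)
    seeds = ss.generate_state(len(cohort_plans(spec)))
    for plan, s in zip(cohort_plans(spec), seeds):
        rec, truth = generate_participant(plan, spec, int(s) % (2**31 - 1), dtype=dtype)
        yield plan, rec, truth
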