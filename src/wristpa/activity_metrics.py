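"""Daily activity metrics from the 5-s epoch series.

Covers intensity classification (<25 mg inactive, 25–99 mg light,
≥100 mg MVPA), time accrual per class, detection of ≥10-min MVPA bouts
under the 80% criterion, the MX metrics (minimum acceleration over the
most active 2/30/60 min), and the 24-h mean acceleration with cross-day
imputation of non-wear.  All functions operate on one midnight-to-midnight
day (17,280 epochs); non-wear epochs never contribute activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .config import (
    EPOCHS_PER_DAY,
    EPOCHS_PER_MIN,
    BoutParams,
    IntensityBands,
    PipelineConfig,
)

__all__ = [
    "INACTIVE",
    "LIGHT",
    "MVPA",
    "BoutSet",
    "DaySummary",
    "classify_epoch_intensity",
    "accrue_class_minutes",
    "detect_mvpa_bouts",
    "mx_metrics",
    "mean_acceleration_24h",
    "summarize_day_activity",
]

INACTIVE, LIGHT, MVPA = 0, 1, 2


def classify_epoch_intensity(
    enmo_mg: np.ndarray, bands: IntensityBands | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Intensity class codes (0/1/2) and the vigorous sub-flag per epoch."""
    b = bands or IntensityBands()
    enmo_mg = np.asarray(enmo_mg)
    classes = np.where(enmo_mg >= b.mvpa_min_mg, MVPA,
                       np.where(enmo_mg >= b.inactive_max_mg, LIGHT, INACTIVE))
    vigorous = enmo_mg >= b.vigorous_min_mg
    return classes, vigorous


def accrue_class_minutes(
    enmo_mg: np.ndarray,
    wear: np.ndarray,
    bands: IntensityBands | None = None,
    mode: str = "epoch",
) -> dict[str, float]:
    """Daily minutes per intensity class.

    ``epoch`` accrual counts wear epochs per class divided by 12.  The
    ``minute80`` alternative scores whole minutes: a minute is MVPA when at
    least 80% of its 12 epochs are worn and above the MVPA cut-point
    (vigorous analogously); other minutes go to the majority class among
    their worn epochs.
    """
    if len(enmo_mg) != EPOCHS_PER_DAY:
        raise ValueError("accrual requires a full-day epoch grid")
    b = bands or IntensityBands()
    classes, vigorous = classify_epoch_intensity(enmo_mg, b)
    wear = np.asarray(wear, bool)
    if mode == "epoch":
        return {
            "inactive_min": float(np.sum(wear & (classes == INACTIVE)) / EPOCHS_PER_MIN),
            "lpa_min": float(np.sum(wear & (classes == LIGHT)) / EPOCHS_PER_MIN),
            "mvpa_min": float(np.sum(wear & (classes == MVPA)) / EPOCHS_PER_MIN),
            "vpa_min": float(np.sum(wear & vigorous) / EPOCHS_PER_MIN),
        }
    if mode != "minute80":
        raise ValueError(f"unknown accrual mode {mode!r}")
    w = wear.reshape(-1, EPOCHS_PER_MIN)
    cls = classes.reshape(-1, EPOCHS_PER_MIN)
    vig = vigorous.reshape(-1, EPOCHS_PER_MIN)
    need = int(np.ceil(0.8 * EPOCHS_PER_MIN))
    mvpa_minutes = (w & (cls == MVPA)).sum(axis=1) >= need
    vpa_minutes = (w & vig).sum(axis=1) >= need
    n_inact = (w & (cls == INACTIVE)).sum(axis=1)
    n_light = (w & (cls == LIGHT)).sum(axis=1)
    n_mvpa = (w & (cls == MVPA)).sum(axis=1)
    any_wear = w.any(axis=1)
    counts = np.stack([n_inact, n_light, n_mvpa], axis=1)
    majority = counts.argmax(axis=1)
    inact_minutes = any_wear & ~mvpa_minutes & (majority == INACTIVE)
    light_minutes = any_wear & ~mvpa_minutes & (majority == LIGHT)
    return {
        "inactive_min": float(inact_minutes.sum()),
        "lpa_min": float(light_minutes.sum()),
        "mvpa_min": float(mvpa_minutes.sum()),
        "vpa_min": float(vpa_minutes.sum()),
    }


@dataclass
class BoutSet:
    """Disjoint, ordered MVPA bout intervals as [start, end) epoch indices."""

    intervals: list[tuple[int, int]] = field(default_factory=list)
    criterion_fraction: float = 0.8
    min_duration_epochs: int = 120

    @property
    def total_epochs(self) -> int:
        return sum(e - s for s, e in self.intervals)

    @property
    def minutes(self) -> float:
        return self.total_epochs / EPOCHS_PER_MIN


def _segments_without_long_gaps(above: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Maximal index ranges containing no below-threshold run longer than max_gap.

    A qualifying bout can never cross such a run (its ends must be above
    threshold), so detection decomposes over these segments.
    """
    n = len(above)
    padded = np.concatenate([[True], above, [True]]).astype(np.int8)
    d = np.diff(padded)
    run_starts = np.flatnonzero(d == -1)
    run_ends = np.flatnonzero(d == 1)
    cuts = [(int(s), int(e)) for s, e in zip(run_starts, run_ends) if e - s > max_gap]
    segments = []
    pos = 0
    for s, e in cuts:
        if s > pos:
            segments.append((pos, s))
        pos = e
    if pos < n:
        segments.append((pos, n))
    return segments


def detect_mvpa_bouts(
    enmo_mg: np.ndarray,
    wear: np.ndarray,
    bands: IntensityBands | None = None,
    bout: BoutParams | None = None,
) -> BoutSet:
    """Detect ≥10-min MVPA bouts under the 80%-of-epochs criterion.

    A qualifying interval has ≥ ``min_duration_epochs`` epochs, at least
    ``criterion_fraction`` of them above the MVPA threshold, above-threshold
    first and last epochs, and no internal below-threshold run longer than
    ``max_gap_epochs``.  Bouts are selected left to right, each extended to
    its maximal qualifying end, and never overlap.  Non-wear epochs count
    as below threshold.
    """
    b = bands or IntensityBands()
    p = bout or BoutParams()
    frac = p.criterion_fraction
    min_len = p.min_duration_epochs
    above = (np.asarray(enmo_mg) >= b.mvpa_min_mg) & np.asarray(wear, bool)

    # exact integer arithmetic: fraction >= p/q  <=>  q*above_count >= p*length
    fr = Fraction(frac).limit_denominator(10_000)
    fp, fq = fr.numerator, fr.denominator

    bouts = BoutSet(criterion_fraction=frac, min_duration_epochs=min_len)
    for a, bnd in _segments_without_long_gaps(above, p.max_gap_epochs):
        seg = above[a:bnd]
        m = len(seg)
        if m < min_len:
            continue
        cum = np.concatenate([[0], np.cumsum(seg)]).astype(np.int64)
        g = fq * cum - fp * np.arange(m + 1, dtype=np.int64)
        # g[e] >= g[s]  <=>  above-fraction of [s, e) >= frac (exactly)
        neg_inf = np.iinfo(np.int64).min
        gm = np.where(np.concatenate([[False], seg]), g, neg_inf)
        suff = np.maximum.accumulate(gm[::-1])[::-1]  # suff[i] = max(gm[i:])
        s = 0
        while s <= m - min_len:
            if not seg[s]:
                s += 1
                continue
            lo = s + min_len
            if lo > m or suff[lo] < g[s]:
                s += 1
                continue
            hi = m
            while lo < hi:  # largest e with suff[e] >= g[s] (suff non-increasing)
                mid = (lo + hi + 1) // 2
                if suff[mid] >= g[s]:
                    lo = mid
                else:
                    hi = mid - 1
            bouts.intervals.append((a + s, a + lo))
            s = lo
    return bouts


def mx_metrics(enmo_mg: np.ndarray, wear: np.ndarray,
               minutes: tuple[int, ...] = (2, 30, 60)) -> dict[str, float]:
    """Minimum ENMO over the most active X minutes (non-wear counts as 0 mg)."""
    if len(enmo_mg) != EPOCHS_PER_DAY:
        raise ValueError("MX metrics require a full-day epoch grid")
    vals = np.where(np.asarray(wear, bool), np.asarray(enmo_mg), 0.0)
    ordered = np.sort(vals)[::-1]
    return {f"m{x}_mg": float(ordered[x * EPOCHS_PER_MIN - 1]) for x in minutes}


def mean_acceleration_24h(
    enmo_mg: np.ndarray,
    wear: np.ndarray,
    donor_mean_mg: np.ndarray | None = None,
) -> float:
    """24-h mean ENMO with non-wear imputed from other valid days.

    ``donor_mean_mg`` holds, per clock epoch, the participant's mean worn
    ENMO over the *other* valid days (NaN where no donor exists); without a
    donor a non-wear epoch contributes 0.
    """
    if len(enmo_mg) != EPOCHS_PER_DAY:
        raise ValueError("24-h mean requires a full-day epoch grid")
    wear = np.asarray(wear, bool)
    filled = np.where(wear, np.asarray(enmo_mg, float), 0.0)
    if donor_mean_mg is not None:
        donor = np.asarray(donor_mean_mg, float)
        use = ~wear & ~np.isnan(donor)
        filled[use] = donor[use]
    return float(filled.mean())


@dataclass
class DaySummary:
    """All per-day metrics for one midnight-to-midnight day."""

    participant_id: str
    day_index: int
    wear_hours: float = 0.0
    inactive_min: float = 0.0
    lpa_min: float = 0.0
    mvpa_min: float = 0.0
    mvpa_bout10_min: float = 0.0
    vpa_min: float = 0.0
    sleep_min: float = 0.0
    mean_acc_mg: float = float("nan")
    m2_mg: float = float("nan")
    m30_mg: float = float("nan")
    m60_mg: float = float("nan")
    steps: int = 0
    mean_cadence_spm: float = 0.0
    cad100_min: float = 0.0
    pct_zero_cadence: float = 0.0
    peak1_cad: float = 0.0
    peak30_cad: float = 0.0
    peak60_cad: float = 0.0


METRIC_COLUMNS = [f.name for f in DaySummary.__dataclass_fields__.values()
                  if f.name not in ("participant_id", "day_index")]


def summarize_day_activity(
    participant_id: str,
    day_index: int,
    enmo_mg: np.ndarray,
    wear: np.ndarray,
    sleep: np.ndarray,
    config: PipelineConfig | None = None,
    donor_mean_mg: np.ndarray | None = None,
) -> DaySummary:
    """Assemble the activity fields of a day summary (steps filled elsewhere)."""
    cfg = config or PipelineConfig()
    wear = np.asarray(wear, bool)
    acc = accrue_class_minutes(enmo_mg, wear, cfg.bands, cfg.accrual_mode)
    bouts = detect_mvpa_bouts(enmo_mg, wear, cfg.bands, cfg.bout)
    mx = mx_metrics(enmo_mg, wear)
    return DaySummary(
        participant_id=participant_id,
        day_index=day_index,
        wear_hours=float(wear.sum() / EPOCHS_PER_MIN / 60.0),
        sleep_min=float(np.asarray(sleep, bool).sum() / EPOCHS_PER_MIN),
        mvpa_bout10_min=bouts.minutes,
        mean_acc_mg=mean_acceleration_24h(enmo_mg, wear, donor_mean_mg),
        **acc,
        **mx,
    )
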