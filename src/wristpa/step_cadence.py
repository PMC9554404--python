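"""Step counting by windowed peak detection, and cadence metrics.

The acceleration magnitude is resampled to a modest rate (default 15 Hz),
candidate peaks are local maxima above a magnitude floor, and a chain of
gait-plausibility filters (inter-peak period, peak-to-peak similarity,
continuity of the peak train, local signal variance) discards isolated or
non-periodic events.  Each surviving peak is one step.  Steps are then
assigned to 5-s epochs, per-minute cadence is their 1-min sum, and the
daily cadence summary (mean over 1,440 fixed minutes, minutes at
≥100 steps/min, percentage of zero-cadence minutes, and the peak 1/30/60
cadences over not-necessarily-consecutive minutes) follows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import EPOCH_S, EPOCHS_PER_MIN, StepDetectorParams
from .epoching import EpochSeries
from .signal_io import RawRecording

__all__ = [
    "CadenceSummary",
    "detect_steps",
    "steps_to_epochs",
    "minute_cadence",
    "cadence_summary",
]

MINUTES_PER_DAY = 1440


@dataclass
class CadenceSummary:
    steps: int
    mean_cadence_spm: float
    cad100_min: float
    pct_zero_cadence: float
    peak1_cad: float
    peak30_cad: float
    peak60_cad: float


def _resample_magnitude(rec: RawRecording, resample_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Linear-interpolation resample of |a| onto a uniform grid; returns (t_s, mag)."""
    s = rec.samples
    mag = np.sqrt(np.einsum("ij,ij->i", s, s, dtype=np.float64))
    t_src = np.arange(rec.n_samples) / rec.sample_rate_hz
    n_out = int(np.floor(t_src[-1] * resample_hz)) + 1
    t_out = np.arange(n_out) / resample_hz
    return t_out, np.interp(t_out, t_src, mag)


def detect_steps(
    rec: RawRecording, params: StepDetectorParams | None = None
) -> np.ndarray:
    """Ordered step-event times (seconds from recording start).

    Filter chain on the resampled magnitude: (1) candidate peaks are
    maxima of their centred window; (2) magnitude ≥ ``magnitude_min_g``;
    (3) inter-peak interval within [period_min, period_max] samples — a
    peak arriving after a longer pause re-seeds a new candidate train;
    (4) peak amplitude within ``similarity_max_g`` of the previous kept
    peak; (5) trains need ≥ ``continuity_min_peaks`` peaks with in-range
    spacing and local variance ≥ ``variance_min_g2``.
    """
    p = params or StepDetectorParams()
    t_out, mag = _resample_magnitude(rec, p.resample_hz)
    n = len(mag)
    half = p.peak_window_samples // 2
    if n < 2 * half + 1:
        raise ValueError("recording shorter than one peak window")

    # local maxima of the centred window (left-biased on ties)
    is_peak = np.ones(n, bool)
    is_peak[:half] = False
    is_peak[n - half:] = False
    for k in range(1, half + 1):
        is_peak[half:n - half] &= (mag[half:n - half] >= mag[half - k:n - half - k])
        is_peak[half:n - half] &= (mag[half:n - half] > mag[half + k:n - half + k])
    is_peak &= mag >= p.magnitude_min_g
    cand = np.flatnonzero(is_peak)
    if len(cand) == 0:
        return np.empty(0)

    # local variance for the continuity filter (~1 s window)
    vwin = max(int(round(p.resample_hz)), 3)
    csum = np.concatenate([[0.0], np.cumsum(mag)])
    csum2 = np.concatenate([[0.0], np.cumsum(mag**2)])
    lo = np.maximum(cand - vwin // 2, 0)
    hi = np.minimum(cand + vwin // 2 + 1, n)
    cnt = hi - lo
    local_var = np.maximum(
        (csum2[hi] - csum2[lo]) / cnt - ((csum[hi] - csum[lo]) / cnt) ** 2, 0.0
    )
    var_ok = dict(zip(cand.tolist(), (local_var >= p.variance_min_g2).tolist()))

    # period + similarity filters, building candidate trains
    trains: list[list[int]] = []
    cur: list[int] = [int(cand[0])]
    for idx in cand[1:].tolist():
        gap = idx - cur[-1]
        if gap < p.period_min_samples:
            continue
        if gap > p.period_max_samples:
            trains.append(cur)
            cur = [idx]  # re-seed a new train after a pause
            continue
        if abs(mag[idx] - mag[cur[-1]]) > p.similarity_max_g:
            continue
        cur.append(idx)
    trains.append(cur)

    kept: list[int] = []
    for train in trains:
        if len(train) < p.continuity_min_peaks:
            continue
        kept.extend(i for i in train if var_ok[i])
    return t_out[np.array(sorted(kept), dtype=int)] if kept else np.empty(0)


def steps_to_epochs(step_times_s: np.ndarray, rec: RawRecording, es: EpochSeries) -> np.ndarray:
    """Per-epoch step counts; a step at an epoch boundary goes to the later epoch."""
    counts = np.zeros(es.n_epochs, np.int64)
    if len(step_times_s) == 0:
        return counts
    abs_times = rec.start_time + pd.to_timedelta(np.asarray(step_times_s), unit="s")
    rel_s = np.asarray((abs_times - es.epoch_start[0]).total_seconds())
    idx = np.floor(rel_s / EPOCH_S + 1e-9).astype(np.int64)
    in_range = (idx >= 0) & (idx < es.n_epochs)
    np.add.at(counts, idx[in_range], 1)
    return counts


def minute_cadence(epoch_steps: np.ndarray) -> np.ndarray:
    """Per-minute cadence (steps/min) as the sum of each minute's 12 epochs."""
    epoch_steps = np.asarray(epoch_steps)
    if len(epoch_steps) % EPOCHS_PER_MIN != 0:
        raise ValueError("epoch count must be a whole number of minutes")
    return epoch_steps.reshape(-1, EPOCHS_PER_MIN).sum(axis=1)


def cadence_summary(minute_steps: np.ndarray) -> CadenceSummary:
    """Daily cadence metrics over the fixed 1,440-minute day."""
    m = np.asarray(minute_steps)
    if len(m) != MINUTES_PER_DAY:
        raise ValueError("cadence summary requires 1,440 minute values")
    total = int(m.sum())
    ordered = np.sort(m)[::-1]
    peak = {x: float(ordered[:x].mean()) for x in (1, 30, 60)}
    return CadenceSummary(
        steps=total,
        mean_cadence_spm=total / MINUTES_PER_DAY,
        cad100_min=float(np.sum(m >= 100)),
        pct_zero_cadence=float(100.0 * np.sum(m == 0) / MINUTES_PER_DAY),
        peak1_cad=peak[1],
        peak30_cad=peak[30],
        peak60_cad=peak[60],
    )
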