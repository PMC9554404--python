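"""Epoch-level features: ENMO, z-angle, non-wear flags, sleep period.

The raw signal is reduced to 5-s epochs (the resolution at which all
downstream metrics operate): per-epoch mean ENMO in mg and the arm angle
relative to the horizontal plane (z-angle).  Non-wear is voted over 60-min
windows advanced in 15-min steps; the nightly sleep period is found by a
sustained-inactivity heuristic on z-angle variability, searched noon to
noon.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import EPOCH_S, EPOCHS_PER_MIN, MG_PER_G, NonwearParams, SleepParams
from .signal_io import RawRecording

__all__ = [
    "EpochSeries",
    "compute_enmo",
    "aggregate_epochs",
    "detect_nonwear",
    "detect_sleep_period",
]


@dataclass
class EpochSeries:
    """Per-5-s features on a grid aligned to local midnight."""

    epoch_start: pd.DatetimeIndex
    enmo_mg: np.ndarray
    z_angle_deg: np.ndarray
    wear: np.ndarray
    steps: np.ndarray
    sleep: np.ndarray
    epoch_length_s: int = EPOCH_S

    def __post_init__(self) -> None:
        n = len(self.epoch_start)
        for name in ("enmo_mg", "z_angle_deg", "wear", "steps", "sleep"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            setattr(self, name, arr)
        self.wear = self.wear.astype(bool)
        self.sleep = self.sleep.astype(bool)
        self.steps = self.steps.astype(np.int64)

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_start)

    def day_slices(self) -> list[tuple[pd.Timestamp, slice]]:
        """(midnight, slice) pairs, one per calendar day present."""
        days = self.epoch_start.normalize()
        out = []
        for day in days.unique():
            idx = np.flatnonzero(days == day)
            out.append((day, slice(int(idx[0]), int(idx[-1]) + 1)))
        return out


def compute_enmo(rec: RawRecording) -> np.ndarray:
    """Per-sample Euclidean norm minus one, truncated at zero, in mg."""
    s = rec.samples
    norm = np.sqrt(np.einsum("ij,ij->i", s, s, dtype=np.float64))
    return np.maximum(norm - 1.0, 0.0) * MG_PER_G


def _epoch_grid(rec: RawRecording) -> tuple[int, int, int, pd.Timestamp]:
    """First full-epoch sample index, samples/epoch, epoch count, first epoch start."""
    spe = int(round(EPOCH_S * rec.sample_rate_hz))
    if abs(spe - EPOCH_S * rec.sample_rate_hz) > 1e-6:
        raise ValueError("sample rate must yield an integer number of samples per epoch")
    midnight = rec.start_time.normalize()
    offset_s = (rec.start_time - midnight).total_seconds()
    first_boundary_s = float(np.ceil(offset_s / EPOCH_S - 1e-9)) * EPOCH_S
    i0 = int(round((first_boundary_s - offset_s) * rec.sample_rate_hz))
    n_epochs = (rec.n_samples - i0) // spe
    first_start = midnight + pd.Timedelta(seconds=first_boundary_s)
    return i0, spe, max(n_epochs, 0), first_start


def aggregate_epochs(rec: RawRecording, per_sample_enmo: np.ndarray | None = None) -> EpochSeries:
    """Aggregate a calibrated recording to the 5-s epoch grid.

    Epoch ENMO is the mean of the epoch's per-sample ENMO; the z-angle is
    atan(z̄ / √(x̄² + ȳ²)) of the epoch's per-axis means.  Partial epochs
    at the recording edges are dropped so the grid stays midnight-aligned.
    """
    if per_sample_enmo is None:
        per_sample_enmo = compute_enmo(rec)
    i0, spe, n_epochs, first_start = _epoch_grid(rec)
    if n_epochs == 0:
        raise ValueError("recording too short for a single aligned epoch")
    end = i0 + n_epochs * spe
    enmo = per_sample_enmo[i0:end].reshape(n_epochs, spe).mean(axis=1)
    axes = rec.samples[i0:end].reshape(n_epochs, spe, 3)
    means = axes.mean(axis=1, dtype=np.float64)
    horiz = np.hypot(means[:, 0], means[:, 1])
    z_angle = np.degrees(np.arctan2(means[:, 2], horiz))
    starts = first_start + pd.to_timedelta(np.arange(n_epochs) * EPOCH_S, unit="s")
    n = n_epochs
    return EpochSeries(
        epoch_start=pd.DatetimeIndex(starts),
        enmo_mg=enmo,
        z_angle_deg=z_angle,
        wear=np.ones(n, bool),
        steps=np.zeros(n, np.int64),
        sleep=np.zeros(n, bool),
    )


def detect_nonwear(
    rec: RawRecording, es: EpochSeries, params: NonwearParams | None = None
) -> np.ndarray:
    """Per-epoch wear flags from windowed stillness votes on the raw signal.

    Each 60-min window (advanced in 15-min steps) votes non-wear when at
    least ``min_axes`` of the three axes are still (per-axis SD below
    ``sd_mg`` or range below ``range_mg``); an epoch is non-wear when any
    covering window votes non-wear.
    """
    p = params or NonwearParams()
    i0, spe, n_epochs, _ = _epoch_grid(rec)
    rate = rec.sample_rate_hz
    chunk_len = int(round(p.slide_min * 60 * rate))
    chunks_per_window = p.window_min // p.slide_min
    epochs_per_chunk = p.slide_min * 60 // EPOCH_S

    n_use = (min(rec.n_samples, i0 + n_epochs * spe) - i0) // chunk_len * chunk_len
    wear = np.ones(n_epochs, bool)
    if n_use < chunk_len * chunks_per_window:
        return wear
    data = rec.samples[i0 : i0 + n_use]
    n_chunks = n_use // chunk_len
    blocks = data.reshape(n_chunks, chunk_len, 3)
    c_sum = blocks.sum(axis=1, dtype=np.float64)
    c_sumsq = np.einsum("ijk,ijk->ik", blocks, blocks, dtype=np.float64)
    c_min = blocks.min(axis=1).astype(np.float64)
    c_max = blocks.max(axis=1).astype(np.float64)

    n_windows = n_chunks - chunks_per_window + 1
    idx = np.arange(n_windows)[:, None] + np.arange(chunks_per_window)[None, :]
    w_n = chunk_len * chunks_per_window
    w_sum = c_sum[idx].sum(axis=1)
    w_sumsq = c_sumsq[idx].sum(axis=1)
    w_mean = w_sum / w_n
    w_var = np.maximum(w_sumsq / w_n - w_mean**2, 0.0)
    w_sd_mg = np.sqrt(w_var) * MG_PER_G
    w_range_mg = (c_max[idx].max(axis=1) - c_min[idx].min(axis=1)) * MG_PER_G

    still_axes = ((w_sd_mg < p.sd_mg) | (w_range_mg < p.range_mg)).sum(axis=1)
    votes_nonwear = still_axes >= p.min_axes

    for w in np.flatnonzero(votes_nonwear):
        lo = w * epochs_per_chunk
        hi = min((w + chunks_per_window) * epochs_per_chunk, n_epochs)
        wear[lo:hi] = False
    return wear


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of True runs."""
    padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def detect_sleep_period(
    es: EpochSeries, params: SleepParams | None = None
) -> tuple[np.ndarray, dict[pd.Timestamp, float]]:
    """Nightly sleep period from sustained low z-angle variability.

    For each 5-min block the mean absolute successive z-angle difference is
    computed; blocks below an adaptive threshold (a multiple of the
    noon-to-noon window's 10th percentile, floored and capped) mark
    sustained inactivity.  Runs separated by less than ``merge_gap_min``
    are merged; the longest merged run of at least ``min_period_min``
    between noon and the following noon is the sleep period.

    Returns per-epoch sleep flags and sleep minutes per night (keyed by the
    noon that opens the search window).
    """
    p = params or SleepParams()
    bpb = p.block_min * EPOCHS_PER_MIN  # epochs per block
    n_blocks = es.n_epochs // bpb
    sleep = np.zeros(es.n_epochs, bool)
    minutes: dict[pd.Timestamp, float] = {}
    if n_blocks == 0:
        return sleep, minutes

    z = es.z_angle_deg[: n_blocks * bpb].reshape(n_blocks, bpb)
    block_val = np.abs(np.diff(z, axis=1)).mean(axis=1)
    block_start = es.epoch_start[np.arange(n_blocks) * bpb]
    # noon-to-noon window key: shift back 12 h and take the date
    window_key = (block_start - pd.Timedelta(hours=12)).normalize()

    for key in window_key.unique():
        sel = np.flatnonzero(window_key == key)
        vals = block_val[sel]
        if len(vals) < p.min_period_min // p.block_min:
            continue
        thr = float(np.clip(
            p.threshold_factor * np.percentile(vals, p.percentile),
            p.threshold_floor_deg,
            p.threshold_cap_deg,
        ))
        below = vals < thr
        runs = _runs(below)
        if not runs:
            continue
        # merge runs separated by gaps shorter than merge_gap_min
        merged = [list(runs[0])]
        gap_blocks = p.merge_gap_min // p.block_min
        for s, e in runs[1:]:
            if s - merged[-1][1] < gap_blocks:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        min_blocks = p.min_period_min // p.block_min
        candidates = [(e - s, s, e) for s, e in merged if e - s >= min_blocks]
        if not candidates:
            minutes[pd.Timestamp(key) + pd.Timedelta(hours=12)] = 0.0
            continue
        length, s, e = max(candidates)
        lo = sel[s] * bpb
        hi = (sel[e - 1] + 1) * bpb
        sleep[lo:hi] = True
        minutes[pd.Timestamp(key) + pd.Timedelta(hours=12)] = length * p.block_min
    return sleep, minutes
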