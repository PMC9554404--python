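"""Raw-signal containers and text-format I/O.

The raw interface is a documented CSV dialect (``time,x,y,z``; ISO-8601
timestamps; accelerations in g) rather than a proprietary binary container:
readers for other formats can be added behind the same
:class:`RawRecording` contract.  Timestamps are timezone-naive local time
and calendar days run from local midnight to local midnight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawRecording",
    "ParticipantMeta",
    "DaySegment",
    "read_raw_recording",
    "write_raw_recording",
    "read_epoch_series",
    "write_epoch_series",
    "slice_days",
]


@dataclass
class ParticipantMeta:
    """Participant-level metadata carried alongside a recording.

    ``pci_date`` is day 0 of the observation clock: daily metrics are
    indexed relative to the date of the coronary intervention.
    """

    participant_id: str
    age_years: float
    sex: str                      # "female" | "male"
    presentation: str             # "ACS" | "CCS"
    pci_date: pd.Timestamp

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.presentation not in ("ACS", "CCS"):
            raise ValueError(f"presentation must be 'ACS' or 'CCS', got {self.presentation!r}")
        if not 18 < self.age_years <= 80:
            raise ValueError("age_years must be in (18, 80]")
        self.pci_date = pd.Timestamp(self.pci_date).normalize()


@dataclass
class RawRecording:
    """Tri-axial wrist acceleration on a strict uniform sampling grid.

    ``samples`` is an (n, 3) array in g.  The device convention is a ±8 g
    dynamic range sampled at a nominal 50 Hz.
    """

    participant_id: str
    start_time: pd.Timestamp
    sample_rate_hz: float
    samples: np.ndarray
    dynamic_range_g: float = 8.0

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array")
        if self.samples.shape[0] == 0:
            raise ValueError("recording must contain at least one sample")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        amax = max(float(self.samples.max()), -float(self.samples.min()))
        if amax > self.dynamic_range_g + 1e-9:
            raise ValueError(
                f"axis value {amax:.3f} g exceeds dynamic range ±{self.dynamic_range_g} g"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def end_time(self) -> pd.Timestamp:
        return self.start_time + pd.Timedelta(seconds=self.duration_s)

    def sample_times(self) -> pd.DatetimeIndex:
        """Timestamps of every sample (may be large)."""
        return self.start_time + pd.to_timedelta(
            np.arange(self.n_samples) / self.sample_rate_hz, unit="s"
        )


class DaySegment(NamedTuple):
    """One midnight-to-midnight (possibly partial) slice of a recording."""

    day_index: int
    recording: RawRecording


def read_raw_recording(
    path: str | Path,
    meta: ParticipantMeta | None = None,
    sample_rate_hz: float | None = None,
    dynamic_range_g: float = 8.0,
    max_gap_s: float = 1.0,
) -> RawRecording:
    """Read the raw CSV dialect onto a strict uniform grid.

    Gaps up to ``max_gap_s`` are filled by holding the last observed
    sample; longer gaps raise.  Non-monotone timestamps and axis values
    outside the dynamic range raise.
    """
    df = pd.read_csv(path)
    expected = ["time", "x", "y", "z"]
    if list(df.columns[:4]) != expected:
        raise ValueError(f"raw CSV must have header {expected}, got {list(df.columns)}")
    t = pd.to_datetime(df["time"]).to_numpy()
    if len(t) < 2:
        raise ValueError("raw CSV needs at least two samples to define a grid")
    dt_s = np.diff(t).astype("timedelta64[ns]").astype(np.int64) / 1e9
    if np.any(dt_s <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if np.any(dt_s > max_gap_s + 1e-9):
        raise ValueError(f"gap of {dt_s.max():.3f} s exceeds the {max_gap_s} s limit")
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    if np.max(np.abs(xyz)) > dynamic_range_g + 1e-9:
        raise ValueError("axis values outside the device dynamic range")

    if sample_rate_hz is not None:
        rate = sample_rate_hz
    else:  # modal spacing, robust to held-over gaps
        vals, counts = np.unique(np.round(dt_s, 6), return_counts=True)
        rate = round(1.0 / float(vals[np.argmax(counts)]))
    step_ns = 1e9 / rate
    t0 = t[0]
    rel_ns = (t - t0).astype("timedelta64[ns]").astype(np.int64)
    idx = np.rint(rel_ns / step_ns).astype(np.int64)
    n = int(idx[-1]) + 1
    grid = np.empty((n, 3), dtype=float)
    have = np.zeros(n, dtype=bool)
    grid[idx] = xyz
    have[idx] = True
    # hold last sample across (short) gaps
    if not have.all():
        last = np.maximum.accumulate(np.where(have, np.arange(n), 0))
        grid = grid[last]
    pid = meta.participant_id if meta is not None else Path(path).stem
    return RawRecording(pid, pd.Timestamp(t0), float(rate), grid, dynamic_range_g)


def write_raw_recording(rec: RawRecording, path: str | Path) -> None:
    """Write a recording in the raw CSV dialect (intended for small files)."""
    times = rec.sample_times()
    df = pd.DataFrame(
        {
            "time": times.strftime("%Y-%m-%dT%H:%M:%S.%f"),
            "x": rec.samples[:, 0],
            "y": rec.samples[:, 1],
            "z": rec.samples[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def write_epoch_series(es, path: str | Path) -> None:
    """Write an epoch series CSV (lossless round-trip of all fields)."""
    df = pd.DataFrame(
        {
            "epoch_start": pd.DatetimeIndex(es.epoch_start).strftime("%Y-%m-%dT%H:%M:%S"),
            "enmo_mg": es.enmo_mg,
            "steps": es.steps.astype(int),
            "wear": es.wear.astype(int),
            "z_angle_deg": es.z_angle_deg,
            "sleep": es.sleep.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.9f")


def read_epoch_series(path: str | Path):
    from .epoching import EpochSeries  # local import to avoid a module cycle

    df = pd.read_csv(path)
    required = ["epoch_start", "enmo_mg", "steps", "wear", "z_angle_deg"]
    if list(df.columns[: len(required)]) != required:
        raise ValueError(f"epoch CSV must start with columns {required}")
    sleep = df["sleep"].to_numpy(bool) if "sleep" in df.columns else np.zeros(len(df), bool)
    return EpochSeries(
        epoch_start=pd.DatetimeIndex(pd.to_datetime(df["epoch_start"])),
        enmo_mg=df["enmo_mg"].to_numpy(float),
        z_angle_deg=df["z_angle_deg"].to_numpy(float),
        wear=df["wear"].to_numpy(bool),
        steps=df["steps"].to_numpy(np.int64),
        sleep=sleep,
    )


def slice_days(rec: RawRecording, pci_date: pd.Timestamp | None = None) -> list[DaySegment]:
    """Partition a recording at local-midnight boundaries.

    Segments are disjoint, ordered, and concatenate back to the input.
    ``day_index`` counts calendar days relative to ``pci_date`` (day 0);
    without a reference date it counts from the recording's first day.
    """
    start = rec.start_time
    first_midnight = start.normalize()
    ref = pd.Timestamp(pci_date).normalize() if pci_date is not None else first_midnight
    segments: list[DaySegment] = []
    day = first_midnight
    ns_per_sample = 1e9 / rec.sample_rate_hz
    while True:
        nxt = day + pd.Timedelta(days=1)
        # sample i falls in [day, nxt) iff start + i/rate in that window
        lo = max(0, int(np.ceil(((day - start).value - 1e-6) / ns_per_sample)))
        hi = min(rec.n_samples, int(np.ceil(((nxt - start).value - 1e-6) / ns_per_sample)))
        if lo >= rec.n_samples:
            break
        if hi > lo:
            seg_start = start + pd.Timedelta(nanoseconds=round(lo * ns_per_sample))
            seg = RawRecording(
                rec.participant_id,
                seg_start,
                rec.sample_rate_hz,
                rec.samples[lo:hi],
                rec.dynamic_range_g,
            )
            segments.append(DaySegment(int((day - ref).days), seg))
        day = nxt
    return segments
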