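"""Pipeline configuration.

Every tunable constant of the processing chain lives here so that a single
:class:`PipelineConfig` object fully determines the behaviour of the
pipeline.  Values the underlying publications print (5-s epochs, 25/100 mg
intensity cut-points, 60/15-min non-wear window geometry, 10-min/80% bout
criterion, 12-h valid-day rule) are defaults that should rarely change;
values the literature leaves open (non-wear axis vote, sleep heuristic
constants, step-detector parameters) are deliberate decisions and are all
exposed for sensitivity analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Standard gravity in milli-g; ENMO thresholds are expressed in mg.
MG_PER_G = 1000.0

#: Epoch length (seconds) for all aggregated series.
EPOCH_S = 5

#: Epochs per minute / per day at 5-s resolution.
EPOCHS_PER_MIN = 60 // EPOCH_S
EPOCHS_PER_DAY = 86400 // EPOCH_S

# ---------------------------------------------------------------------------
# Synthetic gait waveform constants (frozen; see docs/methods.md).
#
# The generated walking signal modulates the magnitude of gravity as
# 1 + A * w(theta) with w(theta) = sin(theta) + GAIT_HARMONIC * sin(2*theta),
# one gait cycle per step.  The positive part of w integrates to 1/pi per
# cycle (the first harmonic integrates to zero over the positive half-wave),
# so the noiseless epoch ENMO is exactly A / pi (in g).  A is
# GAIT_AMP_SCALE * peak_amp_g; the scale is frozen so that peak_amp_g = 0.3
# lands at ~110 mg, safely above the 100 mg MVPA cut-point.
# ---------------------------------------------------------------------------
GAIT_HARMONIC = 0.3
GAIT_AMP_SCALE = 1.15


def expected_walk_enmo_mg(peak_amp_g: float) -> float:
    """Closed-form noiseless epoch ENMO (mg) of a generated walk block."""
    return GAIT_AMP_SCALE * peak_amp_g * MG_PER_G / math.pi


@dataclass
class IntensityBands:
    """ENMO intensity cut-points in mg (inactive < 25 <= light < 100 <= MVPA)."""

    inactive_max_mg: float = 25.0
    mvpa_min_mg: float = 100.0
    vigorous_min_mg: float = 400.0

    def __post_init__(self) -> None:
        if not 0 < self.inactive_max_mg < self.mvpa_min_mg <= self.vigorous_min_mg:
            raise ValueError("intensity bands must be ordered 0 < inactive < mvpa <= vigorous")


@dataclass
class NonwearParams:
    """Windowed non-wear vote: 60-min windows advanced in 15-min steps."""

    window_min: int = 60
    slide_min: int = 15
    sd_mg: float = 13.0
    range_mg: float = 50.0
    min_axes: int = 2  # axes that must look still for a window to vote non-wear


@dataclass
class SleepParams:
    """Z-angle heuristic for the nightly sleep period (noon-to-noon search)."""

    block_min: int = 5            # z-angle successive-difference block (minutes)
    threshold_factor: float = 15.0  # multiplies the 10th percentile of block values
    threshold_floor_deg: float = 0.1
    threshold_cap_deg: float = 15.0
    percentile: float = 10.0
    merge_gap_min: int = 60       # merge inactivity runs separated by < this
    min_period_min: int = 30      # shortest admissible sleep period


@dataclass
class BoutParams:
    """MVPA bout criterion: >=10 min with >=80% of 5-s epochs above threshold."""

    min_duration_min: int = 10
    criterion_fraction: float = 0.8
    max_gap_epochs: int = 12      # longest tolerated below-threshold run inside a bout

    @property
    def min_duration_epochs(self) -> int:
        return self.min_duration_min * EPOCHS_PER_MIN


@dataclass
class StepDetectorParams:
    """Windowed peak detection on the resampled acceleration magnitude."""

    resample_hz: float = 15.0
    peak_window_samples: int = 3
    magnitude_min_g: float = 1.2
    period_min_samples: int = 5
    period_max_samples: int = 15
    similarity_max_g: float = 0.5
    continuity_window: int = 3
    continuity_min_peaks: int = 4
    variance_min_g2: float = 0.001

    def __post_init__(self) -> None:
        if self.period_min_samples >= self.period_max_samples:
            raise ValueError("period_min_samples must be < period_max_samples")


@dataclass
class CalibrationParams:
    """Autocalibration against local gravity on still windows."""

    still_window_s: float = 10.0
    still_sd_mg: float = 13.0
    min_axis_range_g: float = 0.3   # orientation-coverage guard
    max_iter: int = 1000
    tol_mg: float = 0.001
    gain_bounds: tuple[float, float] = (0.9, 1.1)


@dataclass
class ValidityParams:
    """Valid-day and participant-inclusion rules."""

    min_wear_h: float = 12.0
    first_day: int = 2            # days counted as of day 2 after the intervention
    min_valid_days: int = 7


@dataclass
class AdherenceThresholds:
    """The four physical-activity criteria (all boundaries inclusive)."""

    mvpa_min_per_day: float = 30.0
    steps_7500: float = 7500.0
    steps_10000: float = 10000.0


@dataclass
class PipelineConfig:
    bands: IntensityBands = field(default_factory=IntensityBands)
    nonwear: NonwearParams = field(default_factory=NonwearParams)
    sleep: SleepParams = field(default_factory=SleepParams)
    bout: BoutParams = field(default_factory=BoutParams)
    steps: StepDetectorParams = field(default_factory=StepDetectorParams)
    calibration: CalibrationParams = field(default_factory=CalibrationParams)
    validity: ValidityParams = field(default_factory=ValidityParams)
    adherence: AdherenceThresholds = field(default_factory=AdherenceThresholds)
    accrual_mode: str = "epoch"   # or "minute80"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sections = {
            "bands": IntensityBands,
            "nonwear": NonwearParams,
            "sleep": SleepParams,
            "bout": BoutParams,
            "steps": StepDetectorParams,
            "calibration": CalibrationParams,
            "validity": ValidityParams,
            "adherence": AdherenceThresholds,
        }
        kwargs = {}
        for key, klass in sections.items():
            if key in raw:
                val = raw[key]
                if key == "calibration" and "gain_bounds" in val:
                    val["gain_bounds"] = tuple(val["gain_bounds"])
                kwargs[key] = klass(**val)
        if "accrual_mode" in raw:
            kwargs["accrual_mode"] = raw["accrual_mode"]
        return cls(**kwargs)


DEFAULT_CONFIG = PipelineConfig()
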