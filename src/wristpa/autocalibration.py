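"""Per-axis gain/offset autocalibration against local gravity.

During still wear the acceleration vector should sit on the unit sphere
(|a| = 1 g).  Device miscalibration (per-axis offset and gain drift) moves
still points off the sphere; the calibration model is estimated by an
iteratively re-fit per-axis linear map pulling each still point toward its
projection on the sphere, and applied as the exact inverse of the device
distortion: a' = (a − offset) / gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import MG_PER_G, CalibrationParams
from .signal_io import RawRecording

__all__ = [
    "CalibrationModel",
    "find_still_points",
    "estimate_calibration",
    "apply_calibration",
    "calibrate_recording",
]


@dataclass
class CalibrationModel:
    offset_g: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gain: np.ndarray = field(default_factory=lambda: np.ones(3))
    error_before_mg: float = float("nan")
    error_after_mg: float = float("nan")
    n_still_points: int = 0
    converged: bool = False

    def __post_init__(self) -> None:
        self.offset_g = np.asarray(self.offset_g, dtype=float)
        self.gain = np.asarray(self.gain, dtype=float)

    @property
    def is_identity(self) -> bool:
        return bool(np.all(self.offset_g == 0) and np.all(self.gain == 1))


def find_still_points(
    rec: RawRecording, params: CalibrationParams | None = None
) -> np.ndarray:
    """Mean vectors of non-overlapping windows whose per-axis SDs are all small.

    Returns an (m, 3) array, possibly empty.
    """
    p = params or CalibrationParams()
    wlen = int(round(p.still_window_s * rec.sample_rate_hz))
    n_win = rec.n_samples // wlen
    if n_win == 0:
        return np.empty((0, 3))
    data = rec.samples[: n_win * wlen].reshape(n_win, wlen, 3)
    means = data.mean(axis=1, dtype=np.float64)
    sumsq = np.einsum("ijk,ijk->ik", data, data, dtype=np.float64)
    var = np.maximum(sumsq / wlen - means**2, 0.0)
    sd_mg = np.sqrt(var) * MG_PER_G
    still = np.all(sd_mg < p.still_sd_mg, axis=1)
    return means[still]


def estimate_calibration(
    still_points: np.ndarray, params: CalibrationParams | None = None
) -> CalibrationModel:
    """Sphere-fit calibration from still-point mean vectors.

    Iterates a per-axis linear regression of each point's unit-sphere
    projection on the point itself until the mean residual changes by less
    than ``tol_mg``.  When the points span fewer than three distinct
    orientations (per-axis value range below ``min_axis_range_g`` on any
    axis) the geometry is ill-posed and the identity model is returned
    with ``converged=False``.
    """
    p = params or CalibrationParams()
    pts = np.asarray(still_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] == 0:
        raise ValueError("still_points must be a non-empty (m, 3) array")
    err_before = float(np.mean(np.abs(np.linalg.norm(pts, axis=1) - 1.0))) * MG_PER_G

    model = CalibrationModel(error_before_mg=err_before, error_after_mg=err_before,
                             n_still_points=pts.shape[0])
    ranges = pts.max(axis=0) - pts.min(axis=0)
    if np.any(ranges < p.min_axis_range_g):
        return model

    offset = np.zeros(3)
    gain = np.ones(3)
    prev_err = err_before
    converged = False
    for _ in range(p.max_iter):
        cal = (pts - offset) / gain
        norms = np.linalg.norm(cal, axis=1)
        target = cal / norms[:, None]
        # per-axis LS fit target_i ≈ alpha_i + beta_i * cal_i
        for ax in range(3):
            x = cal[:, ax]
            y = target[:, ax]
            xm, ym = x.mean(), y.mean()
            denom = float(np.sum((x - xm) ** 2))
            if denom <= 0:
                return CalibrationModel(error_before_mg=err_before,
                                        error_after_mg=err_before,
                                        n_still_points=pts.shape[0])
            beta = float(np.sum((x - xm) * (y - ym))) / denom
            alpha = ym - beta * xm
            # compose: new_cal = alpha + beta*(p-off)/gain = (p - off')/gain'
            gain[ax] = gain[ax] / beta
            offset[ax] = offset[ax] - alpha * gain[ax]
        err = float(np.mean(np.abs(
            np.linalg.norm((pts - offset) / gain, axis=1) - 1.0))) * MG_PER_G
        if abs(prev_err - err) < p.tol_mg:
            converged = True
            prev_err = err
            break
        prev_err = err

    lo, hi = p.gain_bounds
    if not converged or np.any(gain <= lo) or np.any(gain >= hi) or prev_err > err_before:
        return CalibrationModel(error_before_mg=err_before, error_after_mg=err_before,
                                n_still_points=pts.shape[0])
    return CalibrationModel(
        offset_g=offset,
        gain=gain,
        error_before_mg=err_before,
        error_after_mg=prev_err,
        n_still_points=pts.shape[0],
        converged=True,
    )


def apply_calibration(rec: RawRecording, model: CalibrationModel) -> RawRecording:
    """a' = (a − offset) / gain per axis; identity model returns the input."""
    if model.is_identity:
        return rec
    dtype = rec.samples.dtype
    corrected = ((rec.samples.astype(np.float64, copy=False) - model.offset_g)
                 / model.gain).astype(dtype)
    np.clip(corrected, -rec.dynamic_range_g, rec.dynamic_range_g, out=corrected)
    return RawRecording(rec.participant_id, rec.start_time, rec.sample_rate_hz,
                        corrected, rec.dynamic_range_g)


def calibrate_recording(
    rec: RawRecording, params: CalibrationParams | None = None
) -> tuple[RawRecording, CalibrationModel]:
    """Estimate and apply the calibration for one recording (per participant)."""
    pts = find_still_points(rec, params)
    if pts.shape[0] == 0:
        return rec, CalibrationModel()
    model = estimate_calibration(pts, params)
    return apply_calibration(rec, model), model
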