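"""End-to-end processing: raw recording → epoch series → day summaries.

Order of operations per participant: autocalibrate against still gravity,
compute per-sample ENMO, aggregate to the 5-s epoch grid, vote non-wear,
detect steps and assign them to epochs, find the nightly sleep period,
then cut midnight-to-midnight days (padded with non-wear at the recording
edges) and compute every day-level metric.  Cross-day imputation for the
24-h mean acceleration uses the participant's other ≥12-h-wear days as
donors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .activity_metrics import DaySummary, summarize_day_activity
from .autocalibration import CalibrationModel, calibrate_recording
from .config import EPOCH_S, EPOCHS_PER_DAY, PipelineConfig
from .epoching import EpochSeries, aggregate_epochs, compute_enmo, detect_nonwear, detect_sleep_period
from .signal_io import ParticipantMeta, RawRecording
from .step_cadence import cadence_summary, detect_steps, minute_cadence, steps_to_epochs

__all__ = ["process_recording", "day_summaries_frame"]


def _day_matrices(es: EpochSeries):
    """Pad each calendar day to the full 17,280-epoch grid (non-wear padding)."""
    days = es.epoch_start.normalize()
    uniq = days.unique().sort_values()
    n_days = len(uniq)
    enmo = np.zeros((n_days, EPOCHS_PER_DAY))
    wear = np.zeros((n_days, EPOCHS_PER_DAY), bool)
    sleep = np.zeros((n_days, EPOCHS_PER_DAY), bool)
    steps = np.zeros((n_days, EPOCHS_PER_DAY), np.int64)
    for d, day in enumerate(uniq):
        sel = np.flatnonzero(days == day)
        off = int((es.epoch_start[sel[0]] - day).total_seconds()) // EPOCH_S
        sl = slice(off, off + len(sel))
        enmo[d, sl] = es.enmo_mg[sel]
        wear[d, sl] = es.wear[sel]
        sleep[d, sl] = es.sleep[sel]
        steps[d, sl] = es.steps[sel]
    return uniq, enmo, wear, sleep, steps


def process_recording(
    rec: RawRecording,
    meta: ParticipantMeta | None = None,
    config: PipelineConfig | None = None,
) -> tuple[EpochSeries, list[DaySummary], CalibrationModel]:
    """Process one participant's raw recording into day summaries."""
    cfg = config or PipelineConfig()
    rec, model = calibrate_recording(rec, cfg.calibration)
    enmo = compute_enmo(rec)
    es = aggregate_epochs(rec, enmo)
    es.wear = detect_nonwear(rec, es, cfg.nonwear)
    step_times = detect_steps(rec, cfg.steps)
    es.steps = steps_to_epochs(step_times, rec, es)
    es.sleep, _ = detect_sleep_period(es, cfg.sleep)

    pid = meta.participant_id if meta is not None else rec.participant_id
    ref = meta.pci_date if meta is not None else es.epoch_start[0].normalize()
    uniq, enmo_m, wear_m, sleep_m, steps_m = _day_matrices(es)

    wear_hours = wear_m.sum(axis=1) / (3600 // EPOCH_S)
    valid = wear_hours >= cfg.validity.min_wear_h
    wsum = (enmo_m * wear_m)[valid].sum(axis=0)
    wcnt = wear_m[valid].sum(axis=0).astype(float)

    summaries: list[DaySummary] = []
    for d, day in enumerate(uniq):
        day_index = int((day - ref).days)
        donor = None
        if valid[d]:
            cnt = wcnt - wear_m[d]
            with np.errstate(invalid="ignore", divide="ignore"):
                donor = (wsum - enmo_m[d] * wear_m[d]) / cnt
            donor[cnt <= 0] = np.nan
        summary = summarize_day_activity(
            pid, day_index, enmo_m[d], wear_m[d], sleep_m[d], cfg, donor_mean_mg=donor
        )
        if not valid[d]:
            summary.mean_acc_mg = float("nan")
        cad = cadence_summary(minute_cadence(steps_m[d]))
        summary.steps = cad.steps
        summary.mean_cadence_spm = cad.mean_cadence_spm
        summary.cad100_min = cad.cad100_min
        summary.pct_zero_cadence = cad.pct_zero_cadence
        summary.peak1_cad = cad.peak1_cad
        summary.peak30_cad = cad.peak30_cad
        summary.peak60_cad = cad.peak60_cad
        summaries.append(summary)
    return es, summaries, model


def day_summaries_frame(summaries: list[DaySummary]) -> pd.DataFrame:
    """Day summaries as one row per participant-day."""
    return pd.DataFrame([vars(s) for s in summaries])
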