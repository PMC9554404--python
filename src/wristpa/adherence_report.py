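"""Participant inclusion, adherence classification, and cohort outputs.

A day is valid when worn ≥12 h and on or after day 2 of the observation
clock (the intervention is day 0).  Participants need ≥7 valid days;
their activity profile is the arithmetic mean of each metric over valid
days.  Four criteria are classified with inclusive boundaries:

* 2020 guideline — mean MVPA ≥ 30 min/day, any bout length;
* 2010 guideline — mean MVPA in ≥10-min bouts ≥ 30 min/day;
* ≥ 7,500 steps/day and ≥ 10,000 steps/day.

Cohort outputs are text tables: group medians (Q1, Q3) per metric,
subgroup prevalences with chi-square / Fisher tests, the per-day adherence
curve, the MVPA-vs-steps and MVPA-vs-cadence regressions, and the
criterion set counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .activity_metrics import METRIC_COLUMNS
from .config import AdherenceThresholds, ValidityParams
from .signal_io import ParticipantMeta

__all__ = [
    "ParticipantSummary",
    "select_valid_days",
    "summarize_participant",
    "classify_adherence",
    "participants_frame",
    "daily_adherence_curve",
    "subgroup_prevalence",
    "regress_metrics",
    "cohort_report",
]

CRITERIA = ["who2020", "who2010", "steps7500", "steps10000"]


@dataclass
class ParticipantSummary:
    participant_id: str
    meta: ParticipantMeta | None
    n_valid_days: int
    included: bool
    means: pd.Series          # mean of every day metric over valid days
    flags: dict[str, bool] | None


def select_valid_days(
    days: pd.DataFrame, validity: ValidityParams | None = None
) -> pd.DataFrame:
    """Keep days with wear ≥ min_wear_h and day_index ≥ first_day."""
    v = validity or ValidityParams()
    mask = (days["wear_hours"] >= v.min_wear_h) & (days["day_index"] >= v.first_day)
    return days.loc[mask]


def summarize_participant(
    valid_days: pd.DataFrame,
    meta: ParticipantMeta | None = None,
    validity: ValidityParams | None = None,
    thresholds: AdherenceThresholds | None = None,
) -> ParticipantSummary:
    """Arithmetic mean per metric over valid days; inclusion needs ≥7 of them."""
    v = validity or ValidityParams()
    n = len(valid_days)
    included = n >= v.min_valid_days
    pid = (meta.participant_id if meta is not None
           else (valid_days["participant_id"].iloc[0] if n else "unknown"))
    if n == 0:
        means = pd.Series(np.nan, index=METRIC_COLUMNS)
    else:
        means = valid_days[METRIC_COLUMNS].mean()
    ps = ParticipantSummary(pid, meta, n, included, means, None)
    if included:
        ps.flags = classify_adherence(ps, thresholds)
    return ps


def classify_adherence(
    ps: ParticipantSummary, thresholds: AdherenceThresholds | None = None
) -> dict[str, bool]:
    """The four adherence flags (boundaries inclusive); included participants only."""
    if not ps.included:
        raise ValueError("adherence is defined only for included participants")
    t = thresholds or AdherenceThresholds()
    m = ps.means
    return {
        "who2020": bool(m["mvpa_min"] >= t.mvpa_min_per_day),
        "who2010": bool(m["mvpa_bout10_min"] >= t.mvpa_min_per_day),
        "steps7500": bool(m["steps"] >= t.steps_7500),
        "steps10000": bool(m["steps"] >= t.steps_10000),
    }


def participants_frame(summaries: list[ParticipantSummary]) -> pd.DataFrame:
    """One row per participant: metadata, mean metrics, adherence flags."""
    rows = []
    for ps in summaries:
        row: dict = {"participant_id": ps.participant_id,
                     "n_valid_days": ps.n_valid_days, "included": ps.included}
        if ps.meta is not None:
            row.update(age_years=ps.meta.age_years, sex=ps.meta.sex,
                       presentation=ps.meta.presentation)
        row.update(ps.means.to_dict())
        for c in CRITERIA:
            row[c] = ps.flags[c] if ps.flags is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def daily_adherence_curve(
    days: pd.DataFrame,
    validity: ValidityParams | None = None,
    thresholds: AdherenceThresholds | None = None,
) -> pd.DataFrame:
    """Fraction of participants fulfilling each criterion on each single day.

    Day-level adherence conditions on the day being valid (≥12 h wear);
    day indices before ``first_day`` are dropped.  Fractions are NaN where
    no participant has a valid day.
    """
    t = thresholds or AdherenceThresholds()
    valid = select_valid_days(days, validity)
    if valid.empty:
        return pd.DataFrame(columns=["n"] + CRITERIA).rename_axis("day_index")
    flags = pd.DataFrame(
        {
            "day_index": valid["day_index"],
            "who2020": valid["mvpa_min"] >= t.mvpa_min_per_day,
            "who2010": valid["mvpa_bout10_min"] >= t.mvpa_min_per_day,
            "steps7500": valid["steps"] >= t.steps_7500,
            "steps10000": valid["steps"] >= t.steps_10000,
        }
    )
    grouped = flags.groupby("day_index")
    out = grouped[CRITERIA].mean()
    out.insert(0, "n", grouped.size())
    return out


def _two_by_two_test(table: np.ndarray) -> tuple[str, float]:
    """Pearson chi-square, or Fisher's exact when any expected cell < 5."""
    table = np.asarray(table)
    if table.sum() == 0 or (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        return "none", float("nan")
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        return "fisher", float(stats.fisher_exact(table)[1])
    chi2 = stats.chi2_contingency(table, correction=False)
    return "chi2", float(chi2.pvalue)


def subgroup_prevalence(participants: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Adherence prevalence per subgroup with a two-sided between-group test.

    ``grouping`` is one of ``age`` (median split of the included cohort),
    ``sex``, or ``presentation``.
    """
    df = participants.loc[participants["included"]].copy()
    if df.empty:
        raise ValueError("no included participants")
    if grouping == "age":
        cut = float(df["age_years"].median())
        df["group"] = np.where(df["age_years"] < cut, f"age<{cut:g}", f"age>={cut:g}")
    elif grouping in ("sex", "presentation"):
        df["group"] = df[grouping]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    levels = sorted(df["group"].unique())
    rows = []
    for crit in CRITERIA:
        row: dict = {"criterion": crit}
        for lv in levels:
            sub = df.loc[df["group"] == lv, crit].astype(bool)
            row[f"n_{lv}"] = int(sub.sum())
            row[f"total_{lv}"] = len(sub)
            row[f"pct_{lv}"] = 100.0 * sub.mean() if len(sub) else float("nan")
        if len(levels) == 2:
            a = df.loc[df["group"] == levels[0], crit].astype(bool)
            b = df.loc[df["group"] == levels[1], crit].astype(bool)
            table = np.array([[a.sum(), len(a) - a.sum()], [b.sum(), len(b) - b.sum()]])
            row["test"], row["p_value"] = _two_by_two_test(table)
        rows.append(row)
    return pd.DataFrame(rows).set_index("criterion")


DEFAULT_REGRESSION_PAIRS = (
    ("mvpa_min", "steps"),
    ("mvpa_bout10_min", "steps"),
    ("mvpa_min", "peak30_cad"),
    ("mvpa_bout10_min", "peak30_cad"),
)


def regress_metrics(participants: pd.DataFrame, pairs=DEFAULT_REGRESSION_PAIRS) -> pd.DataFrame:
    """OLS of participant-mean MVPA (both definitions) on steps and peak-30 cadence.

    Reports slope, intercept, r, R², standard errors, and the predictor
    value where the fitted line crosses 30 min/day of MVPA (NaN when the
    slope is not positive).
    """
    df = participants.loc[participants["included"]]
    if len(df) < 3:
        raise ValueError("regression needs at least 3 included participants")
    rows = []
    for y, x in pairs:
        xv = df[x].to_numpy(float)
        yv = df[y].to_numpy(float)
        if np.ptp(xv) == 0:
            raise ValueError(f"zero variance in predictor {x!r}")
        fit = stats.linregress(xv, yv)
        x_at_30 = (30.0 - fit.intercept) / fit.slope if fit.slope > 0 else float("nan")
        rows.append(
            {
                "response": y,
                "predictor": x,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r": fit.rvalue,
                "r_squared": fit.rvalue**2,
                "slope_se": fit.stderr,
                "intercept_se": fit.intercept_stderr,
                "p_value": fit.pvalue,
                "x_at_30min": x_at_30,
                "n": len(df),
            }
        )
    return pd.DataFrame(rows)


def _median_q1_q3(s: pd.Series) -> tuple[float, float, float]:
    # linear-interpolation quartile convention
    return tuple(np.nanpercentile(s.to_numpy(float), [50, 25, 75]))


def cohort_report(
    participants: pd.DataFrame, days: pd.DataFrame,
    validity: ValidityParams | None = None,
    thresholds: AdherenceThresholds | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble the cohort tables.

    ``table1``: median (Q1, Q3) per metric for all included participants
    and for each adherent subgroup.  ``table2``: subgroup prevalences.
    ``fig2_curve``: per-day fulfilment fractions.  ``fig3_regressions``:
    the OLS table.  ``fig4_sets``: adherent counts per criterion plus
    pairwise overlaps with the 2020 criterion.
    """
    inc = participants.loc[participants["included"]]
    groups = {"all": inc}
    for crit in CRITERIA:
        groups[crit] = inc.loc[inc[crit].astype(bool)]
    t1_rows = []
    for metric in METRIC_COLUMNS:
        row: dict = {"metric": metric}
        for name, g in groups.items():
            if len(g):
                med, q1, q3 = _median_q1_q3(g[metric])
            else:
                med = q1 = q3 = float("nan")
            row[f"{name}_median"] = med
            row[f"{name}_q1"] = q1
            row[f"{name}_q3"] = q3
        t1_rows.append(row)
    table1 = pd.DataFrame(t1_rows).set_index("metric")

    t2 = []
    for grouping in ("age", "sex", "presentation"):
        try:
            sub = subgroup_prevalence(participants, grouping).reset_index()
            sub.insert(0, "grouping", grouping)
            t2.append(sub)
        except ValueError:
            continue
    table2 = pd.concat(t2, ignore_index=True) if t2 else pd.DataFrame()

    n_inc = len(inc)
    sets = []
    for crit in CRITERIA:
        flags = inc[crit].astype(bool)
        both2020 = (flags & inc["who2020"].astype(bool)).sum()
        sets.append(
            {
                "criterion": crit,
                "n_adherent": int(flags.sum()),
                "pct_adherent": 100.0 * flags.mean() if n_inc else float("nan"),
                "n_also_who2020": int(both2020),
                "n_included": n_inc,
            }
        )
    try:
        regressions = regress_metrics(participants)
    except ValueError:  # too few participants or a degenerate predictor
        regressions = pd.DataFrame()
    return {
        "table1": table1,
        "table2": table2,
        "fig2_curve": daily_adherence_curve(days, validity, thresholds),
        "fig3_regressions": regressions,
        "fig4_sets": pd.DataFrame(sets).set_index("criterion"),
    }
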