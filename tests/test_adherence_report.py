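"""Valid days, participant means, adherence flags, cohort statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wristpa import adherence_report as ar
from wristpa.activity_metrics import METRIC_COLUMNS
from wristpa.config import ValidityParams
from wristpa.signal_io import ParticipantMeta


def make_days(pid="P0", n=10, first_index=2, wear=16.0, **metrics):
    rows = []
    for k in range(n):
        row = {c: 0.0 for c in METRIC_COLUMNS}
        row.update(participant_id=pid, day_index=first_index + k, wear_hours=wear)
        row.update(metrics)
        rows.append(row)
    return pd.DataFrame(rows)


def meta(pid="P0", age=60.0, sex="male", pres="ACS"):
    return ParticipantMeta(pid, age, sex, pres, pd.Timestamp("2021-03-01"))


class TestValidDays:
    def test_low_wear_excluded(self):
        days = make_days(n=3)
        days.loc[1, "wear_hours"] = 11.9
        assert len(ar.select_valid_days(days)) == 2

    def test_day_one_excluded(self):
        days = make_days(n=3, first_index=1, wear=16.0)
        out = ar.select_valid_days(days)
        assert out["day_index"].min() == 2

    def test_full_wear_span_counts(self):
        days = make_days(n=17, first_index=2)
        assert len(ar.select_valid_days(days)) == 17


class TestParticipantSummary:
    def test_six_valid_days_not_included(self):
        days = make_days(n=6)
        ps = ar.summarize_participant(days, meta())
        assert not ps.included and ps.flags is None

    def test_identical_days_mean(self):
        days = make_days(n=8, mvpa_min=45.0, steps=9000.0)
        ps = ar.summarize_participant(days, meta())
        assert ps.included
        assert ps.means["mvpa_min"] == 45.0
        assert ps.means["steps"] == 9000.0

    def test_means_match_brute_force(self, rng):
        days = make_days(n=9)
        days["mvpa_min"] = rng.uniform(0, 90, 9)
        days["steps"] = rng.uniform(2000, 15000, 9)
        ps = ar.summarize_participant(days, meta())
        assert ps.means["mvpa_min"] == pytest.approx(days["mvpa_min"].mean())
        assert ps.means["steps"] == pytest.approx(days["steps"].mean())

    def test_zero_valid_days(self):
        ps = ar.summarize_participant(make_days(n=0), meta())
        assert not ps.included and ps.n_valid_days == 0


class TestClassification:
    def test_typical_cohort_median_profile(self):
        # mean MVPA 57 min but only 7.1 bouted: 2020 yes, 2010 no
        days = make_days(n=8, mvpa_min=57.0, mvpa_bout10_min=7.1, steps=10463.0)
        ps = ar.summarize_participant(days, meta())
        assert ps.flags == {
            "who2020": True, "who2010": False,
            "steps7500": True, "steps10000": True,
        }

    def test_inclusive_boundary(self):
        days = make_days(n=8, mvpa_min=30.0, mvpa_bout10_min=30.0, steps=7500.0)
        ps = ar.summarize_participant(days, meta())
        assert ps.flags["who2010"] and ps.flags["who2020"] and ps.flags["steps7500"]
        assert not ps.flags["steps10000"]

    def test_flag_monotonicity(self, rng):
        for _ in range(20):
            days = make_days(n=8, steps=float(rng.uniform(0, 15000)))
            ps = ar.summarize_participant(days, meta())
            if ps.flags["steps10000"]:
                assert ps.flags["steps7500"]

    def test_excluded_participant_rejected(self):
        ps = ar.summarize_participant(make_days(n=3), meta())
        with pytest.raises(ValueError):
            ar.classify_adherence(ps)


class TestDailyCurve:
    def test_uniform_cohort_all_adherent(self):
        days = pd.concat(
            [make_days(pid=f"P{i}", n=5, mvpa_min=40.0, mvpa_bout10_min=40.0,
                       steps=12000.0) for i in range(4)],
            ignore_index=True,
        )
        curve = ar.daily_adherence_curve(days)
        assert (curve["who2010"] == 1.0).all()
        assert (curve["n"] == 4).all()

    def test_fractions_match_brute_force(self, rng):
        days = pd.concat(
            [make_days(pid=f"P{i}", n=6) for i in range(10)], ignore_index=True
        )
        days["mvpa_min"] = rng.uniform(0, 60, len(days))
        days["wear_hours"] = rng.uniform(10, 20, len(days))
        curve = ar.daily_adherence_curve(days)
        for d in curve.index:
            sel = days[(days["day_index"] == d) & (days["wear_hours"] >= 12)]
            assert curve.loc[d, "who2020"] == pytest.approx(
                (sel["mvpa_min"] >= 30).mean())

    def test_no_valid_days_absent_from_curve(self):
        days = make_days(n=3, wear=5.0)
        assert ar.daily_adherence_curve(days).empty


def _participants(flags_a, flags_b, group_col, a_label, b_label):
    rows = []
    for i, f in enumerate(flags_a):
        rows.append({"participant_id": f"A{i}", "included": True, "age_years": 50.0,
                     "sex": "male", "presentation": "ACS",
                     group_col: a_label, "who2020": f, "who2010": f,
                     "steps7500": f, "steps10000": f})
    for i, f in enumerate(flags_b):
        rows.append({"participant_id": f"B{i}", "included": True, "age_years": 70.0,
                     "sex": "female", "presentation": "CCS",
                     group_col: b_label, "who2020": f, "who2010": f,
                     "steps7500": f, "steps10000": f})
    return pd.DataFrame(rows)


class TestSubgroups:
    def test_percentages(self):
        flags_a = [True] * 4 + [False] * 41       # 4/45 = 8.9%
        flags_b = [True] * 121 + [False] * 20     # 121/141 = 85.8%
        df = _participants(flags_a, flags_b, "sex", "male", "female")
        out = ar.subgroup_prevalence(df, "sex")
        assert out.loc["who2010", "pct_male"] == pytest.approx(8.9, abs=0.05)
        assert out.loc["who2020", "pct_female"] == pytest.approx(85.8, abs=0.05)

    def test_identical_proportions_p_one(self):
        flags = [True] * 10 + [False] * 10
        df = _participants(flags, flags, "presentation", "ACS", "CCS")
        out = ar.subgroup_prevalence(df, "presentation")
        assert out["p_value"].tolist() == pytest.approx([1.0] * 4)

    def test_chi2_matches_permutation(self, rng):
        """Chi-square p agrees with a permutation test on random 2x2 tables."""
        for _ in range(5):
            na, nb = int(rng.integers(30, 80)), int(rng.integers(30, 80))
            pa, pb = rng.uniform(0.2, 0.8, 2)
            fa = rng.random(na) < pa
            fb = rng.random(nb) < pb
            table = np.array([[fa.sum(), na - fa.sum()], [fb.sum(), nb - fb.sum()]])
            if (stats.contingency.expected_freq(table) < 5).any():
                continue
            p_chi = stats.chi2_contingency(table, correction=False).pvalue
            # permutation reference (mid-p: half weight on ties, the
            # convention that matches the continuous asymptotic null)
            pooled = np.concatenate([fa, fb])
            obs = abs(fa.mean() - fb.mean())
            greater = ties = 0
            n_perm = 10_000
            for _ in range(n_perm):
                rng.shuffle(pooled)
                d = abs(pooled[:na].mean() - pooled[na:].mean())
                if d > obs + 1e-12:
                    greater += 1
                elif d > obs - 1e-12:
                    ties += 1
            p_perm = (greater + 0.5 * ties) / n_perm
            assert abs(p_chi - p_perm) < 0.01 + 0.05 * p_chi

    def test_age_median_split(self):
        df = _participants([True] * 5, [False] * 5, "ignored", "x", "y")
        out = ar.subgroup_prevalence(df, "age")
        assert out.filter(like="total_").iloc[0].sum() == 10


class TestRegression:
    def _frame(self, x, y):
        df = pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(len(x))],
            "included": True, "steps": x, "mvpa_min": y,
            "mvpa_bout10_min": y, "peak30_cad": x / 100.0,
        })
        return df

    def test_exact_line(self):
        x = np.linspace(2000, 18000, 30)
        y = 0.004 * x - 10.0
        out = ar.regress_metrics(self._frame(x, y))
        row = out[(out.response == "mvpa_min") & (out.predictor == "steps")].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["x_at_30min"] == pytest.approx(10_000.0)

    def test_zero_variance_predictor(self):
        with pytest.raises(ValueError, match="variance"):
            ar.regress_metrics(self._frame(np.full(10, 5000.0), np.arange(10.0)))

    def test_parameter_recovery_within_2se(self, rng):
        n = 200
        x = rng.uniform(2000, 16000, n)
        y = 0.005 * x - 5 + rng.normal(0, 8, n)
        out = ar.regress_metrics(self._frame(x, y))
        row = out[(out.response == "mvpa_min") & (out.predictor == "steps")].iloc[0]
        assert abs(row["slope"] - 0.005) <= 2 * row["slope_se"]
        assert abs(row["intercept"] - (-5)) <= 2 * row["intercept_se"]


class TestCohortReport:
    def test_single_participant_medians(self):
        days = make_days(n=8, mvpa_min=40.0, steps=9000.0)
        ps = ar.summarize_participant(days, meta())
        participants = ar.participants_frame([ps])
        participants["peak30_cad"] = [90.0]
        tables = ar.cohort_report(participants, days)
        assert tables["table1"].loc["mvpa_min", "all_median"] == 40.0
        assert tables["table1"].loc["mvpa_min", "all_q1"] == 40.0
        assert tables["fig3_regressions"].empty  # needs >= 3 participants

    def test_quartiles_match_order_statistics(self, rng):
        summaries = []
        for i in range(9):
            days = make_days(pid=f"P{i}", n=8,
                             mvpa_min=float(rng.uniform(0, 90)),
                             steps=float(rng.uniform(3000, 14000)))
            days["peak30_cad"] = rng.uniform(40, 120)
            summaries.append(ar.summarize_participant(days, meta(pid=f"P{i}")))
        participants = ar.participants_frame(summaries)
        all_days = make_days(n=8)
        tables = ar.cohort_report(participants, all_days)
        t1 = tables["table1"]
        med, q1, q3 = np.percentile(participants["mvpa_min"], [50, 25, 75])
        assert t1.loc["mvpa_min", "all_median"] == pytest.approx(med)
        assert t1.loc["mvpa_min", "all_q1"] == pytest.approx(q1)
        assert t1.loc["mvpa_min", "all_q3"] == pytest.approx(q3)
        assert set(tables) == {"table1", "table2", "fig2_curve",
                               "fig3_regressions", "fig4_sets"}
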