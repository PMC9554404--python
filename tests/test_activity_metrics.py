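"""Intensity classification, accrual, bout detection, MX metrics.

The bout oracle here re-derives the reference semantics by exhaustive
enumeration: for the leftmost admissible start, every candidate end is
checked literally (length, exact 80% fraction, above-threshold ends, no
internal below-run longer than 12 epochs); the longest interval is kept
and the scan resumes after it.
"""

import numpy as np
import pytest

from wristpa.activity_metrics import (
    accrue_class_minutes,
    classify_epoch_intensity,
    detect_mvpa_bouts,
    mean_acceleration_24h,
    mx_metrics,
    summarize_day_activity,
)
from wristpa.config import EPOCHS_PER_DAY, IntensityBands

FULL = EPOCHS_PER_DAY
WEAR = np.ones(FULL, bool)


def oracle_bout_intervals(above, min_len=120, frac_p=4, frac_q=5, max_gap=12):
    """Brute-force reference bouts (leftmost start, maximal end, no overlap)."""
    above = np.asarray(above, bool)
    n = len(above)
    run_len = np.zeros(n, np.int64)
    c = 0
    for i, a in enumerate(above):
        c = 0 if a else c + 1
        run_len[i] = c
    bad = np.flatnonzero(run_len > max_gap)
    cum = np.concatenate([[0], np.cumsum(above)]).astype(np.int64)
    intervals = []
    s = 0
    while s <= n - min_len:
        if not above[s]:
            s += 1
            continue
        k = np.searchsorted(bad, s + max_gap)
        e_limit = int(bad[k]) if k < len(bad) else n
        ends = np.arange(s + min_len, e_limit + 1)
        if len(ends) == 0:
            s += 1
            continue
        ok = above[ends - 1] & (frac_q * (cum[ends] - cum[s]) >= frac_p * (ends - s))
        if ok.any():
            e = int(ends[ok][-1])
            intervals.append((s, e))
            s = e
        else:
            s += 1
    return intervals


def _bouts(above):
    enmo = np.where(above, 150.0, 0.0)
    return detect_mvpa_bouts(enmo, np.ones(len(above), bool))


class TestClassification:
    @pytest.mark.parametrize(
        "enmo,klass",
        [(10, 0), (24.999, 0), (25, 1), (99.9, 1), (100, 2), (500, 2)],
    )
    def test_band_boundaries(self, enmo, klass):
        classes, _ = classify_epoch_intensity(np.array([float(enmo)]))
        assert classes[0] == klass

    def test_vigorous_subflag(self):
        _, vig = classify_epoch_intensity(np.array([399.9, 400.0]))
        assert list(vig) == [False, True]


class TestAccrual:
    def test_scattered_mvpa_epochs(self, rng):
        enmo = np.zeros(FULL)
        idx = rng.choice(FULL, 684, replace=False)
        enmo[idx] = 150.0
        out = accrue_class_minutes(enmo, WEAR)
        assert out["mvpa_min"] == 57.0

    def test_all_nonwear_zero(self, rng):
        enmo = rng.uniform(0, 300, FULL)
        out = accrue_class_minutes(enmo, np.zeros(FULL, bool))
        assert all(v == 0 for v in out.values())

    def test_epoch_accrual_matches_brute_force(self, rng):
        enmo = rng.uniform(0, 200, FULL)
        wear = rng.random(FULL) < 0.8
        out = accrue_class_minutes(enmo, wear)
        assert out["inactive_min"] == np.sum(wear & (enmo < 25)) / 12
        assert out["lpa_min"] == np.sum(wear & (enmo >= 25) & (enmo < 100)) / 12
        assert out["mvpa_min"] == np.sum(wear & (enmo >= 100)) / 12

    def test_partition_of_wear_minutes(self, rng):
        enmo = rng.uniform(0, 200, FULL)
        wear = rng.random(FULL) < 0.7
        out = accrue_class_minutes(enmo, wear)
        total = out["inactive_min"] + out["lpa_min"] + out["mvpa_min"]
        assert total == pytest.approx(wear.sum() / 12)

    def test_minute80_mode(self):
        enmo = np.zeros(FULL)
        enmo[:10] = 150.0   # 10 of first minute's 12 epochs above
        enmo[12:21] = 150.0  # 9 of second minute's epochs above -> not an MVPA minute
        out = accrue_class_minutes(enmo, WEAR, mode="minute80")
        assert out["mvpa_min"] == 1.0


class TestBouts:
    def test_exact_minimum_duration(self):
        above = np.zeros(400, bool)
        above[100:220] = True
        bouts = _bouts(above)
        assert bouts.intervals == [(100, 220)]
        assert bouts.minutes == 10.0

    def test_one_epoch_short(self):
        above = np.zeros(400, bool)
        above[100:219] = True
        assert _bouts(above).minutes == 0.0

    def test_interrupted_pattern_qualifies(self):
        # (9 above, 1 below) x 13 = 130 epochs at 90% above
        above = np.tile(np.r_[np.ones(9, bool), np.zeros(1, bool)], 13)
        padded = np.r_[np.zeros(50, bool), above, np.zeros(50, bool)]
        bouts = _bouts(padded)
        assert bouts.minutes == oracle_bout_minutes(padded)

    def test_isolated_bursts_no_bout(self):
        # forty 1-min bursts separated by 2-min rests: unbouted MVPA only
        unit = np.r_[np.ones(12, bool), np.zeros(24, bool)]
        above = np.tile(unit, 40)
        bouts = _bouts(above)
        assert bouts.minutes == 0.0
        enmo = np.zeros(FULL)
        enmo[: len(above)][above] = 150.0
        out = accrue_class_minutes(enmo, WEAR)
        assert out["mvpa_min"] == 40.0

    def test_nonwear_counts_below_threshold(self):
        enmo = np.full(400, 150.0)
        wear = np.ones(400, bool)
        wear[150:350] = False
        bouts = detect_mvpa_bouts(enmo, wear)
        assert bouts.intervals == [(0, 150)]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_oracle_on_structured_random_days(self, seed):
        rng = np.random.default_rng(seed)
        # block-structured sequences hit the boundary cases more often
        parts = []
        while sum(map(len, parts)) < 360:
            parts.append(np.full(rng.integers(1, 60), rng.random() < 0.7))
        above = np.concatenate(parts)[:360]
        assert _bouts(above).minutes == oracle_bout_minutes(above)


def oracle_bout_minutes(above):
    return sum(e - s for s, e in oracle_bout_intervals(above)) / 12


class TestMx:
    def test_uniform_day(self):
        out = mx_metrics(np.full(FULL, 50.0), WEAR)
        assert out == {"m2_mg": 50.0, "m30_mg": 50.0, "m60_mg": 50.0}

    def test_rank_arithmetic(self):
        enmo = np.zeros(FULL)
        enmo[:24] = 200.0
        out = mx_metrics(enmo, WEAR)
        assert out["m2_mg"] == 200.0
        assert out["m30_mg"] == 0.0

    def test_matches_sort_oracle(self, rng):
        enmo = rng.uniform(0, 400, FULL)
        wear = rng.random(FULL) < 0.9
        out = mx_metrics(enmo, wear)
        vals = np.sort(np.where(wear, enmo, 0.0))[::-1]
        for x in (2, 30, 60):
            assert out[f"m{x}_mg"] == vals[x * 12 - 1]

    def test_m30_mvpa_duality(self, rng):
        """m30 >= 100 mg iff daily MVPA >= 30 min under epoch accrual."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            enmo = r.uniform(0, 130, FULL) * (r.random(FULL) < 0.05)
            out = mx_metrics(enmo, WEAR)
            mvpa = accrue_class_minutes(enmo, WEAR)["mvpa_min"]
            assert (out["m30_mg"] >= 100) == (mvpa >= 30)


class TestMeanAcceleration:
    def test_full_wear_constant(self):
        assert mean_acceleration_24h(np.full(FULL, 20.0), WEAR) == 20.0

    def test_donor_blend(self):
        enmo = np.full(FULL, 20.0)
        wear = WEAR.copy()
        wear[:720] = False  # one hour non-wear
        donor = np.full(FULL, np.nan)
        donor[:720] = 30.0
        got = mean_acceleration_24h(enmo, wear, donor)
        expected = (30.0 * 720 + 20.0 * (FULL - 720)) / FULL
        assert got == pytest.approx(expected)

    def test_no_donor_contributes_zero(self):
        enmo = np.full(FULL, 20.0)
        wear = WEAR.copy()
        wear[:720] = False
        got = mean_acceleration_24h(enmo, wear)
        assert got == pytest.approx(20.0 * (FULL - 720) / FULL)


class TestDayInvariants:
    @pytest.mark.parametrize("seed", range(10))
    def test_bouted_at_most_mvpa_over_criterion(self, seed):
        rng = np.random.default_rng(seed)
        enmo = np.where(rng.random(FULL) < rng.uniform(0.05, 0.9), 150.0, 0.0)
        wear = rng.random(FULL) < 0.95
        s = summarize_day_activity("p", 2, enmo, wear, np.zeros(FULL, bool))
        assert s.mvpa_bout10_min <= s.mvpa_min / 0.8 + 1e-9
        assert 0 <= s.mvpa_min <= 1440
        assert s.m2_mg >= s.m30_mg >= s.m60_mg
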