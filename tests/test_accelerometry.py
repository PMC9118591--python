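"""Accelerometer processing rules: non-wear, sleep, classification, weighting."""

import numpy as np
import pandas as pd
import pytest

from movecoda.accelerometry import (
    DaySummary,
    EpochSeries,
    classify_counts,
    classify_intensity,
    detect_nonwear,
    estimate_sleep,
    impute_missing_sleep,
    process_epoch_table,
    subject_valid,
    summarize_days,
    to_composition,
    weekly_weighted_means,
)
from movecoda.simulate import SimulationConfig, simulate_cohort, simulate_epochs

MON = pd.Timestamp("2006-03-06")  # a Monday


def series_from_counts(counts, start=MON, subject="S1"):
    counts = np.asarray(counts)
    ts = pd.date_range(start, periods=len(counts), freq="min")
    return EpochSeries(subject_id=subject, timestamps=ts, counts=counts)


class TestDetectNonwear:
    def test_plain_90_minute_zero_run(self):
        s = series_from_counts([500] * 10 + [0] * 90 + [500] * 10)
        mask = detect_nonwear(s)
        assert mask.intervals == [(10, 100)]
        assert mask.worn.sum() == 20

    def test_single_allowance_minute_bridges(self):
        s = series_from_counts([500] * 5 + [0] * 45 + [50] + [0] * 44
                               + [500] * 5)
        mask = detect_nonwear(s)
        assert mask.intervals == [(5, 95)]

    def test_three_minute_interruption_breaks(self):
        s = series_from_counts([500] * 5 + [0] * 30 + [50] * 3 + [0] * 30
                               + [500] * 5)
        assert detect_nonwear(s).intervals == []

    def test_high_count_minute_breaks(self):
        s = series_from_counts([0] * 45 + [150] + [0] * 44)
        assert detect_nonwear(s).intervals == []

    def test_two_allowances_accepted_third_rejected(self):
        block = [0] * 20
        s = series_from_counts(block + [50] + block + [50] + block)
        assert detect_nonwear(s).intervals == [(0, 62)]
        s3 = series_from_counts(block + [50] + block + [50] + block
                                + [50] + block)
        # third allowance terminates the window after the 62-min span
        assert detect_nonwear(s3).intervals == [(0, 62)]

    def test_short_run_not_flagged(self):
        s = series_from_counts([0] * 59 + [500] * 10)
        assert detect_nonwear(s).intervals == []


class TestClassifyIntensity:
    @pytest.mark.parametrize("cpm, expected", [
        (0, "SB"), (99, "SB"), (100, "LPA"), (2295, "LPA"),
        (2296, "MVPA"), (9999, "MVPA"),
    ])
    def test_boundaries(self, cpm, expected):
        assert classify_intensity(cpm) == expected

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            classify_intensity(-1)

    def test_total_and_exhaustive(self):
        cpm = np.arange(0, 6000)
        classes = classify_counts(cpm)
        assert set(np.unique(classes)) == {0, 1, 2}
        assert (classes == 0).sum() == 100
        assert (classes == 1).sum() == 2196


def overnight_series(removal="22:00", refit="07:30", days=1):
    """Worn (LPA) except zeros between nightly removal and morning refit."""
    n = (days + 1) * 1440
    ts = pd.date_range(MON, periods=n, freq="min")
    counts = np.full(n, 500)
    rem_min = int(pd.Timedelta(removal + ":00").total_seconds() // 60)
    ref_min = int(pd.Timedelta(refit + ":00").total_seconds() // 60)
    for d in range(days):
        a = d * 1440 + rem_min
        b = (d + 1) * 1440 + ref_min
        counts[a:b] = 0
    return EpochSeries("S1", ts, counts)


class TestEstimateSleep:
    def test_simple_overnight_gap(self):
        s = overnight_series("22:00", "07:30")
        mask = detect_nonwear(s)
        sleep, smask = estimate_sleep(s, mask)
        assert sleep == {MON.date(): 570}
        assert smask.sum() == 570

    def test_no_overnight_gap_is_missing(self):
        s = series_from_counts([500] * (2 * 1440))
        sleep, _ = estimate_sleep(s, detect_nonwear(s))
        assert sleep == {}

    def test_longest_gap_wins_shorter_stays_nonwear(self):
        n = 2 * 1440
        counts = np.full(n, 500)
        # gap 1: 22:00-23:00 (60 min); gap 2: 23:30-07:00 (450 min)
        counts[22 * 60:23 * 60] = 0
        counts[23 * 60 + 30:1440 + 7 * 60] = 0
        s = series_from_counts(counts)
        mask = detect_nonwear(s)
        sleep, smask = estimate_sleep(s, mask)
        assert sleep == {MON.date(): 450}
        nonwear_left = (~mask.worn) & ~smask
        assert nonwear_left.sum() == 60

    def test_afternoon_gap_not_sleep(self):
        counts = np.full(1440, 500)
        counts[13 * 60:15 * 60] = 0  # 13:00-15:00
        s = series_from_counts(counts)
        sleep, _ = estimate_sleep(s, detect_nonwear(s))
        assert sleep == {}


class TestSummarizeDays:
    def test_wear_threshold_at_600(self):
        for worn, expect in [(600, True), (599, False)]:
            counts = np.concatenate([np.full(worn, 500),
                                     np.zeros(1440 - worn, dtype=int)])
            s = series_from_counts(counts)
            mask = detect_nonwear(s)
            days = summarize_days(s, mask, {}, np.zeros(1440, bool))
            assert days[0].is_valid is expect

    def test_weekend_flag(self):
        sat = pd.Timestamp("2006-03-11")
        s = series_from_counts([500] * 1440, start=sat)
        days = summarize_days(s, detect_nonwear(s), {}, np.zeros(1440, bool))
        assert days[0].is_weekend

    def test_intensity_tallies(self):
        counts = np.concatenate([
            np.full(300, 50), np.full(250, 1000), np.full(50, 3000),
            np.full(840, 50)])
        s = series_from_counts(counts)
        mask = detect_nonwear(s)
        days = summarize_days(s, mask, {}, np.zeros(1440, bool))
        d = days[0]
        assert (d.sb_minutes, d.lpa_minutes, d.mvpa_minutes) == (1140, 250, 50)
        assert d.sb_minutes + d.lpa_minutes + d.mvpa_minutes == d.wear_minutes

    def test_partition_of_day(self):
        s = overnight_series("22:00", "07:30", days=2)
        mask = detect_nonwear(s)
        sleep, smask = estimate_sleep(s, mask)
        dates = s.timestamps.normalize()
        for day in pd.unique(dates):
            sel = np.asarray(dates == day)
            n_sleep = (smask & sel).sum()
            n_nonwear = ((~mask.worn) & ~smask & sel).sum()
            n_worn = (mask.worn & sel).sum()
            assert n_sleep + n_nonwear + n_worn == 1440


def _day(date, wear=700, weekend=False, valid=None, **kw):
    kw.setdefault("sleep_minutes", 600)
    kw.setdefault("sb_minutes", 300)
    kw.setdefault("lpa_minutes", 300)
    kw.setdefault("mvpa_minutes", 40)
    return DaySummary(date=date, wear_minutes=wear, is_weekend=weekend,
                      is_valid=wear >= 600 if valid is None else valid, **kw)


class TestSubjectValidity:
    def test_needs_a_weekend_day(self):
        days = [_day(f"d{i}") for i in range(4)]
        assert not subject_valid(days)

    def test_four_days_with_saturday(self):
        days = [_day(f"d{i}") for i in range(3)] + [_day("sat", weekend=True)]
        assert subject_valid(days)

    def test_empty_and_invalid_days(self):
        assert not subject_valid([])
        days = [_day(f"d{i}", wear=500) for i in range(5)]
        assert not subject_valid(days)


class TestWeeklyWeighting:
    def test_weighted_mean_example(self):
        days = ([_day(f"wd{i}", mvpa_minutes=30) for i in range(4)]
                + [_day("sat", weekend=True, mvpa_minutes=44)])
        assert weekly_weighted_means(days)["MVPA"] == pytest.approx(34.0)

    def test_identity_when_equal(self):
        days = [_day("wd", mvpa_minutes=25),
                _day("we", weekend=True, mvpa_minutes=25)]
        assert weekly_weighted_means(days)["MVPA"] == pytest.approx(25.0)

    def test_sleep_example(self):
        days = ([_day(f"wd{i}", sleep_minutes=600) for i in range(3)]
                + [_day("sat", weekend=True, sleep_minutes=610)])
        assert weekly_weighted_means(days)["sleep"] == pytest.approx(602.857,
                                                                     abs=1e-3)

    def test_no_weekend_errors(self):
        with pytest.raises(ValueError):
            weekly_weighted_means([_day("wd")])

    def test_duplicated_day_invariance(self):
        days = ([_day(f"wd{i}", mvpa_minutes=30) for i in range(2)]
                + [_day("sat", weekend=True, mvpa_minutes=44)])
        doubled = days + [_day("wd_dup", mvpa_minutes=30),
                          _day("sat_dup", weekend=True, mvpa_minutes=44)]
        assert weekly_weighted_means(days)["MVPA"] == pytest.approx(
            weekly_weighted_means(doubled)["MVPA"])


class TestToComposition:
    def test_closure_to_1440(self):
        w = {"sleep": 600.0, "SB": 360.0, "LPA": 420.0, "MVPA": 36.0}
        out = to_composition("S1", w)
        assert out.composition.values == pytest.approx(
            [610.17, 366.10, 427.12, 36.61], abs=0.01)

    def test_already_closed_unchanged(self):
        w = {"sleep": 600.0, "SB": 360.0, "LPA": 420.0, "MVPA": 60.0}
        out = to_composition("S1", w)
        assert out.composition.values == pytest.approx(
            [600.0, 360.0, 420.0, 60.0])

    def test_zero_mvpa_floored(self):
        w = {"sleep": 600.0, "SB": 400.0, "LPA": 440.0, "MVPA": 0.0}
        out = to_composition("S1", w)
        assert out.composition.values[3] > 0
        assert out.composition.values.sum() == pytest.approx(1440.0)


class TestImputation:
    def test_missing_sleep_borrows_subject_mean(self):
        days = [_day("a", sleep_minutes=590), _day("b", sleep_minutes=610),
                _day("c", sleep_minutes=None)]
        out = impute_missing_sleep(days)
        assert out[2].sleep_minutes == pytest.approx(600.0)

    def test_no_sleep_anywhere_drops_days(self):
        days = [_day("a", sleep_minutes=None)]
        assert impute_missing_sleep(days) == []


class TestGeneratorRoundTrip:
    def test_exact_recovery_without_artifacts(self):
        cfg = SimulationConfig(
            n_subjects=2, seed=3, removal_jitter=0, clr_effects={},
            base_hours=(10.0, 6.0, 7.0, 1.0), p_daytime_nonwear=0.0,
            deterministic_counts=True, noise_scale=0.0)
        sim = simulate_cohort(cfg, with_epochs=True)
        beh = process_epoch_table(sim.epochs)
        rec = beh[["sleep_min", "sb_min", "lpa_min", "mvpa_min"]].to_numpy()
        assert beh["valid"].all()
        assert np.allclose(rec, [[600.0, 360.0, 420.0, 60.0]] * 2)

    def test_inserted_nonwear_block_detected(self):
        cfg = SimulationConfig(n_subjects=1, seed=9, removal_jitter=0,
                               clr_effects={}, noise_scale=0.0,
                               p_daytime_nonwear=1.0,
                               nonwear_minutes=(90, 90),
                               deterministic_counts=True)
        sim = simulate_cohort(cfg, with_epochs=True)
        grp = sim.epochs
        s = EpochSeries("S0001", pd.DatetimeIndex(grp["timestamp"]),
                        grp["cpm"].to_numpy())
        mask = detect_nonwear(s)
        sleep, smask = estimate_sleep(s, mask)
        daytime = [(a, b) for (a, b) in mask.intervals
                   if not smask[a:b].any()]
        lengths = sorted(b - a for a, b in daytime)
        # 7 days, each with one inserted 90-min block (pre-study morning
        # tail and final-night tail are scored as sleep or lost, not here)
        assert lengths.count(90) == 7
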