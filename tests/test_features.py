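"""Unit and property tests for the activity-feature formulas."""

import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actipred import features
from actipred.features import (
    EPOCHS_PER_MINUTE,
    MINUTES_PER_DAY,
    daily_qoa,
    day_features,
    epoch_stats,
    extract_daily_features,
    hourly_pa,
    minute_activity_index,
    regularity_index,
    resultant_acceleration,
    wear_validity,
)
from actipred.synth import AccelStream, DayRecord

from conftest import D0, random_day_record
from oracles import brute_force_hourly, brute_force_minute_ai


class TestResultantAcceleration:
    @pytest.mark.parametrize(
        "axes,expected",
        [
            ((3.0, 4.0, 0.0), 5.0),
            ((0.0, 0.0, 1.0), 1.0),
            ((0.6, 0.8, 1.0), math.sqrt(2.0)),
        ],
    )
    def test_euclidean_norm(self, axes, expected):
        assert resultant_acceleration(*axes) == pytest.approx(expected, rel=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            resultant_acceleration(math.nan, 0.0, 1.0)


class TestEpochStats:
    def test_constant_signal_has_zero_sd(self):
        s = epoch_stats([1.0] * 100)
        assert s.mu == 1.0 and s.sigma == 0.0 and s.n_samples == 100

    def test_degenerate_two_sample_epoch_uses_population_sd(self):
        s = epoch_stats([1.0, 3.0])
        assert s.mu == pytest.approx(2.0)
        assert s.sigma == pytest.approx(1.0)  # 1/N form, not 1/(N-1)

    def test_symmetric_alternating_signal(self):
        s = epoch_stats([0.9, 1.1] * 50)
        assert s.mu == pytest.approx(1.0)
        assert s.sigma == pytest.approx(0.1)

    def test_empty_epoch_is_missing_not_zero(self):
        s = epoch_stats([])
        assert math.isnan(s.sigma) and math.isnan(s.mu) and s.n_samples == 0

    def test_overfull_epoch_rejected(self):
        with pytest.raises(ValueError):
            epoch_stats([1.0] * 101)


class TestMinuteActivityIndex:
    def test_quiet_minute(self):
        ai, n = minute_activity_index([0.0] * 12)
        assert ai == 0.0 and n == 12

    def test_sum_of_epoch_sds(self):
        ai, _ = minute_activity_index([0.05] * 12)
        assert ai == pytest.approx(0.6)

    def test_partial_minute_sums_present_epochs(self):
        ai, n = minute_activity_index([0.1] * 6 + [math.nan] * 6)
        assert ai == pytest.approx(0.6) and n == 6

    def test_all_missing_minute(self):
        ai, n = minute_activity_index([math.nan] * 12)
        assert math.isnan(ai) and n == 0

    def test_structural_error_on_too_many_epochs(self):
        with pytest.raises(ValueError):
            minute_activity_index([0.0] * 13)


class TestHourlyPA:
    @pytest.mark.parametrize(
        "minutes,expected",
        [
            ([0.0] * 60, 0.0),
            ([0.6] * 60, 36.0),
            ([1.0] * 30 + [math.nan] * 30, 30.0),
        ],
    )
    def test_hourly_sum(self, minutes, expected):
        assert hourly_pa(minutes) == pytest.approx(expected)


class TestRegularityIndex:
    def test_identical_patterns_perfectly_regular(self):
        pattern = np.sin(np.arange(24) / 3.0) + 2.0
        assert regularity_index(pattern, pattern) == pytest.approx(1.0)

    def test_negated_pattern_anti_correlates(self):
        pattern = np.sin(np.arange(24) / 3.0) + 2.0
        mirrored = 2 * pattern.mean() - pattern
        assert regularity_index(pattern, mirrored) == pytest.approx(-1.0)

    def test_reversed_linear_ramp(self):
        assert regularity_index(
            np.arange(1.0, 25.0), np.arange(24.0, 0.0, -1.0)
        ) == pytest.approx(-1.0)

    def test_zero_variance_day_is_undefined(self):
        assert math.isnan(regularity_index(np.ones(24), np.arange(24.0)))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_bounded_in_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        ri = regularity_index(r.random(24), r.random(24))
        assert -1.0 <= ri <= 1.0


class TestDailyQoA:
    def test_regularity_neutral(self):
        ai = np.full(MINUTES_PER_DAY, 0.1)
        assert daily_qoa(ai, 0.0) == pytest.approx(ai.sum())

    def test_perfect_regularity_doubles(self):
        ai = np.full(MINUTES_PER_DAY, 100.0 / MINUTES_PER_DAY)
        assert daily_qoa(ai, 1.0) == pytest.approx(200.0)

    def test_perfect_anti_regularity_annihilates(self):
        ai = np.full(MINUTES_PER_DAY, 0.7)
        assert daily_qoa(ai, -1.0) == 0.0

    def test_undefined_ri_treated_as_neutral(self):
        ai = np.full(MINUTES_PER_DAY, 0.1)
        assert daily_qoa(ai, math.nan) == pytest.approx(ai.sum())


class TestWearValidity:
    def test_full_day(self):
        idx = np.arange(86400, dtype=np.int64)  # 1 Hz
        assert wear_validity(idx, 1.0) == (True, 86400.0)

    def test_ten_hours_insufficient(self):
        idx = np.arange(36000, dtype=np.int64)
        assert wear_validity(idx, 1.0) == (False, 36000.0)

    def test_two_blocks_count_cumulatively(self):
        block1 = np.arange(8 * 3600, dtype=np.int64)
        block2 = np.arange(16 * 3600, 24 * 3600, dtype=np.int64)
        idx = np.concatenate([block1, block2])
        assert wear_validity(idx, 1.0) == (True, 57600.0)

    def test_gap_limit_invalidates_interrupted_day(self):
        block1 = np.arange(8 * 3600, dtype=np.int64)
        block2 = np.arange(16 * 3600, 24 * 3600, dtype=np.int64)
        idx = np.concatenate([block1, block2])
        valid, seconds = wear_validity(idx, 1.0, max_gap_seconds=3600.0)
        assert not valid and seconds == 57600.0


class TestAgainstBruteForceOracle:
    @pytest.mark.parametrize("gap_fraction,n_hours", [(0.0, 24.0), (0.3, 6.0)])
    def test_minute_ai_matches_nested_loop_recomputation(
        self, rng, gap_fraction, n_hours
    ):
        rec = random_day_record(
            rng, sampling_rate=5, n_hours=n_hours, gap_fraction=gap_fraction
        )
        f = day_features(rec, "P001", 5)
        expected = brute_force_minute_ai(rec.sample_index, rec.xyz, 5)
        for m in range(MINUTES_PER_DAY):
            if math.isnan(expected[m]):
                assert math.isnan(f.minute_ai[m])
            else:
                assert f.minute_ai[m] == pytest.approx(
                    expected[m], rel=1e-12, abs=1e-300
                )
        hourly = brute_force_hourly(expected)
        assert f.hourly_pa == pytest.approx(hourly, rel=1e-12)

    def test_gravity_offset_invariance(self, rng):
        """A constant additive component in the resultant acceleration —
        the static gravity contribution — leaves σ_k unchanged: the SD
        removes the constant component exactly."""
        for _ in range(20):
            samples = 1.0 + 0.1 * rng.standard_normal(25)
            offset = rng.uniform(-2.0, 2.0)
            base = epoch_stats(samples)
            shifted = epoch_stats(samples + offset)
            assert shifted.sigma == pytest.approx(base.sigma, rel=1e-9, abs=1e-12)
            assert shifted.mu == pytest.approx(base.mu + offset, rel=1e-9)

    def test_scale_equivariance(self, rng):
        """Scaling samples by c scales AI and QoA by c; RI is unchanged."""
        c = 3.0
        rec1 = random_day_record(rng, sampling_rate=5, date=D0)
        rec2 = random_day_record(rng, sampling_rate=5, date=D0 + dt.timedelta(days=1))
        rec1 = DayRecord(rec1.date, rec1.sample_index, rec1.xyz.astype(np.float64))
        rec2 = DayRecord(rec2.date, rec2.sample_index, rec2.xyz.astype(np.float64))
        f1 = day_features(rec1, "P001", 5)
        f2 = day_features(rec2, "P001", 5, prev=f1)
        s1 = DayRecord(rec1.date, rec1.sample_index, rec1.xyz * c)
        s2 = DayRecord(rec2.date, rec2.sample_index, rec2.xyz * c)
        g1 = day_features(s1, "P001", 5)
        g2 = day_features(s2, "P001", 5, prev=g1)
        np.testing.assert_allclose(g2.minute_ai, c * f2.minute_ai, rtol=1e-9)
        assert g2.ri == pytest.approx(f2.ri, abs=1e-9)
        assert g2.qoa == pytest.approx(c * f2.qoa, rel=1e-9)


def _stream_from_days(recs, fs=1.0):
    spd = int(fs * 86400)
    idx = np.concatenate(
        [r.sample_index + i * spd for i, r in enumerate(recs)]
    )
    xyz = np.concatenate([r.xyz for r in recs])
    return AccelStream("P001", recs[0].date, fs, len(recs), idx, xyz)


class TestExtractDailyFeatures:
    def test_gravity_only_day_has_zero_activity(self):
        idx = np.arange(86400, dtype=np.int64)
        xyz = np.zeros((86400, 3), dtype=np.float32)
        xyz[:, 2] = 1.0
        stream = _stream_from_days([DayRecord(D0, idx, xyz)])
        (f,) = extract_daily_features(stream)
        assert np.all(f.minute_ai == 0.0)
        assert f.qoa == 0.0 and f.wear_valid

    def test_identical_active_days_are_perfectly_regular(self, rng):
        rec1 = random_day_record(rng, sampling_rate=1)
        rec2 = DayRecord(
            D0 + dt.timedelta(days=1), rec1.sample_index, rec1.xyz
        )
        stream = _stream_from_days([rec1, rec2])
        f1, f2 = extract_daily_features(stream)
        assert math.isnan(f1.ri)  # no previous day
        assert f2.ri == pytest.approx(1.0, abs=1e-9)

    def test_day_after_invalid_day_has_undefined_ri(self, rng):
        rec1 = random_day_record(rng, sampling_rate=1, n_hours=4.0)  # short
        full = random_day_record(rng, sampling_rate=1)
        rec2 = DayRecord(D0 + dt.timedelta(days=1), full.sample_index, full.xyz)
        stream = _stream_from_days([rec1, rec2])
        f1, f2 = extract_daily_features(stream)
        assert not f1.wear_valid
        assert math.isnan(f2.ri)

    def test_minute_ai_long_format_skips_missing_minutes(self, rng):
        rec = random_day_record(rng, sampling_rate=1, n_hours=2.0)
        f = day_features(rec, "P001", 1)
        frame = features.minute_ai_to_frame([f])
        assert len(frame) == 120  # two observed hours
        assert list(frame.columns) == ["patient_id", "date", "minute", "ai"]
        assert frame["minute"].min() == 1

    def test_out_of_order_stream_rejected(self, rng):
        rec = random_day_record(rng, sampling_rate=1, n_hours=1.0)
        stream = _stream_from_days([rec])
        stream.sample_index = stream.sample_index[::-1].copy()
        with pytest.raises(ValueError):
            extract_daily_features(stream)
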