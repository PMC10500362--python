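"""Band lookup, score computation, and EWS series construction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wardews import (
    EwsSource,
    Parameter,
    ValidationError,
    compute_ews,
    max_achievable_score,
    nurse_ews_series,
    score_parameter,
    sensor_ews_series,
)
from wardews.core import NURSE_PARAMETERS, SENSOR_PARAMETERS, NurseObservation
from wardews.scoring import band_representatives, score_values

from conftest import make_patient


class TestScoreParameter:
    @pytest.mark.parametrize(
        ("param", "value", "points"),
        [
            # printed band edges
            (Parameter.HR, 105, 1),
            (Parameter.HR, 100, 0),
            (Parameter.HR, 110, 1),
            (Parameter.HR, 111, 2),
            (Parameter.HR, 130, 3),
            (Parameter.HR, 40, 2),
            (Parameter.HR, 41, 1),
            (Parameter.SPO2, 90, 3),
            (Parameter.SPO2, 91, 3),
            (Parameter.SPO2, 92, 2),
            (Parameter.SPO2, 94, 1),
            (Parameter.SPO2, 96, 0),
            (Parameter.RR, 12, 0),
            (Parameter.RR, 8, 2),
            (Parameter.RR, 9, 0),
            (Parameter.RR, 15, 1),
            (Parameter.RR, 21, 2),
            (Parameter.RR, 30, 3),
            (Parameter.AT, 37.0, 0),
            (Parameter.AT, 34.9, 2),
            (Parameter.AT, 35.0, 0),
            (Parameter.AT, 38.4, 0),
            (Parameter.AT, 38.5, 2),
            (Parameter.SBP, 70, 3),
            (Parameter.SBP, 80, 2),
            (Parameter.SBP, 100, 1),
            (Parameter.SBP, 200, 0),
            (Parameter.SBP, 201, 2),
            (Parameter.TT, 38.5, 2),
            # real-valued window means round half-away-from-zero to band
            # resolution before lookup
            (Parameter.RR, 8.4, 2),
            (Parameter.RR, 8.5, 0),
            (Parameter.HR, 100.4, 0),
            (Parameter.HR, 100.5, 1),
            (Parameter.AT, 38.44, 0),
            (Parameter.AT, 38.45, 2),
            (Parameter.AT, 34.94, 2),
            (Parameter.AT, 34.96, 0),
        ],
    )
    def test_band_lookup(self, param, value, points, table):
        assert score_parameter(param, value, table) == points

    def test_non_finite_rejected(self, table):
        with pytest.raises(ValidationError):
            score_parameter(Parameter.HR, float("nan"), table)

    def test_monotone_toward_extremes(self, table):
        """Moving outward from the normal band never loses points."""
        for param in NURSE_PARAMETERS:
            reps = band_representatives(table, param)
            pts = [p for _, p in reps]
            zero = pts.index(min(pts))
            low_side = pts[: zero + 1]
            high_side = pts[zero:]
            assert low_side == sorted(low_side, reverse=True)
            assert high_side == sorted(high_side)

    def test_vectorized_lookup_matches_naive_oracle(self, table):
        """10^5 random values per parameter against an if/elif re-implementation."""

        def naive(param, v):
            # independent restatement of the printed criteria
            if param in (Parameter.AT, Parameter.TT):
                r = np.floor(v * 10 + 0.5) / 10
                if r <= 34.9 or r >= 38.5:
                    return 2
                return 0
            r = np.floor(v + 0.5)
            if param is Parameter.HR:
                if r <= 40: return 2
                if r <= 50: return 1
                if r <= 100: return 0
                if r <= 110: return 1
                if r <= 129: return 2
                return 3
            if param is Parameter.RR:
                if r <= 8: return 2
                if r <= 14: return 0
                if r <= 20: return 1
                if r <= 29: return 2
                return 3
            if param is Parameter.SPO2:
                if r <= 91: return 3
                if r <= 93: return 2
                if r <= 95: return 1
                return 0
            if param is Parameter.SBP:
                if r <= 70: return 3
                if r <= 80: return 2
                if r <= 100: return 1
                if r <= 200: return 0
                return 2
            raise AssertionError(param)

        rng = np.random.default_rng(12345)
        ranges = {
            Parameter.HR: (20, 220),
            Parameter.RR: (2, 60),
            Parameter.SPO2: (60, 100),
            Parameter.SBP: (40, 260),
            Parameter.AT: (30, 42),
            Parameter.TT: (30, 42),
        }
        for param, (lo, hi) in ranges.items():
            vals = rng.uniform(lo, hi, size=100_000)
            got = score_values(param, vals, table)
            expected = np.fromiter((naive(param, v) for v in vals), dtype=np.int64)
            np.testing.assert_array_equal(got, expected)


class TestComputeEws:
    def test_all_normal_sensor(self, table):
        score, n = compute_ews(
            {Parameter.HR: 70, Parameter.RR: 12, Parameter.SPO2: 97,
             Parameter.AT: 37.0},
            EwsSource.SENSOR,
            table,
        )
        assert score == 0 and n == 4

    def test_maximal_sensor_combination(self, table):
        score, n = compute_ews(
            {Parameter.HR: 135, Parameter.RR: 31, Parameter.SPO2: 90,
             Parameter.AT: 38.6},
            EwsSource.SENSOR,
            table,
        )
        assert score == 11 and n == 4

    def test_single_parameter_gives_absent_score(self, table):
        score, n = compute_ews({Parameter.HR: 70}, EwsSource.SENSOR, table)
        assert np.isnan(score) and n == 1

    def test_mixed_band_sum(self, table):
        score, _ = compute_ews(
            {Parameter.HR: 105, Parameter.RR: 22, Parameter.SPO2: 94,
             Parameter.AT: 38.6},
            EwsSource.SENSOR,
            table,
        )
        assert score == 1 + 2 + 1 + 2

    def test_nurse_pairs(self, table):
        score, n = compute_ews(
            {Parameter.HR: 80, Parameter.SBP: 120}, EwsSource.NURSE, table
        )
        assert score == 0 and n == 2
        score, n = compute_ews({Parameter.SBP: 65}, EwsSource.NURSE, table)
        assert np.isnan(score) and n == 1
        score, _ = compute_ews(
            {Parameter.HR: 115, Parameter.RR: 25, Parameter.SBP: 95,
             Parameter.TT: 38.7, Parameter.SPO2: 92},
            EwsSource.NURSE,
            table,
        )
        assert score == 2 + 2 + 1 + 2 + 2

    def test_wrong_source_parameter_rejected(self, table):
        with pytest.raises(ValidationError):
            compute_ews({Parameter.SBP: 120}, EwsSource.SENSOR, table)

    @given(
        values=st.dictionaries(
            st.sampled_from(list(SENSOR_PARAMETERS)),
            st.floats(min_value=0, max_value=300, allow_nan=False),
            min_size=2,
            max_size=4,
        )
    )
    def test_sensor_score_bounded(self, values, table):
        score, n = compute_ews(values, EwsSource.SENSOR, table)
        assert 0 <= score <= 11
        assert n == len(values)

    def test_maxima_attained_by_enumeration(self, table):
        assert max_achievable_score(table, SENSOR_PARAMETERS) == 11
        assert max_achievable_score(table, NURSE_PARAMETERS) == 14


class TestSeries:
    def test_full_data_series_shape(self, table):
        hours = 3
        p = make_patient(
            {
                Parameter.HR: [70] * hours,
                Parameter.RR: [12] * hours,
                Parameter.SPO2: [97] * hours,
                Parameter.AT: [37.0] * hours,
            },
            end_min=hours * 60,
        )
        s = sensor_ews_series(p, 60, table)
        assert len(s) == hours
        np.testing.assert_array_equal(s.scores, [0, 0, 0])
        np.testing.assert_array_equal(s.n_params, [4, 4, 4])

    def test_known_band_placements(self, table):
        """Three hours engineered to score [0, 3, 6]."""
        p = make_patient(
            {
                Parameter.HR: [70, 70, 105],
                Parameter.RR: [12, 12, 22],
                Parameter.SPO2: [97, 90, 94],
                Parameter.AT: [37.0, 37.0, 38.6],
            },
            end_min=180,
        )
        s = sensor_ews_series(p, 60, table)
        np.testing.assert_array_equal(s.scores, [0, 3, 6])

    def test_single_surviving_parameter_gives_absent_score(self, table):
        # SpO2 full hour; HR only 20 minutes (disregarded window)
        p = make_patient(
            {
                Parameter.SPO2: [97.0],
                Parameter.HR: (np.arange(20), np.full(20, 70.0)),
            },
            end_min=60,
        )
        s = sensor_ews_series(p, 60, table)
        assert len(s) == 1
        assert np.isnan(s.scores[0])
        assert s.n_params[0] == 1

    def test_no_channels_rejected(self, table):
        p = make_patient({}, end_min=60)
        with pytest.raises(ValidationError):
            sensor_ews_series(p, 60, table)

    def test_nurse_series(self, table):
        obs = [
            NurseObservation("P1", 10, hr=80.0, sbp=120.0),
            NurseObservation("P1", 500, sbp=65.0),
            NurseObservation("P1", 900, hr=115.0, rr=25.0, sbp=95.0,
                             tt=38.7, spo2=92.0),
        ]
        p = make_patient({Parameter.HR: [70] * 1}, end_min=1000, nurse=obs)
        s = nurse_ews_series(p, table)
        assert len(s) == 3
        assert s.scores[0] == 0 and s.n_params[0] == 2
        assert np.isnan(s.scores[1]) and s.n_params[1] == 1
        assert s.scores[2] == 9 and s.n_params[2] == 5
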