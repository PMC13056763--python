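"""Windowing arithmetic, the volume-weighted USG, and the marker predicates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrascore import (
    BodyMassSeries,
    Void,
    body_mass_change,
    extract_windows,
    long_void_flag,
    thirst_percent,
    weighted_usg,
    window_metrics,
)
from hydrascore.features import FeatureError
from conftest import make_voids

T0 = pd.Timestamp("2024-06-01 08:00:00")


def _hour(h):
    return T0 + pd.Timedelta(hours=float(h))


class TestWindowing:
    def test_hourly_stream_splits_into_overlapping_windows(self):
        voids = make_voids("P1", range(1, 33), [200] * 32, [1.010] * 32)
        w_m, w_a = extract_windows(voids, (_hour(24), _hour(32)))
        assert len(w_m.voids) == 24 and len(w_a.voids) == 24
        m_times = {v.time for v in w_m.voids}
        a_times = {v.time for v in w_a.voids}
        overlap = m_times & a_times
        assert len(overlap) == 16
        assert {pd.Timestamp(t) for t in voids["time"]} == m_times | a_times
        assert (w_a.start - w_m.start) == pd.Timedelta(hours=8)

    def test_void_at_exact_window_start_is_excluded(self):
        voids = make_voids("P1", [0.0, 5.0], [300, 300], [1.010, 1.010])
        w_m, _ = extract_windows(voids, (_hour(24), _hour(32)))
        # the void at t-24h exactly falls outside the half-open interval
        assert [v.time for v in w_m.voids] == [_hour(5.0)]

    def test_void_at_assessment_moment_is_included(self):
        voids = make_voids("P1", [24.0], [300], [1.010])
        w_m, _ = extract_windows(voids, (_hour(24), _hour(32)))
        assert len(w_m.voids) == 1

    def test_union_of_windows_is_full_stream(self, default_cohort):
        pid = default_cohort.participants["participant_id"].iloc[0]
        voids = default_cohort.voids.query("participant_id == @pid")
        times = default_cohort.assessments.query("participant_id == @pid")
        pair = (
            times[times.session == "morning"]["assessment_time"].iloc[0],
            times[times.session == "afternoon"]["assessment_time"].iloc[0],
        )
        w_m, w_a = extract_windows(voids, pair)
        union = {v.time for v in w_m.voids} | {v.time for v in w_a.voids}
        assert union == set(pd.to_datetime(voids["time"]))

    def test_empty_void_list_is_an_error(self):
        with pytest.raises(FeatureError):
            extract_windows([], (_hour(24), _hour(32)))

    def test_partial_coverage_is_flagged(self):
        voids = make_voids("P1", [6.0, 23.0], [300, 300], [1.010, 1.010])
        w_m, w_a = extract_windows(voids, (_hour(24), _hour(32)))
        assert w_m.partial  # first void + 24 h is later than the anchor
        assert not w_a.partial


class TestWeightedUsg:
    def test_equal_volumes_average(self):
        voids = [Void("P", _hour(1), 1000, 1.010), Void("P", _hour(2), 1000, 1.020)]
        assert weighted_usg(voids) == pytest.approx(1.015, abs=1e-12)

    def test_single_void_identity(self):
        assert weighted_usg([Void("P", _hour(1), 350, 1.013)]) == 1.013

    def test_three_void_hand_computation(self):
        voids = [
            Void("P", _hour(1), 300, 1.005),
            Void("P", _hour(2), 600, 1.015),
            Void("P", _hour(3), 100, 1.030),
        ]
        # independent evaluation of sum(usg*vol)/sum(vol)
        expected = (1.005 * 300 + 1.015 * 600 + 1.030 * 100) / 1000.0
        assert weighted_usg(voids) == pytest.approx(expected, abs=1e-15)

    def test_empty_window_is_an_error(self):
        with pytest.raises(FeatureError):
            weighted_usg([])

    @settings(deadline=None, max_examples=200)
    @given(st.data())
    def test_mixture_consistency_and_bounds(self, data):
        """Splitting a void into same-USG parts never changes the mean,
        and the mean stays within the member USG range."""
        n = data.draw(st.integers(1, 8))
        vols = data.draw(
            st.lists(st.floats(1.0, 2000.0), min_size=n, max_size=n)
        )
        usgs = data.draw(
            st.lists(st.floats(1.000, 1.040), min_size=n, max_size=n)
        )
        voids = [Void("P", _hour(i), v, u) for i, (v, u) in enumerate(zip(vols, usgs))]
        base = weighted_usg(voids)
        assert min(usgs) <= base <= max(usgs)
        frac = data.draw(st.floats(0.1, 0.9))
        split = voids[:-1] + [
            Void("P", _hour(n), vols[-1] * frac, usgs[-1]),
            Void("P", _hour(n + 1), vols[-1] * (1 - frac), usgs[-1]),
        ]
        assert weighted_usg(split) == pytest.approx(base, abs=1e-9)


class TestMarkerPredicates:
    def test_window_metrics_counts_and_volume(self):
        voids = make_voids("P1", [10, 12, 14], [200, 200, 200], [1.01, 1.01, 1.01])
        w_m, _ = extract_windows(voids, (_hour(24), _hour(32)))
        met = window_metrics(w_m)
        assert met["volume_24h"] == 600 and met["void_count_24h"] == 3

    @pytest.mark.parametrize(
        "mm,pct,flag", [(0, 0.0, True), (175, 100.0, False), (70, 40.0, True)]
    )
    def test_thirst_percentage_and_inclusive_threshold(self, mm, pct, flag):
        out = thirst_percent(mm)
        assert out["percent"] == pytest.approx(pct, abs=1e-12)
        assert out["not_thirsty"] is flag

    def test_negative_vas_is_an_error(self):
        with pytest.raises(FeatureError):
            thirst_percent(-1)

    @pytest.mark.parametrize(
        "d1,d2,d3,pct,flag",
        [
            (80, 80, 80, 0.0, False),
            (80, 79.2, 80, -1.0, True),  # exactly -1% flags (inclusive)
            (80, 80.8, 80, 1.0, False),  # gains never flag
        ],
    )
    def test_body_mass_change_from_two_day_baseline(self, d1, d2, d3, pct, flag):
        out = body_mass_change(BodyMassSeries("P", d1, d2, d3))
        assert out["percent_change"] == pytest.approx(pct, abs=1e-9)
        assert out["flag_ge_1pct"] is flag

    def test_nonpositive_mass_is_an_error(self):
        with pytest.raises(FeatureError):
            BodyMassSeries("P", 80, 0, 80)

    @pytest.mark.parametrize("dur,flag", [(16, True), (15.9, False), (0, False)])
    def test_long_void_threshold_inclusive(self, dur, flag):
        assert long_void_flag(dur) is flag

    def test_negative_duration_is_an_error(self):
        with pytest.raises(FeatureError):
            long_void_flag(-0.1)
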