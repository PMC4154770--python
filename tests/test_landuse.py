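"""Land-use intensity indices: hand-checked arithmetic and invariances."""

from datetime import date, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grasslandsem.landuse import (
    FertilizerApplication,
    GrazingPeriod,
    MowingEvent,
    fertilization_intensity,
    grazing_intensity,
    mowing_frequency,
    time_after_mowing,
)


def _fert(year, amount, plot="p1"):
    return FertilizerApplication(plot, date(year, 4, 1), amount)


class TestFertilization:
    def test_no_applications_is_zero(self):
        assert fertilization_intensity([], 2008) == 0.0

    def test_three_year_mean(self):
        apps = [_fert(2006, 60.0), _fert(2008, 30.0)]
        assert fertilization_intensity(apps, 2008) == pytest.approx(30.0)

    def test_same_year_applications_sum(self):
        apps = [_fert(2007, 25.0), _fert(2007, 25.0)]
        assert fertilization_intensity(apps, 2008) == pytest.approx(50.0 / 3.0)

    def test_outside_window_ignored(self):
        apps = [_fert(2005, 500.0), _fert(2009, 500.0)]
        assert fertilization_intensity(apps, 2008) == 0.0

    def test_negative_amount_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            _fert(2008, -1.0)


def _graze(year, count, days, area, weight=1.0, month=5):
    start = date(year, month, 1)
    return GrazingPeriod("p1", start, start + timedelta(days=days - 1), count, weight, area)


class TestGrazing:
    def test_no_grazing_is_zero(self):
        assert grazing_intensity([], 2008) == 0.0

    def test_hand_case(self):
        # 20 cattle x 1.0 LU x 30 days on 2 ha in one of three window years
        assert grazing_intensity([_graze(2007, 20, 30, 2.0)], 2008) == pytest.approx(100.0)

    @given(
        c1=st.integers(1, 50), d1=st.integers(1, 60),
        c2=st.integers(1, 50), d2=st.integers(1, 60),
    )
    @settings(max_examples=50, deadline=None)
    def test_additive_over_disjoint_periods(self, c1, d1, c2, d2):
        p1 = _graze(2007, c1, d1, 2.0, month=4)
        p2 = _graze(2007, c2, d2, 2.0, month=8)
        both = grazing_intensity([p1, p2], 2008)
        assert both == pytest.approx(
            grazing_intensity([p1], 2008) + grazing_intensity([p2], 2008)
        )

    @given(count=st.integers(1, 40), k=st.integers(2, 5))
    @settings(max_examples=30, deadline=None)
    def test_linear_in_livestock_count(self, count, k):
        one = grazing_intensity([_graze(2008, count, 20, 1.5)], 2008)
        scaled = grazing_intensity([_graze(2008, count * k, 20, 1.5)], 2008)
        assert scaled == pytest.approx(k * one)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError, match="area"):
            _graze(2008, 10, 5, 0.0)

    def test_backwards_period_rejected(self):
        with pytest.raises(ValueError, match="ends before"):
            GrazingPeriod("p1", date(2008, 6, 1), date(2008, 5, 1), 5, 1.0, 1.0)


def _mow(year, month, day, plot="p1"):
    return MowingEvent(plot, date(year, month, day))


class TestMowing:
    def test_unmown_plot(self):
        assert mowing_frequency([], 2008, date(2008, 6, 15)) == 0.0

    def test_sampling_year_truncation(self):
        events = [
            _mow(2006, 5, 1), _mow(2006, 7, 1),
            _mow(2007, 5, 1), _mow(2007, 7, 1),
            _mow(2008, 5, 10), _mow(2008, 7, 10),  # July cut after June sampling
        ]
        assert mowing_frequency(events, 2008, date(2008, 6, 15)) == pytest.approx(5.0 / 3.0)

    def test_cut_on_sampling_date_counts(self):
        events = [_mow(2008, 6, 15)]
        assert mowing_frequency(events, 2008, date(2008, 6, 15)) == pytest.approx(1.0 / 3.0)
        assert mowing_frequency([_mow(2008, 6, 16)], 2008, date(2008, 6, 15)) == 0.0

    @given(shift=st.integers(-400, 400))
    @settings(max_examples=30, deadline=None)
    def test_translation_invariance(self, shift):
        # shifting every date by whole years leaves the counts unchanged
        years = shift // 365
        events = [_mow(2006, 5, 1), _mow(2007, 8, 2), _mow(2008, 6, 1)]
        shifted = [MowingEvent("p1", e.date.replace(year=e.date.year + years)) for e in events]
        base = mowing_frequency(events, 2008, date(2008, 6, 15))
        moved = mowing_frequency(shifted, 2008 + years, date(2008 + years, 6, 15))
        assert moved == pytest.approx(base)


class TestTimeAfterMowing:
    ONSET = date(2008, 4, 1)
    S1, S2 = date(2008, 6, 15), date(2008, 8, 15)

    def test_symmetric_cuts(self):
        events = [_mow(2008, 6, 5), _mow(2008, 8, 5)]
        assert time_after_mowing(events, (self.S1, self.S2), self.ONSET) == pytest.approx(10.0)

    def test_unmown_falls_back_to_onset(self):
        s1 = self.ONSET + timedelta(days=60)
        s2 = self.ONSET + timedelta(days=120)
        assert time_after_mowing([], (s1, s2), self.ONSET) == pytest.approx(90.0)

    def test_single_cut_between_samplings(self):
        cut = date(2008, 7, 10)
        expected = ((self.S1 - self.ONSET).days + (self.S2 - cut.replace()).days) / 2.0
        got = time_after_mowing([MowingEvent("p1", cut)], (self.S1, self.S2), self.ONSET)
        assert got == pytest.approx(expected)

    def test_sampling_before_onset_rejected(self):
        with pytest.raises(ValueError, match="onset"):
            time_after_mowing([], (date(2008, 3, 1), self.S2), self.ONSET)
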