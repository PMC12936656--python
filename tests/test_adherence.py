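import datetime as dt
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxsupply.adherence import (EligibilityError, PeriodMissingError, cma5,
                                daily_oracle, deviation_band, mean_ds_summary,
                                period_change, yearly_adherence, SupplyEvent,
                                AdherenceResult)

D0 = dt.date(2014, 1, 1)


def ev(day: int, ds: int) -> tuple[dt.date, int]:
    return (D0 + dt.timedelta(days=day), ds)


# ---------------------------------------------------------------------------
# CMA5 point cases (expected values from the day-by-day oracle)

@pytest.mark.parametrize("events, expected", [
    ([ev(0, 30), ev(30, 30)], 1.0),       # seamless refill
    ([ev(0, 10), ev(20, 10)], 0.5),       # 10 covered days in a 20-day window
    ([ev(0, 30), ev(20, 30), ev(60, 30)], 1.0),  # second fill stored to day 30
    ([ev(0, 5), ev(10, 5), ev(30, 5)], 1 / 3),
    ([ev(0, 100), ev(10, 100), ev(20, 1)], 1.0),  # oversupply capped at 1
])
def test_cma5_known_values(events, expected):
    assert cma5(events) == pytest.approx(expected)
    assert daily_oracle(events) == pytest.approx(expected)


def test_final_fill_supply_is_discarded():
    # the last dispensing closes the window; its huge supply must not count
    assert cma5([ev(0, 10), ev(20, 1000)]) == 0.5


def test_same_day_fills_accumulate():
    assert cma5([ev(0, 5), ev(0, 5), ev(10, 5)]) == 1.0


@pytest.mark.parametrize("events", [
    [ev(0, 30)],                 # a single fill
    [ev(0, 30), ev(0, 30)],      # zero-length window
])
def test_ineligible_streams_raise(events):
    with pytest.raises(EligibilityError):
        cma5(events)
    with pytest.raises(EligibilityError):
        daily_oracle(events)


# ---------------------------------------------------------------------------
# oracle equivalence and invariants

def random_event_sets(rng, n_sets, max_events=6, max_gap=120, max_ds=150):
    for _ in range(n_sets):
        k = rng.integers(2, max_events + 1)
        days = np.concatenate([[0], np.cumsum(rng.integers(0, max_gap, size=k - 1))])
        if days[-1] == 0:
            days[-1] = 1
        yield [ev(int(d), int(rng.integers(1, max_ds))) for d in days]


def test_interval_form_equals_oracle_on_random_streams():
    rng = np.random.default_rng(42)
    for events in random_event_sets(rng, 500):
        assert cma5(events) == daily_oracle(events)


@settings(deadline=None, max_examples=150)
@given(gaps=st.lists(st.integers(0, 90), min_size=1, max_size=4),
       supplies=st.lists(st.integers(1, 120), min_size=5, max_size=5),
       bump=st.integers(0, 60), which=st.integers(0, 4), shift=st.integers(-3000, 3000))
def test_cma5_invariants(gaps, supplies, bump, which, shift):
    days = list(itertools.accumulate([0] + gaps))
    if days[-1] == 0:
        return
    events = [ev(d, s) for d, s in zip(days, supplies)]
    base = cma5(events)
    assert 0.0 <= base <= 1.0
    assert base == daily_oracle(events)
    # monotone in any event's supply
    which = min(which, len(events) - 1)
    d, s = events[which]
    more = events[:which] + [(d, s + bump)] + events[which + 1:]
    assert cma5(more) >= base
    # translation invariant
    moved = [(d + dt.timedelta(days=shift), s) for d, s in events]
    assert cma5(moved) == base


# ---------------------------------------------------------------------------
# yearly windows

def _events(patient, atc, fills):
    return [SupplyEvent(patient, atc, d, ds) for d, ds in fills]


def test_single_fill_years_produce_no_result():
    events = _events("P1", "H03AA01", [ev(0, 30)])
    events += _events("P1", "H03AA01", [(dt.date(2015, 1, 1), 30),
                                        (dt.date(2015, 3, 1), 30)])
    results = yearly_adherence(events)
    assert [(r.year, r.n_events) for r in results] == [(2015, 2)]


def test_window_spans_first_to_last_fill_of_the_year():
    events = _events("P1", "H03AA01", [(dt.date(2015, 1, 1), 181),
                                       (dt.date(2015, 7, 1), 10)])
    (res,) = yearly_adherence(events)
    assert (res.window_start, res.window_end) == (dt.date(2015, 1, 1), dt.date(2015, 7, 1))
    assert res.cma5 == 1.0


def test_substance_filter_and_empty_match():
    events = _events("P1", "H03AA01", [ev(0, 30), ev(30, 30)])
    assert yearly_adherence(events, substances=["C01AA05"]) == []
    assert len(yearly_adherence(events, substances=["H03AA01"])) == 1


def test_cross_year_carry_in_is_optional():
    # a December stockpile either dies at the year boundary (default) or
    # seeds the next year's window (carry_in=True)
    events = _events("P1", "H03AA01", [
        (dt.date(2014, 12, 1), 60), (dt.date(2014, 12, 21), 10),
        (dt.date(2015, 1, 10), 5), (dt.date(2015, 1, 20), 5)])
    no_carry = {r.year: r.cma5 for r in yearly_adherence(events)}
    assert no_carry == {2014: 1.0, 2015: 0.5}
    carry = {r.year: r.cma5 for r in yearly_adherence(events, carry_in=True)}
    # leftover at 2014's last fill: 60 - 20 used + 10 dispensed = 50,
    # depleted over the 20 days to 2015's first fill -> 30 in hand
    assert carry == {2014: 1.0, 2015: 1.0}


def test_streams_are_independent_per_medication():
    events = _events("P1", "H03AA01", [ev(0, 30), ev(40, 30)])
    events += _events("P1", "C01AA05", [ev(0, 30), ev(30, 30)])
    results = {r.medication_key: r.cma5 for r in yearly_adherence(events)}
    assert results["C01AA05"] == 1.0
    assert results["H03AA01"] == pytest.approx(30 / 40)


# ---------------------------------------------------------------------------
# period summaries and banding

def test_band_boundaries_closed_on_the_right():
    assert deviation_band(0) == "green"
    assert deviation_band(7) == "green"
    assert deviation_band(7.1) == "yellow"
    assert deviation_band(30) == "yellow"
    assert deviation_band(30.1) == "red"
    assert deviation_band(-40) == "red"


def _ds_table(values_a, values_b, atc="H03AA01"):
    import pandas as pd
    rows = [{"atc_code": atc, "year": 2013, "ds_days": v} for v in values_a]
    rows += [{"atc_code": atc, "year": 2018, "ds_days": v} for v in values_b]
    return pd.DataFrame(rows)


@pytest.mark.parametrize("a, b, band", [
    ([30] * 5, [30] * 5, "green"),
    ([40] * 5, [20] * 5, "yellow"),
    ([100] * 5, [60] * 5, "red"),
])
def test_mean_ds_banding(a, b, band):
    summaries = mean_ds_summary(_ds_table(a, b))
    assert {s.band for s in summaries} == {band}
    for s in summaries:
        assert s.ci_low <= s.mean_ds <= s.ci_high


def test_transition_year_excluded_from_periods():
    import pandas as pd
    df = _ds_table([30] * 5, [30] * 5)
    spike = pd.DataFrame([{"atc_code": "H03AA01", "year": 2016, "ds_days": 500}])
    summaries = mean_ds_summary(pd.concat([df, spike], ignore_index=True))
    assert all(s.mean_ds == 30 for s in summaries)


def test_subgroup_missing_in_one_period_omitted_with_warning():
    import pandas as pd
    df = pd.DataFrame([{"atc_code": "C01AA05", "year": 2013, "ds_days": 30}])
    with pytest.warns(UserWarning, match="C01"):
        assert mean_ds_summary(df) == []


def _adh(patient, atc, year, value):
    return AdherenceResult(patient, atc, year, value, 2,
                           dt.date(year, 1, 1), dt.date(year, 6, 1))


def test_period_change_is_difference_of_means():
    adh = [_adh("P1", "H03AA01", 2013, 0.4), _adh("P2", "H03AA01", 2014, 0.6),
           _adh("P1", "H03AA01", 2018, 0.9), _adh("P2", "H03AA01", 2019, 0.7)]
    change = period_change(adh)
    assert change.loc["H03", "change"] == pytest.approx(0.8 - 0.5)


def test_equal_adherence_means_zero_change():
    adh = [_adh("P1", "C01AA05", 2013, 0.8), _adh("P1", "C01AA05", 2018, 0.8)]
    assert period_change(adh).loc["C01", "change"] == 0.0


def test_single_period_input_is_an_error():
    adh = [_adh("P1", "C01AA05", 2013, 0.8)]
    with pytest.raises(PeriodMissingError):
        period_change(adh)
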