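"""CMA5 medication adherence and period-comparison quality control.

CMA5 is one of the continuous multiple-interval measures of medication
availability.  It assumes a refill dispensed while the previous supply is
still running is *stored* and consumed only once that supply runs out
(carryover), and it discards whatever supply is left at the end of the
observation window.  Here the observation window for a patient-medication
stream runs from the first dispensing to the last, half-open — the final
dispensing closes the window and its own supply is never consumed — and
CMA5 is the fraction of window days on which the patient had supply
in hand.

Used as quality control for days'-supply resolution: if imputed DS values
are sound, mean DS and mean adherence should be stable between an era when
daily doses were mostly missing (and DS mostly imputed) and an era when
they were recorded (and DS mostly calculated).
"""

from __future__ import annotations

import datetime as dt
import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import PrescriptionRecord
from .resolve import DSResult


class EligibilityError(ValueError):
    """Stream does not qualify for adherence calculation (code ELIGIBILITY)."""


class PeriodMissingError(ValueError):
    """A requested comparison period has no data (code PERIOD_MISSING)."""


@dataclass(frozen=True)
class SupplyEvent:
    patient_id: str
    medication_key: str  # full ATC code
    dispense_date: dt.date
    ds_days: int


@dataclass(frozen=True)
class AdherenceResult:
    patient_id: str
    medication_key: str
    year: int
    cma5: float
    n_events: int
    window_start: dt.date
    window_end: dt.date


@dataclass(frozen=True)
class PeriodSummary:
    atc_subgroup: str  # 3-character ATC therapeutic subgroup
    period: str
    mean_ds: float
    ci_low: float
    ci_high: float
    n: int
    band: str  # green | yellow | red


def _sorted_events(events: Sequence[SupplyEvent | tuple]) -> list[tuple[dt.date, int]]:
    pairs = []
    for e in events:
        if isinstance(e, SupplyEvent):
            pairs.append((e.dispense_date, int(e.ds_days)))
        else:
            d, ds = e
            pairs.append((d, int(ds)))
    pairs.sort(key=lambda p: p[0])
    return pairs


def _interval_sim(pairs: Sequence[tuple[dt.date, int]],
                  initial_stock: int = 0) -> tuple[int, int]:
    """Covered days over [first, last) and the stock left at the last fill
    (excluding the last fill's own supply)."""
    stock = initial_stock
    covered = 0
    for (d0, ds0), (d1, _) in zip(pairs, pairs[1:]):
        gap = (d1 - d0).days
        stock += ds0
        used = min(stock, gap)
        covered += used
        stock -= used
    return covered, stock


def cma5(events: Sequence[SupplyEvent | tuple], initial_stock: int = 0) -> float:
    """Event-interval CMA5 for one patient-medication window.

    Stock accumulates at each dispensing and is drawn down one day of
    supply per covered day; within each inter-fill interval the covered
    days are therefore the first ``min(stock, gap)`` days.  The window is
    ``[first fill, last fill)``; supply outstanding at the window end
    (including the last fill itself) is discarded.  Requires at least two
    events and a window of at least one day.  ``initial_stock`` seeds
    stock already in hand at the window start (cross-window carryover).
    """
    pairs = _sorted_events(events)
    if len(pairs) < 2:
        raise EligibilityError("ELIGIBILITY: fewer than 2 dispensings")
    window = (pairs[-1][0] - pairs[0][0]).days
    if window < 1:
        raise EligibilityError("ELIGIBILITY: zero-length window")
    covered, _ = _interval_sim(pairs, initial_stock)
    return covered / window


def daily_oracle(events: Sequence[SupplyEvent | tuple],
                 initial_stock: int = 0) -> float:
    """Literal day-by-day stock simulation; same contract as :func:`cma5`.

    Kept deliberately naive — it is the independent reference the interval
    implementation is tested against.
    """
    pairs = _sorted_events(events)
    if len(pairs) < 2:
        raise EligibilityError("ELIGIBILITY: fewer than 2 dispensings")
    start = pairs[0][0]
    window = (pairs[-1][0] - start).days
    if window < 1:
        raise EligibilityError("ELIGIBILITY: zero-length window")
    add_on_day: dict[int, int] = defaultdict(int)
    for d, ds in pairs[:-1]:  # the final fill opens no consumable window
        add_on_day[(d - start).days] += ds
    stock = initial_stock
    covered = 0
    for day in range(window):
        stock += add_on_day.get(day, 0)
        if stock > 0:
            covered += 1
            stock -= 1
    return covered / window


def events_from_results(records: Iterable[PrescriptionRecord],
                        results: Iterable[DSResult],
                        substances: Iterable[str] | None = None) -> list[SupplyEvent]:
    """Join resolved DS values back onto dispensings as supply events.

    Unresolved prescriptions are excluded (no silent default), as are ATC
    codes outside the ``substances`` filter when one is given.
    """
    ds_by_id = {r.prescription_id: r for r in results}
    wanted = {s.strip().upper() for s in substances} if substances is not None else None
    events = []
    for rec in records:
        res = ds_by_id.get(rec.prescription_id)
        if res is None or res.ds_days is None:
            continue
        atc = rec.atc_code.strip().upper()
        if wanted is not None and atc not in wanted:
            continue
        events.append(SupplyEvent(rec.patient_id, atc, rec.dispense_date, res.ds_days))
    return events


def yearly_adherence(events: Iterable[SupplyEvent],
                     substances: Iterable[str] | None = None,
                     years: Iterable[int] | None = None,
                     carry_in: bool = False) -> list[AdherenceResult]:
    """CMA5 per patient x medication x calendar year.

    Each year's window runs from that year's first to last dispensing of
    the medication; patients with fewer than two dispensings in the year
    (or a zero-length window) are ineligible and produce no result.  By
    default no stock is carried across year boundaries; with
    ``carry_in=True`` the stock physically in hand at a year's first fill
    (the previous window's leftover plus its final fill, depleted one day
    of supply per intervening day) seeds the new window.
    """
    wanted = {s.strip().upper() for s in substances} if substances is not None else None
    year_set = set(years) if years is not None else None
    streams: dict[tuple[str, str], dict[int, list[SupplyEvent]]] = defaultdict(
        lambda: defaultdict(list))
    for e in events:
        if wanted is not None and e.medication_key not in wanted:
            continue
        y = e.dispense_date.year
        if year_set is not None and y not in year_set:
            continue
        streams[(e.patient_id, e.medication_key)][y].append(e)

    out = []
    for (pid, key), by_year in sorted(streams.items()):
        carry = 0
        prev_date: dt.date | None = None
        for year in sorted(by_year):
            pairs = _sorted_events(by_year[year])
            first, last = pairs[0][0], pairs[-1][0]
            if carry_in and prev_date is not None:
                carry = max(0, carry - (first - prev_date).days)
            initial = carry if carry_in else 0
            try:
                value = cma5(pairs, initial_stock=initial)
            except EligibilityError:
                value = None
            if value is not None:
                out.append(AdherenceResult(pid, key, year, value, len(pairs),
                                           first, last))
            # physical stock at the year's last fill (that fill included)
            _, leftover = _interval_sim(pairs, initial)
            carry = leftover + pairs[-1][1]
            prev_date = last
    out.sort(key=lambda a: (a.patient_id, a.medication_key, a.year))
    return out


# ---------------------------------------------------------------------------
# period comparison

def deviation_band(mean_difference: float) -> str:
    """Traffic-light band on |mean difference| in days: <=7 green,
    (7, 30] yellow, >30 red."""
    d = abs(mean_difference)
    if d <= 7:
        return "green"
    if d <= 30:
        return "yellow"
    return "red"


def _period_label(period: tuple[int, int]) -> str:
    return f"{period[0]}-{period[1]}"


def _in_period(year: int, period: tuple[int, int]) -> bool:
    return period[0] <= year <= period[1]


def mean_ds_summary(ds_table: pd.DataFrame,
                    periods: tuple[tuple[int, int], tuple[int, int]] = ((2012, 2015), (2017, 2019)),
                    exclude_years: Iterable[int] = (2016,),
                    atc_level: int = 3) -> list[PeriodSummary]:
    """Mean DS with 95% CI per ATC subgroup per period, with deviation band.

    ``ds_table`` needs columns ``atc_code``, ``year`` and ``ds_days``.  The
    CI uses the normal approximation (mean +/- 1.96 sd/sqrt(n)).  The band
    is a pure function of the absolute difference between the two period
    means of a subgroup; subgroups absent from one period are omitted with
    a warning.  Transition years in ``exclude_years`` take part in neither
    period.
    """
    pa, pb = periods
    if not (pa[1] < pb[0] or pb[1] < pa[0]):
        raise ValueError("comparison periods must not overlap")
    df = ds_table.dropna(subset=["ds_days"]).copy()
    df = df[~df["year"].isin(set(exclude_years))]
    df["subgroup"] = df["atc_code"].str.upper().str[:atc_level]

    out: list[PeriodSummary] = []
    for sub, g in df.groupby("subgroup"):
        stats = {}
        for period in (pa, pb):
            vals = g.loc[g["year"].apply(lambda y: _in_period(y, period)), "ds_days"]
            if len(vals) == 0:
                continue
            n = len(vals)
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if n > 1 else 0.0
            half = 1.96 * sd / np.sqrt(n) if n > 1 else 0.0
            stats[period] = (mean, mean - half, mean + half, n)
        if len(stats) < 2:
            warnings.warn(f"ATC subgroup {sub}: no data in one period; omitted")
            continue
        band = deviation_band(stats[pa][0] - stats[pb][0])
        for period in (pa, pb):
            mean, lo, hi, n = stats[period]
            out.append(PeriodSummary(sub, _period_label(period), mean, lo, hi, n, band))
    return out


def period_change(adherence: Sequence[AdherenceResult],
                  periods: tuple[tuple[int, int], tuple[int, int]] = ((2012, 2015), (2017, 2019)),
                  atc_level: int = 3) -> pd.DataFrame:
    """Mean CMA5 per ATC subgroup per period and the between-period change.

    Returns a frame indexed by subgroup with columns ``mean_a``, ``mean_b``,
    ``change`` (b - a) plus the per-period stream counts.  Raises
    :class:`PeriodMissingError` when either period has no eligible streams
    at all.
    """
    pa, pb = periods
    rows = [(r.medication_key[:atc_level].upper(), r.year, r.cma5) for r in adherence]
    df = pd.DataFrame(rows, columns=["subgroup", "year", "cma5"])
    in_a = df["year"].apply(lambda y: _in_period(y, pa)) if len(df) else pd.Series(dtype=bool)
    in_b = df["year"].apply(lambda y: _in_period(y, pb)) if len(df) else pd.Series(dtype=bool)
    if len(df) == 0 or not in_a.any() or not in_b.any():
        raise PeriodMissingError("PERIOD_MISSING: both periods need adherence data")

    a = df[in_a].groupby("subgroup")["cma5"].agg(["mean", "size"])
    b = df[in_b].groupby("subgroup")["cma5"].agg(["mean", "size"])
    out = a.join(b, how="inner", lsuffix="_a", rsuffix="_b")
    out = out.rename(columns={"mean_a": "mean_a", "mean_b": "mean_b",
                              "size_a": "n_a", "size_b": "n_b"})
    out["change"] = out["mean_b"] - out["mean_a"]
    return out[["mean_a", "n_a", "mean_b", "n_b", "change"]]
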