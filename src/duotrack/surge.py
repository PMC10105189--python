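"""Winter-surge demand profile.

Hospital admissions in Hong Kong follow a 90-day winter surge: demand ramps
up linearly over the 30 days before January 15, holds at a peak of
``peak_ratio`` times the non-surge level through February 13, and ramps back
down linearly over the following 30 days.  Annual admission totals relate to
the non-surge daily level ``x`` through

    annual = (days_in_year - 90) * x + 30 * r * x + 2 * 30 * (x + r*x) / 2

(two trapezoidal ramps around a 30-day plateau).  The daily sampling below is
chosen so that summing the profile over a calendar year reproduces that
closed form exactly: the up-ramp starts at the non-surge level on December 16
and reaches the peak on January 15, while the down-ramp starts *at* the peak
on February 14 and reaches the non-surge level the day after March 15.  In a
leap year the extra day is a non-surge day.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

from .params import AnnualInputs

__all__ = [
    "SurgeCalendar",
    "surge_multiplier",
    "daily_admissions",
    "nonsurge_from_annual",
    "annual_from_nonsurge",
]


@dataclass(frozen=True)
class SurgeCalendar:
    """Shape of the annual winter surge.

    ``peak_start``/``peak_end`` are (month, day) pairs; the peak window is
    closed on both ends and must span ``peak_days`` calendar days.
    """

    peak_start: tuple[int, int] = (1, 15)
    peak_end: tuple[int, int] = (2, 13)
    ramp_days: int = 30
    peak_ratio: float = 1.196

    def __post_init__(self) -> None:
        if self.ramp_days <= 0:
            raise ValueError("ramp_days must be positive")
        if self.peak_ratio < 1.0:
            raise ValueError("peak_ratio must be >= 1")
        window = (self.peak_end_date(2015) - self.peak_start_date(2015)).days + 1
        if window <= 0:
            raise ValueError("peak window must have positive length")

    def peak_start_date(self, year: int) -> dt.date:
        return dt.date(year, *self.peak_start)

    def peak_end_date(self, year: int) -> dt.date:
        return dt.date(year, *self.peak_end)


def surge_multiplier(day: dt.date, calendar: SurgeCalendar | None = None) -> float:
    """Demand multiplier for ``day``: 1 off-season, ``peak_ratio`` at peak.

    Piecewise linear and continuous: rises from 1 over the ``ramp_days`` days
    before the peak window, holds the peak ratio through the window, and
    decays back to 1 over the ``ramp_days`` days after it (the first
    post-peak day still carries the full ratio; see the module notes on why
    this sampling conserves annual totals exactly).
    """
    cal = calendar or SurgeCalendar()
    season_year = day.year + 1 if day.month == 12 else day.year
    ps = cal.peak_start_date(season_year)
    pe = cal.peak_end_date(season_year)
    r = cal.peak_ratio
    m = cal.ramp_days
    if ps <= day <= pe:
        return r
    up = (ps - day).days
    if 0 < up <= m:
        return 1.0 + (r - 1.0) * (m - up) / m
    down = (day - pe).days
    if 1 <= down <= m:
        return r - (r - 1.0) * (down - 1) / m
    return 1.0


def daily_admissions(
    day: dt.date, inputs: AnnualInputs, calendar: SurgeCalendar | None = None
) -> float:
    """Admission demand (patients/day) on ``day``.

    The active year's non-surge daily level scaled by the surge multiplier;
    during the peak window this equals the tabulated surge level up to the
    rounding of the published inputs.
    """
    return inputs.value("inpt_nonsurge", day) * surge_multiplier(day, calendar)


def nonsurge_from_annual(
    annual_total: float, peak_ratio: float = 1.196, days_in_year: int = 365
) -> float:
    """Non-surge daily level ``x`` consistent with an annual admission total.

    Inverts ``annual = (days - 90)x + 30rx + 2*30*(x + rx)/2`` in closed
    form: ``x = annual / (days - 60 + 60r)``.
    """
    if annual_total <= 0 or peak_ratio < 1 or days_in_year <= 90:
        raise ValueError("annual_total must be positive, peak_ratio >= 1, days > 90")
    return annual_total / (days_in_year - 60.0 + 60.0 * peak_ratio)


def annual_from_nonsurge(
    nonsurge: float, peak_ratio: float = 1.196, days_in_year: int = 365
) -> float:
    """Annual admission total implied by a non-surge daily level (inverse of
    :func:`nonsurge_from_annual`)."""
    if nonsurge <= 0 or peak_ratio < 1 or days_in_year <= 90:
        raise ValueError("nonsurge must be positive, peak_ratio >= 1, days > 90")
    return nonsurge * (days_in_year - 60.0 + 60.0 * peak_ratio)
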