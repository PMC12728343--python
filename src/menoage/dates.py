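"""Calendar arithmetic used throughout the LMP algorithm.

Conventions (applied before all interval arithmetic):

* attendance dates carry only month and year, so the day is standardised to
  the midpoint of the month (the 15th by default);
* "N months before" is calendar-month subtraction with end-of-month clamping
  (2012-09-15 minus 3 months is 2012-06-15);
* "one year before" is calendar-year subtraction (2012-09-15 to 2011-09-15);
* midpoints are earlier-biased: ``a + floor((b - a)/2)`` days.
"""

from __future__ import annotations

from datetime import date, timedelta

from dateutil.relativedelta import relativedelta

DAYS_PER_YEAR = 365.25


def standardize_attendance_date(month: int, year: int, day: int = 15) -> date:
    """Return the standardised attendance date for a month/year report."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be 1-12, got {month!r}")
    return date(year, month, day)


def months_before(d: date, months: int) -> date:
    return d - relativedelta(months=months)


def years_before(d: date, years: int) -> date:
    return d - relativedelta(years=years)


def midpoint_date(a: date, b: date) -> date:
    """Earlier-biased midpoint of two dates; requires ``a <= b``."""
    if a > b:
        raise ValueError(f"midpoint_date requires a <= b, got {a} > {b}")
    return a + timedelta(days=(b - a).days // 2)


def date_at_age(birth_reference: date, age_years: float) -> date:
    """Calendar date at which a woman born at ``birth_reference`` has ``age_years``."""
    return birth_reference + timedelta(days=round(age_years * DAYS_PER_YEAR))


def age_at_date(birth_reference: date, d: date) -> float:
    """Continuous age in years at date ``d``."""
    return (d - birth_reference).days / DAYS_PER_YEAR
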