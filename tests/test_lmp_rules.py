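"""Worked examples and an exhaustive brute-force oracle for the LMP rules."""

from datetime import date, timedelta

import pytest
from dateutil.relativedelta import relativedelta

from menoage import (
    AssignedLMP,
    Provenance,
    assign_from_bleeding_history,
    assign_from_reported_date,
    assign_lmp_year_only,
    carry_forward,
    check_bleeding_consistency,
    check_future_date,
    check_prior_timepoint,
    reconcile_bleeding_flags,
)
from menoage.lmp import assign_one

from conftest import make_ctx

SEP = date(2012, 9, 15)
FEB = date(2012, 2, 15)


class TestReportedDate:
    def test_complete_date_used_verbatim(self):
        ctx = make_ctx(date(2008, 7, 15), lmp_day=17, lmp_month=6, lmp_year=2008)
        lmp = assign_from_reported_date(ctx)
        assert lmp.lmp_date == date(2008, 6, 17)
        assert lmp.provenance is Provenance.FULL_DATE

    def test_month_year_gets_mid_month_day(self):
        ctx = make_ctx(date(2008, 7, 15), lmp_month=6, lmp_year=2008)
        lmp = assign_from_reported_date(ctx)
        assert lmp.lmp_date == date(2008, 6, 15)
        assert lmp.provenance is Provenance.MONTH_YEAR_MID

    def test_impossible_calendar_date_demoted_to_month_year(self):
        # a reported "31st February 2009" keeps its month and year
        ctx = make_ctx(date(2015, 10, 15), lmp_day=31, lmp_month=2, lmp_year=2009)
        lmp = assign_from_reported_date(ctx)
        assert lmp.lmp_date == date(2009, 2, 15)
        assert lmp.provenance is Provenance.MONTH_YEAR_MID

    def test_no_year_no_assignment(self):
        assert assign_from_reported_date(make_ctx(SEP, lmp_day=3)) is None


# (attendance, lmp_year, bled3, bled12) -> expected date or None; midpoints
# frozen from the day-count oracle applied to the rules' printed endpoints
YEAR_ONLY_CASES = [
    ("3.1a", SEP, 2012, False, False, None),
    ("3.1b", SEP, 2011, False, False, date(2011, 5, 9)),    # mid(1 Jan, 15 Sep 2011)
    ("3.1c", SEP, 2010, False, False, date(2010, 6, 15)),
    ("3.2a", SEP, 2012, False, True, date(2012, 3, 24)),    # mid(1 Jan, 15 Jun 2012)
    ("3.2b", SEP, 2011, False, True, date(2011, 11, 7)),    # mid(15 Sep, 31 Dec 2011)
    ("3.2d", FEB, 2011, False, True, date(2011, 7, 1)),     # mid(15 Feb, 15 Nov 2011)
    ("3.2e", FEB, 2012, False, True, None),
    ("3.2f", FEB, 2010, False, True, None),
    ("3.3a", SEP, 2012, True, True, date(2012, 7, 31)),     # mid(15 Jun, 15 Sep 2012)
    ("3.3b", FEB, 2012, True, True, date(2012, 1, 23)),     # mid(1 Jan, 15 Feb 2012)
    ("3.3c", FEB, 2011, True, True, date(2011, 12, 8)),     # mid(15 Nov, 31 Dec 2011)
    ("3.3d", SEP, 2011, True, True, None),
    ("future-year", SEP, 2013, True, True, None),
    ("missing-flags", SEP, 2011, None, None, None),
]


@pytest.mark.parametrize("tag, att, year, b3, b12, expected",
                         YEAR_ONLY_CASES, ids=[c[0] for c in YEAR_ONLY_CASES])
def test_year_only_rules(tag, att, year, b3, b12, expected):
    ctx = make_ctx(att, lmp_year=year, bled_last_3mo=b3, bled_last_12mo=b12)
    lmp = assign_lmp_year_only(ctx, year)
    if expected is None:
        assert lmp is None
    else:
        assert lmp.lmp_date == expected
        assert lmp.provenance is Provenance.YEAR_ONLY_RULE
        assert lmp.rule_tag == tag


class TestBleedingHistoryFallback:
    def test_bled_3mo_places_lmp_45_days_before_attendance(self):
        ctx = make_ctx(SEP, bled_last_3mo=True, bled_last_12mo=True)
        lmp = assign_from_bleeding_history(ctx)
        assert lmp.lmp_date == date(2012, 8, 1)
        assert (SEP - lmp.lmp_date).days == 45
        assert lmp.provenance is Provenance.BLEEDING_3MO

    def test_bled_12mo_only_places_lmp_228_days_before_attendance(self):
        ctx = make_ctx(SEP, bled_last_3mo=False, bled_last_12mo=True)
        lmp = assign_from_bleeding_history(ctx)
        assert lmp.lmp_date == date(2012, 1, 31)
        assert (SEP - lmp.lmp_date).days == 228
        assert lmp.provenance is Provenance.BLEEDING_12MO

    @pytest.mark.parametrize("b3, b12", [(False, False), (None, None), (None, True)])
    def test_no_usable_flags_no_assignment(self, b3, b12):
        assert assign_from_bleeding_history(
            make_ctx(SEP, bled_last_3mo=b3, bled_last_12mo=b12)
        ) is None


def _lmp(d, provenance=Provenance.FULL_DATE, pid="p1", wave="W0"):
    return AssignedLMP(pid, wave, d, provenance, "1")


class TestConsistencyChecks:
    @pytest.mark.parametrize(
        "b3, b12, lmp_date, keep",
        [
            (True, True, date(2012, 4, 1), True),    # within 6-month lower bound
            (True, True, date(2012, 2, 1), False),   # >6 months back contradicts 3-mo bleeding
            (False, True, date(2011, 5, 1), True),   # inside [A-18m, A+31d]
            (False, True, date(2011, 2, 1), False),  # >18 months back
            (False, False, date(2012, 5, 1), False), # only ~4.5 months before attendance
            (False, False, date(2012, 3, 1), True),  # >6 months before
            (None, None, date(2012, 9, 1), True),    # nothing to check against
        ],
    )
    def test_bleeding_consistency_windows(self, b3, b12, lmp_date, keep):
        ctx = make_ctx(SEP, bled_last_3mo=b3, bled_last_12mo=b12)
        assert check_bleeding_consistency(_lmp(lmp_date), ctx) is keep

    def test_check_a_skips_year_only_assignments(self):
        ctx = make_ctx(SEP, bled_last_3mo=False, bled_last_12mo=False)
        lmp = _lmp(date(2012, 9, 1), Provenance.YEAR_ONLY_RULE)
        assert check_bleeding_consistency(lmp, ctx) is True

    @pytest.mark.parametrize(
        "offset_days, keep", [(16, True), (31, True), (0, True), (32, False), (40, False)]
    )
    def test_future_dates_allowed_up_to_31_days(self, offset_days, keep):
        ctx = make_ctx(SEP)
        assert check_future_date(_lmp(SEP + timedelta(days=offset_days)), ctx) is keep

    def test_date_before_previous_attendance_dropped_when_previous_assigned(self):
        prev = _lmp(date(2008, 6, 17), wave="W0")
        ctx = make_ctx(date(2015, 10, 15), previous_attendance=date(2013, 5, 15),
                       previous_lmp=prev)
        assert check_prior_timepoint(_lmp(date(2009, 2, 15), wave="W1"), ctx) is False

    def test_date_before_previous_attendance_kept_when_previous_unassigned(self):
        ctx = make_ctx(date(2015, 10, 15), previous_attendance=date(2013, 5, 15),
                       previous_lmp=None)
        assert check_prior_timepoint(_lmp(date(2009, 2, 15)), ctx) is True

    def test_date_after_previous_attendance_kept(self):
        prev = _lmp(date(2013, 4, 1))
        ctx = make_ctx(date(2015, 10, 15), previous_attendance=date(2013, 5, 15),
                       previous_lmp=prev)
        assert check_prior_timepoint(_lmp(date(2014, 1, 10)), ctx) is True


class TestCarryForward:
    def test_gap_over_three_years_blocks_carry(self):
        prev = _lmp(date(2010, 9, 17))
        ctx = make_ctx(date(2015, 2, 15), previous_attendance=date(2010, 10, 15),
                       previous_lmp=prev, bled_last_3mo=False, bled_last_12mo=False)
        assert carry_forward(ctx, dropped_by_prior_check=False) is None

    def test_gap_within_three_years_carries_previous_lmp(self):
        prev = _lmp(date(2010, 9, 17))
        ctx = make_ctx(date(2013, 2, 15), previous_attendance=date(2010, 10, 15),
                       previous_lmp=prev, bled_last_3mo=False, bled_last_12mo=False)
        lmp = carry_forward(ctx, dropped_by_prior_check=False)
        assert lmp.lmp_date == date(2010, 9, 17)
        assert lmp.provenance is Provenance.CARRIED_FORWARD

    def test_carry_requires_amenorrhoea_and_no_reported_date(self):
        prev = _lmp(date(2010, 9, 17))
        menstruating = make_ctx(date(2013, 2, 15), previous_attendance=date(2010, 10, 15),
                                previous_lmp=prev, bled_last_12mo=True)
        assert carry_forward(menstruating, dropped_by_prior_check=False) is None
        reported = make_ctx(date(2013, 2, 15), previous_attendance=date(2010, 10, 15),
                            previous_lmp=prev, bled_last_12mo=False, lmp_year=2012)
        assert carry_forward(reported, dropped_by_prior_check=False) is None

    def test_drop_by_prior_check_always_carries(self):
        prev = _lmp(date(2008, 6, 17))
        ctx = make_ctx(date(2015, 10, 15), previous_attendance=date(2013, 5, 15),
                       previous_lmp=prev)
        lmp = carry_forward(ctx, dropped_by_prior_check=True)
        assert lmp.lmp_date == date(2008, 6, 17)
        assert lmp.rule_tag == "cf-i"


class TestPerWavePipeline:
    def test_rejected_second_report_carries_first_assignment(self):
        # timepoint 1: LMP 17 Jun 2008; timepoint 2 reports "31 Feb 2009",
        # which predates the first attendance and is replaced by carry-forward
        prev = _lmp(date(2008, 6, 17))
        ctx = make_ctx(date(2015, 10, 15), previous_attendance=date(2013, 5, 15),
                       previous_lmp=prev, lmp_day=31, lmp_month=2, lmp_year=2009)
        lmp = assign_one(ctx)
        assert lmp.lmp_date == date(2008, 6, 17)
        assert lmp.provenance is Provenance.CARRIED_FORWARD

    def test_future_invalid_report_falls_back_to_bleeding_history(self):
        ctx = make_ctx(SEP, lmp_day=25, lmp_month=10, lmp_year=2012,
                       bled_last_3mo=True, bled_last_12mo=True)
        lmp = assign_one(ctx)
        assert lmp.provenance is Provenance.BLEEDING_3MO
        assert lmp.lmp_date == SEP - timedelta(days=45)

    def test_check_a_drop_falls_back_to_bleeding_history(self):
        # reported date contradicts 3-month bleeding; the 45-day rule applies
        ctx = make_ctx(SEP, lmp_month=1, lmp_year=2012,
                       bled_last_3mo=True, bled_last_12mo=True)
        lmp = assign_one(ctx)
        assert lmp.provenance is Provenance.BLEEDING_3MO


def brute_force_year_only(att: date, year: int, b3, b12) -> date | None:
    """Independent re-derivation: intersect the flag-implied window with the
    reported LMP year and take the midpoint, except that an amenorrhoeic
    report for a year two or more before attendance pins mid-June."""
    if b3 is True:
        b12 = True
    if b3 is None or b12 is None:
        return None
    jan1, dec31 = date(year, 1, 1), date(year, 12, 31)
    if b3:
        lo, hi = att - relativedelta(months=3), att
    elif b12:
        lo, hi = att - relativedelta(months=12), att - relativedelta(months=3)
    else:
        if year >= att.year:
            lo, hi = jan1, att - relativedelta(years=1)  # empty for same-year
        elif year == att.year - 1:
            lo, hi = jan1, att - relativedelta(years=1)
        else:
            return date(year, 6, 15)
    lo, hi = max(lo, jan1), min(hi, dec31)
    if lo > hi:
        return None
    return lo + timedelta(days=(hi - lo).days // 2)


def test_year_only_agrees_with_brute_force_on_exhaustive_grid():
    """Daily 2-year attendance grid x 3 candidate years x 4 flag patterns."""
    start = date(2011, 6, 1)
    n_cases = 0
    for i in range(0, 730, 2):
        att = start + timedelta(days=i)
        for year in (att.year, att.year - 1, att.year - 2):
            for flags in ((False, False), (False, True), (True, True), (True, False)):
                b3, b12 = reconcile_bleeding_flags(*flags)
                ctx = make_ctx(att, lmp_year=year, bled_last_3mo=b3, bled_last_12mo=b12)
                got = assign_lmp_year_only(ctx, year)
                expected = brute_force_year_only(att, year, *flags)
                got_date = got.lmp_date if got else None
                assert got_date == expected, (att, year, flags, got_date, expected)
                n_cases += 1
    assert n_cases >= 2000
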