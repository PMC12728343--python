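"""The LMP assignment engine.

Per wave, in time order, the pipeline is:

1. reported-date path — a complete date is used as-is; month+year gets day 15;
   a year-only report is resolved against the 3-/12-month bleeding history
   (rules 3.1-3.3 below);
2. consistency checks — (a) agreement with the bleeding history within ±3/±6
   month buffers (day/month-precision reports only), (b) a 31-day cap on
   dates after the standardised attendance date, (c) rejection of dates that
   predate the previous timepoint's attendance when that timepoint already
   has an assignment;
3. bleeding-history fallback — with no usable reported date, bleeding within
   3 months places the LMP 45 days before attendance (midpoint of the
   3-month window) and bleeding within 12 but not 3 months places it 228
   days before (midpoint of the 3-to-12-month window);
4. carry-forward — the most recent earlier assignment is re-used when the
   current one was rejected by check (c), or when nothing was reported, the
   woman is amenorrhoeic over 12 months and the previous timepoint is within
   3 years.

Year-only rules (attendance date A, reported LMP year Y, window = the 3
calendar months before A):

* no bleeding in 3 or 12 months — 3.1a: Y is the attendance year: none
  (inconsistent); 3.1b: Y is the year before: midpoint(1 Jan of Y, A − 1
  year); 3.1c: Y earlier still: 15 June of Y.
* bleeding in 12 but not 3 months — 3.2a: same year, window within it:
  midpoint(1 Jan of Y, A − 3 months); 3.2b: previous year, window not
  reaching Y: midpoint(A − 1 year, 31 Dec of Y); 3.2d: previous year, window
  reaching into Y: midpoint(A − 1 year, A − 3 months); 3.2e/f: none.
* bleeding in 3 months — 3.3a: same year, window within it:
  midpoint(A − 3 months, A); 3.3b: same year, window crossing 1 Jan:
  midpoint(1 Jan of Y, A); 3.3c: previous year, window reaching into Y:
  midpoint(A − 3 months, 31 Dec of Y); 3.3d: none.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta

from .config import AlgorithmConfig
from .preprocess import OrderedTrajectory
from .types import AssignedLMP, CensorDecision, Provenance, TimepointObservation
from .dates import midpoint_date, months_before, years_before

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LmpContext:
    """Inputs available when assigning an LMP at one wave."""

    wave: TimepointObservation
    attendance_date: date
    previous_attendance_date: date | None = None
    previous_assigned_lmp: AssignedLMP | None = None
    most_recent_lmp: AssignedLMP | None = None
    config: AlgorithmConfig = AlgorithmConfig()

    def _make(self, lmp_date: date, provenance: Provenance, rule_tag: str) -> AssignedLMP:
        return AssignedLMP(
            participant_id=self.wave.participant_id,
            wave_label=self.wave.wave_label,
            lmp_date=lmp_date,
            provenance=provenance,
            rule_tag=rule_tag,
        )


def assign_from_reported_date(ctx: LmpContext) -> AssignedLMP | None:
    """Rules 1-3: resolve whatever LMP date parts were reported."""
    w = ctx.wave
    if w.lmp_year is None:
        return None
    if w.lmp_month is not None:
        if w.lmp_day is not None:
            try:
                return ctx._make(date(w.lmp_year, w.lmp_month, w.lmp_day),
                                 Provenance.FULL_DATE, "1")
            except ValueError:
                # e.g. a reported "31st February": keep the valid month+year
                log.warning(
                    "participant=%s wave=%s: impossible reported date %04d-%02d-%02d, "
                    "using month+year", w.participant_id, w.wave_label,
                    w.lmp_year, w.lmp_month, w.lmp_day,
                )
        day = ctx.config.attendance_day_of_month
        return ctx._make(date(w.lmp_year, w.lmp_month, day), Provenance.MONTH_YEAR_MID, "2")
    return assign_lmp_year_only(ctx, w.lmp_year)


def assign_lmp_year_only(ctx: LmpContext, lmp_year: int) -> AssignedLMP | None:
    """Rules 3.1-3.3: year-only report resolved via the bleeding history."""
    att = ctx.attendance_date
    b3 = ctx.wave.bled_last_3mo
    b12 = ctx.wave.bled_last_12mo
    cfg = ctx.config
    att_year = att.year
    window_start = months_before(att, cfg.buffer_3mo_months)  # 3 months before A

    def make(d: date, tag: str) -> AssignedLMP:
        return ctx._make(d, Provenance.YEAR_ONLY_RULE, tag)

    if lmp_year > att_year:
        return None
    if b3 is True:
        if lmp_year == att_year:
            if window_start.year == att_year:
                return make(midpoint_date(window_start, att), "3.3a")
            return make(midpoint_date(date(lmp_year, 1, 1), att), "3.3b")
        if lmp_year == att_year - 1 and window_start.year == lmp_year:
            return make(midpoint_date(window_start, date(lmp_year, 12, 31)), "3.3c")
        return None  # 3.3d
    if b3 is False and b12 is True:
        if lmp_year == att_year:
            if window_start.year == att_year:
                return make(midpoint_date(date(lmp_year, 1, 1), window_start), "3.2a")
            return None  # 3.2e
        if lmp_year == att_year - 1:
            one_year_before = years_before(att, 1)
            if window_start.year == att_year:
                return make(midpoint_date(one_year_before, date(lmp_year, 12, 31)), "3.2b")
            return make(midpoint_date(one_year_before, window_start), "3.2d")
        return None  # 3.2f
    if b3 is False and b12 is False:
        if lmp_year == att_year:
            return None  # 3.1a
        if lmp_year == att_year - 1:
            return make(midpoint_date(date(lmp_year, 1, 1), years_before(att, 1)), "3.1b")
        return make(date(lmp_year, 6, 15), "3.1c")
    return None  # bleeding history missing: fall through


def assign_from_bleeding_history(ctx: LmpContext) -> AssignedLMP | None:
    """Rule 4: no usable reported date; place the LMP from the bleeding flags."""
    att = ctx.attendance_date
    b3, b12 = ctx.wave.bled_last_3mo, ctx.wave.bled_last_12mo
    if b3 is True:
        return ctx._make(att - timedelta(days=ctx.config.bleed3_offset_days),
                         Provenance.BLEEDING_3MO, "4a")
    if b3 is False and b12 is True:
        return ctx._make(att - timedelta(days=ctx.config.bleed12_offset_days),
                         Provenance.BLEEDING_12MO, "4b")
    return None  # 4c, or flags missing


def check_bleeding_consistency(lmp: AssignedLMP, ctx: LmpContext) -> bool:
    """Check (a): a day/month-precision date must fit the bleeding history.

    Returns True to keep. Applies only to full-date and month+year reports;
    year-only assignments already embed the bleeding history. The upper
    (future) side is governed by check (b)'s 31-day cap.
    """
    if lmp.provenance not in (Provenance.FULL_DATE, Provenance.MONTH_YEAR_MID):
        return True
    att = ctx.attendance_date
    b3, b12 = ctx.wave.bled_last_3mo, ctx.wave.bled_last_12mo
    cfg = ctx.config
    if b3 is True:
        # within the 3-month window, with a 3-month buffer below it
        return lmp.lmp_date >= months_before(att, cfg.buffer_3mo_months * 2)
    if b3 is False and b12 is True:
        # window [A-12m, A-3m] with a ±6-month buffer
        lo = months_before(att, 12 + cfg.buffer_12mo_months)
        hi = att + timedelta(days=cfg.future_cap_days)  # +3m buffer capped by check (b)
        return lo <= lmp.lmp_date <= hi
    if b12 is False:
        # amenorrhoeic: LMP at least 12 months ago, 6-month buffer allowed
        return lmp.lmp_date <= months_before(att, cfg.min_gap_no_bleed_months)
    return True  # no bleeding history to check against


def check_future_date(lmp: AssignedLMP, ctx: LmpContext) -> bool:
    """Check (b): keep iff the date is at most 31 days after attendance."""
    return lmp.lmp_date <= ctx.attendance_date + timedelta(days=ctx.config.future_cap_days)


def check_prior_timepoint(lmp: AssignedLMP, ctx: LmpContext) -> bool:
    """Check (c): reject dates before the previous timepoint's attendance.

    The rejection only applies when the previous timepoint itself has an
    assigned LMP — the estimate most proximal to its reporting period wins.
    """
    if ctx.previous_attendance_date is None or ctx.previous_assigned_lmp is None:
        return True
    return lmp.lmp_date >= ctx.previous_attendance_date


def carry_forward(ctx: LmpContext, *, dropped_by_prior_check: bool) -> AssignedLMP | None:
    """Re-use the most recent earlier assignment in the two permitted scenarios.

    (i) the current assignment was rejected by check (c); (ii) no LMP date
    part was reported, no bleeding in the last 12 months, and the previous
    timepoint is within the carry-forward limit (3 years).
    """
    recent = ctx.most_recent_lmp
    if recent is None:
        return None
    if dropped_by_prior_check:
        return ctx._make(recent.lmp_date, Provenance.CARRIED_FORWARD, "cf-i")
    w = ctx.wave
    no_report = w.lmp_year is None and w.lmp_month is None and w.lmp_day is None
    if (
        no_report
        and w.bled_last_12mo is False
        and ctx.previous_attendance_date is not None
        and ctx.previous_attendance_date
        >= years_before(ctx.attendance_date, ctx.config.carry_forward_limit_years)
    ):
        return ctx._make(recent.lmp_date, Provenance.CARRIED_FORWARD, "cf-ii")
    return None


def assign_one(ctx: LmpContext, audit: list[dict] | None = None) -> AssignedLMP | None:
    """Run the full per-wave pipeline; optionally append an audit record."""
    record: dict = {
        "participant_id": ctx.wave.participant_id,
        "wave_label": ctx.wave.wave_label,
        "attendance_date": ctx.attendance_date.isoformat(),
    }
    dropped_by_c = False
    future_invalid = False
    lmp = assign_from_reported_date(ctx)
    record["reported_date_stage"] = lmp.rule_tag if lmp else None
    if lmp is not None and not check_bleeding_consistency(lmp, ctx):
        record["check_a"] = "drop"
        lmp = None
    if lmp is not None and not check_future_date(lmp, ctx):
        record["check_b"] = "invalidate"
        lmp = None
        future_invalid = True
    if lmp is not None and not check_prior_timepoint(lmp, ctx):
        record["check_c"] = "drop"
        lmp = None
        dropped_by_c = True
    if lmp is None and not dropped_by_c:
        no_report = ctx.wave.lmp_year is None and ctx.wave.lmp_month is None and ctx.wave.lmp_day is None
        dropped_by_a = record.get("check_a") == "drop"
        if no_report or future_invalid or dropped_by_a:
            lmp = assign_from_bleeding_history(ctx)
            record["bleeding_history_stage"] = lmp.rule_tag if lmp else None
            if lmp is not None and not check_prior_timepoint(lmp, ctx):
                record["check_c"] = "drop"
                lmp = None
                dropped_by_c = True
    if lmp is None:
        lmp = carry_forward(ctx, dropped_by_prior_check=dropped_by_c)
        record["carry_forward"] = lmp.rule_tag if lmp else None
    record["assigned"] = lmp.lmp_date.isoformat() if lmp else None
    record["rule_tag"] = lmp.rule_tag if lmp else None
    if audit is not None:
        audit.append(record)
    return lmp


def assign_all(
    trajectory: OrderedTrajectory,
    censors: list[CensorDecision],
    config: AlgorithmConfig | None = None,
    audit: list[dict] | None = None,
) -> list[AssignedLMP]:
    """Assign LMP dates at every retained (non-censored) wave, in time order."""
    config = config or AlgorithmConfig()
    censored_waves = {c.wave_label for c in censors}
    out: list[AssignedLMP] = []
    prev_att: date | None = None
    prev_lmp: AssignedLMP | None = None
    recent: AssignedLMP | None = None
    for wave, att in zip(trajectory.waves, trajectory.attendance_dates):
        if wave.wave_label in censored_waves:
            continue
        ctx = LmpContext(
            wave=wave,
            attendance_date=att,
            previous_attendance_date=prev_att,
            previous_assigned_lmp=prev_lmp,
            most_recent_lmp=recent,
            config=config,
        )
        lmp = assign_one(ctx, audit)
        if lmp is not None:
            out.append(lmp)
            recent = lmp
        prev_att, prev_lmp = att, lmp
    return out
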