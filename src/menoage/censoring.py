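"""Surgery resolution and wave censoring.

Menstruation-ending surgery (hysterectomy and/or bilateral oophorectomy,
reported either as an operation or as a cessation reason) is resolved to a
single earliest event per woman. Waves from that event onward are censored,
as are waves reporting current hormonal contraception or HRT, or a
non-menopausal cessation cause (chemo/radiotherapy, ablation/resection,
pregnancy/breastfeeding, contraception, other). Waves preceding surgery stay
usable. A woman who explicitly reports surgery but never provides a date or
age anywhere is excluded outright.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date

from .dates import age_at_date, date_at_age
from .preprocess import OrderedTrajectory
from .types import (
    CENSORING_CESSATION_REASONS,
    CESSATION_PROCEDURES,
    SURGICAL_CESSATION_REASONS,
    CensorDecision,
    CensorReason,
    SurgeryReport,
    TimepointObservation,
)

log = logging.getLogger(__name__)


class SurgeryOutcome:
    NONE = "none"
    CENSOR_FROM_DATE = "censor_from_date"
    EXCLUDE_PARTICIPANT = "exclude_participant"


@dataclass(frozen=True)
class SurgeryResolution:
    participant_id: str
    outcome: str = SurgeryOutcome.NONE
    surgery_date: date | None = None
    surgery_age: float | None = None
    proxy: bool = False

    def __post_init__(self) -> None:
        if self.outcome == SurgeryOutcome.CENSOR_FROM_DATE:
            if self.surgery_date is None and self.surgery_age is None:
                raise ValueError("censor_from_date requires a surgery date or age")


def _report_date(report: SurgeryReport, day: int = 15) -> date | None:
    if report.surgery_year is None:
        return None
    month = report.surgery_month if report.surgery_month is not None else 6
    return date(report.surgery_year, month, day)


def resolve_surgery(
    reports: list[SurgeryReport],
    cessation_waves: list[tuple[TimepointObservation, date]],
    participant_id: str | None = None,
) -> SurgeryResolution:
    """Collapse all surgery evidence for one woman into a single resolution.

    ``cessation_waves`` pairs each observation with its standardised
    attendance date; waves whose cessation reasons include surgery,
    hysterectomy or oophorectomy contribute a proxy event at that attendance
    date (no operation date was asked for those items). Dated events are
    compared on the date scale and the earliest wins; an age-only report is
    kept as an age and converted downstream. An explicit operation report
    with no date or age anywhere excludes the participant.
    """
    relevant = [r for r in reports if r.procedure in CESSATION_PROCEDURES]
    if participant_id is None:
        if relevant:
            participant_id = relevant[0].participant_id
        elif cessation_waves:
            participant_id = cessation_waves[0][0].participant_id
        else:
            raise ValueError("participant_id required when no evidence is supplied")

    dated: list[tuple[date | None, float | None, bool]] = []  # (date, age, proxy)
    for r in relevant:
        d = _report_date(r)
        if d is not None or r.surgery_age is not None:
            dated.append((d, r.surgery_age, False))
    for obs, att in cessation_waves:
        if obs.cessation_reasons & SURGICAL_CESSATION_REASONS:
            dated.append((att, obs.age_at_attendance, True))

    if dated:
        # earliest event; date-bearing events ordered by date, age-only events
        # by age (converted downstream); dates win ties per finer granularity
        def sort_key(item: tuple[date | None, float | None, bool]):
            d, age, _ = item
            return (d is None, d or date.min, age if age is not None else float("inf"))

        d, age, proxy = sorted(dated, key=sort_key)[0]
        return SurgeryResolution(
            participant_id, SurgeryOutcome.CENSOR_FROM_DATE,
            surgery_date=d, surgery_age=age, proxy=proxy,
        )
    if any(r.explicit_report for r in relevant):
        log.info("participant=%s: surgery reported without date or age -> excluded",
                 participant_id)
        return SurgeryResolution(participant_id, SurgeryOutcome.EXCLUDE_PARTICIPANT)
    return SurgeryResolution(participant_id)


def effective_surgery_date(
    surgery: SurgeryResolution, birth_reference: date | None
) -> date | None:
    """Surgery date on the calendar scale, converting an age-only report."""
    if surgery.outcome != SurgeryOutcome.CENSOR_FROM_DATE:
        return None
    if surgery.surgery_date is not None:
        return surgery.surgery_date
    if birth_reference is not None and surgery.surgery_age is not None:
        return date_at_age(birth_reference, surgery.surgery_age)
    return None


def effective_surgery_age(
    surgery: SurgeryResolution, birth_reference: date | None
) -> float | None:
    if surgery.outcome != SurgeryOutcome.CENSOR_FROM_DATE:
        return None
    if surgery.surgery_age is not None:
        return surgery.surgery_age
    if birth_reference is not None and surgery.surgery_date is not None:
        return age_at_date(birth_reference, surgery.surgery_date)
    return None


def censor_waves(
    trajectory: OrderedTrajectory,
    surgery: SurgeryResolution,
    birth_reference: date | None = None,
) -> list[CensorDecision]:
    """Censor waves affected by surgery, hormones or other cessation causes.

    Surgery censoring is monotone: every wave at or after the surgery date is
    censored. One decision per wave, with the first applicable reason in the
    order post-surgery > contraception > HRT > other-cessation.
    """
    cutoff = effective_surgery_date(surgery, birth_reference)
    decisions: list[CensorDecision] = []
    for wave, att in zip(trajectory.waves, trajectory.attendance_dates):
        reason: CensorReason | None = None
        if cutoff is not None and att >= cutoff:
            reason = CensorReason.SURGERY_PROXY if surgery.proxy else CensorReason.POST_SURGERY
        elif wave.current_contraception is True:
            reason = CensorReason.CONTRACEPTION
        elif wave.current_hrt is True:
            reason = CensorReason.HRT
        elif wave.cessation_reasons & CENSORING_CESSATION_REASONS:
            reason = CensorReason.OTHER_CESSATION
        if reason is not None:
            decisions.append(CensorDecision(wave.participant_id, wave.wave_label, reason))
    return decisions
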