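"""Final classification: postmenopausal status and age at natural menopause.

The algorithm path declares the final menstrual period (FMP) when a woman's
most recent assigned LMP lies more than 365 days before her last retained
attendance; age at menopause is then her age at that LMP. Self-reported ages
(the maximum across qualifying questionnaire items) provide a fallback when
the algorithm yields no age, subject to a two-year plausibility window
against the most recent LMP and invalidation by any surgery at or before the
reported age. When both paths produce an age the algorithm wins, being less
exposed to recall bias.

Dates and reported ages are compared on one continuous scale through a
per-woman birth reference: the mean, over waves, of attendance date minus
age at attendance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta

from .censoring import SurgeryResolution, effective_surgery_age
from .config import AlgorithmConfig
from .dates import DAYS_PER_YEAR, age_at_date
from .preprocess import OrderedTrajectory
from .types import (
    AssignedLMP,
    EstimateMethod,
    MenopauseEstimate,
    MenopauseStatus,
    TimepointObservation,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BirthReference:
    participant_id: str
    reference_birth_date: date


@dataclass(frozen=True)
class SelfReportAge:
    participant_id: str
    age: float
    source: str


def derive_birth_reference(trajectory: OrderedTrajectory) -> BirthReference | None:
    """Mean of (attendance date − age at attendance) over waves with an age.

    Returns None when no wave carries an age: the woman is then unclassifiable
    by the algorithm path. Waves implying birth dates more than a year apart
    are flagged but still averaged.
    """
    implied: list[date] = []
    for wave, att in zip(trajectory.waves, trajectory.attendance_dates):
        if wave.age_at_attendance is not None:
            implied.append(att - timedelta(days=round(wave.age_at_attendance * DAYS_PER_YEAR)))
    if not implied:
        return None
    ordinals = [d.toordinal() for d in implied]
    if max(ordinals) - min(ordinals) > DAYS_PER_YEAR:
        log.warning(
            "participant=%s: reported ages imply birth dates %.1f years apart; using mean",
            trajectory.participant_id, (max(ordinals) - min(ordinals)) / DAYS_PER_YEAR,
        )
    mean = round(sum(ordinals) / len(ordinals))
    return BirthReference(trajectory.participant_id, date.fromordinal(mean))


def classify_fmp(
    lmps: list[AssignedLMP],
    trajectory: OrderedTrajectory,
    reference: BirthReference | None,
    config: AlgorithmConfig | None = None,
    last_attendance: date | None = None,
) -> MenopauseEstimate:
    """Algorithm path: amenorrhoea > 365 days at the last wave defines the FMP.

    ``last_attendance`` is the attendance date of the last retained
    (non-censored) wave; it defaults to the trajectory's last wave.
    """
    config = config or AlgorithmConfig()
    pid = trajectory.participant_id
    if not lmps:
        return MenopauseEstimate(pid, MenopauseStatus.NOT_CLASSIFIABLE)
    last = max(lmps, key=lambda l: l.lmp_date)
    att = last_attendance if last_attendance is not None else trajectory.attendance_dates[-1]
    if (att - last.lmp_date).days > config.fmp_threshold_days:
        if reference is None:
            return MenopauseEstimate(pid, MenopauseStatus.NOT_CLASSIFIABLE)
        return MenopauseEstimate(
            pid,
            MenopauseStatus.POSTMENOPAUSAL,
            age_at_menopause=age_at_date(reference.reference_birth_date, last.lmp_date),
            fmp_date=last.lmp_date,
            method=EstimateMethod.ALGORITHM,
        )
    return MenopauseEstimate(pid, MenopauseStatus.PREMENOPAUSAL_AT_LAST_WAVE)


def collect_self_report_age(
    waves: list[TimepointObservation], config: AlgorithmConfig | None = None
) -> SelfReportAge | None:
    """Maximum qualifying self-reported age across questionnaires.

    Age-at-last-period items qualify only when at least one year below the
    age at reporting (a recent LMP is not a menopause report); direct
    age-at-menopause items qualify unconditionally.
    """
    config = config or AlgorithmConfig()
    best: SelfReportAge | None = None
    for w in waves:
        candidates: list[float] = []
        if w.self_reported_age_at_menopause is not None:
            candidates.append(w.self_reported_age_at_menopause)
        if w.self_reported_age_at_lmp is not None and w.age_at_attendance is not None:
            if w.self_reported_age_at_lmp <= w.age_at_attendance - config.min_self_report_lag_years:
                candidates.append(w.self_reported_age_at_lmp)
        for age in candidates:
            if best is None or age > best.age:
                best = SelfReportAge(w.participant_id, age, w.wave_label)
    return best


def validate_self_report(
    sr: SelfReportAge,
    lmps: list[AssignedLMP],
    surgery: SurgeryResolution | None,
    reference: BirthReference | None,
    config: AlgorithmConfig | None = None,
) -> bool:
    """True to keep: within two years of the most recent LMP, before surgery."""
    config = config or AlgorithmConfig()
    if lmps and reference is not None:
        age_at_recent = age_at_date(
            reference.reference_birth_date, max(l.lmp_date for l in lmps)
        )
        if sr.age < age_at_recent - config.self_report_tolerance_years:
            return False
    if surgery is not None:
        surgery_age = effective_surgery_age(surgery, reference.reference_birth_date if reference else None)
        if surgery_age is not None and sr.age >= surgery_age:
            return False
    return True


def finalize_estimate(
    algorithm: MenopauseEstimate, sr: SelfReportAge | None
) -> MenopauseEstimate:
    """Prioritise the algorithm age; fall back to a validated self-report."""
    if algorithm.method is EstimateMethod.ALGORITHM:
        return algorithm
    if sr is not None:
        return MenopauseEstimate(
            algorithm.participant_id,
            MenopauseStatus.POSTMENOPAUSAL,
            age_at_menopause=sr.age,
            method=EstimateMethod.SELF_REPORT,
        )
    return algorithm
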