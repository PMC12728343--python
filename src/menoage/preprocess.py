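"""Wave ordering, duplicate resolution and bleeding-flag reconciliation.

Raw observations for one woman are turned into an :class:`OrderedTrajectory`:
attendance dates standardised to the 15th, waves sorted in time, clinic
records preferred over questionnaires completed in the same month, and the
3-/12-month bleeding flags recoded for internal consistency (a report of
bleeding within 3 months forces the 12-month answer to yes — the minimal
logically forced recode; no other combination is touched, and absence of an
answer never becomes evidence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from datetime import date

from .config import AlgorithmConfig
from .dates import standardize_attendance_date
from .types import SourceKind, TimepointObservation

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrderedTrajectory:
    """One woman's retained waves, sorted by standardised attendance date."""

    participant_id: str
    waves: tuple[TimepointObservation, ...]
    attendance_dates: tuple[date, ...]

    def __len__(self) -> int:
        return len(self.waves)


def reconcile_bleeding_flags(
    bled3: bool | None, bled12: bool | None
) -> tuple[bool | None, bool | None]:
    """Force the 12-month answer to yes when 3-month bleeding was reported.

    Bleeding within the last 3 months logically entails bleeding within the
    last 12, so (yes, no) and (yes, missing) both become (yes, yes). No other
    combination changes: a yes is never demoted and a missing 3-month answer
    is never inferred from the 12-month one.
    """
    if bled3 is True and bled12 is not True:
        return True, True
    return bled3, bled12


def resolve_same_month_duplicates(
    waves: list[TimepointObservation],
) -> list[TimepointObservation]:
    """Keep the clinic record when a clinic visit and questionnaire share a month.

    Two records of the same kind in one month are not expected; the first by
    wave_label lexical order is kept with a warning.
    """
    by_month: dict[tuple[int, int], list[TimepointObservation]] = {}
    for w in waves:
        by_month.setdefault((w.attendance_year, w.attendance_month), []).append(w)
    kept: list[TimepointObservation] = []
    for key in sorted(by_month):
        group = sorted(by_month[key], key=lambda w: (w.source_kind is not SourceKind.CLINIC, w.wave_label))
        clinics = [w for w in group if w.source_kind is SourceKind.CLINIC]
        if len(clinics) > 1 or (not clinics and len(group) > 1):
            log.warning(
                "DEDUP participant=%s month=%04d-%02d: %d same-kind records, keeping wave %s",
                group[0].participant_id, key[0], key[1], len(group), group[0].wave_label,
            )
        kept.append(group[0])
    return kept


def build_trajectory(
    waves: list[TimepointObservation], config: AlgorithmConfig | None = None
) -> OrderedTrajectory:
    """Standardise, deduplicate, reconcile and order one woman's waves."""
    config = config or AlgorithmConfig()
    if not waves:
        raise ValueError("build_trajectory requires at least one observation")
    pid = waves[0].participant_id
    if any(w.participant_id != pid for w in waves):
        raise ValueError("all waves must belong to one participant")
    retained = resolve_same_month_duplicates(list(waves))
    reconciled = []
    for w in retained:
        b3, b12 = reconcile_bleeding_flags(w.bled_last_3mo, w.bled_last_12mo)
        if (b3, b12) != (w.bled_last_3mo, w.bled_last_12mo):
            log.info(
                "RECODE participant=%s wave=%s: bleeding flags (%s, %s) -> (%s, %s)",
                pid, w.wave_label, w.bled_last_3mo, w.bled_last_12mo, b3, b12,
            )
            w = replace(w, bled_last_3mo=b3, bled_last_12mo=b12)
        reconciled.append(w)
    reconciled.sort(key=lambda w: (w.attendance_year, w.attendance_month, w.wave_label))
    dates = tuple(
        standardize_attendance_date(w.attendance_month, w.attendance_year,
                                    config.attendance_day_of_month)
        for w in reconciled
    )
    return OrderedTrajectory(pid, tuple(reconciled), dates)
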