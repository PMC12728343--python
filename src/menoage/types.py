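"""Domain types for raw observations and derived results.

The interchange model is long-format: one :class:`TimepointObservation` per
participant-wave, carrying the three key menstrual-history items (self-reported
LMP date parts, bleeding in the last 3 months, bleeding in the last 12 months)
together with cessation reasons, hormone-use flags and self-reported ages.
Tri-state yes/no items are held as ``Optional[bool]`` — ``None`` means the item
was not answered and is never coerced to "no": the blank-vs-no distinction
drives both the bleeding rules and censoring.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date


class SourceKind(str, enum.Enum):
    CLINIC = "clinic"
    QUESTIONNAIRE = "questionnaire"


class CessationReason(str, enum.Enum):
    """Reported cause of period cessation (asked when no bleeding in 12 months)."""

    SURGERY = "surgery"
    HYSTERECTOMY = "hysterectomy"
    OOPHORECTOMY = "oophorectomy"
    ABLATION_RESECTION = "ablation_resection"
    CHEMO_RADIO = "chemo_radio"
    PREGNANCY_BREASTFEEDING = "pregnancy_breastfeeding"
    MENOPAUSE = "menopause"
    CONTRACEPTION = "contraception"
    OTHER = "other"


#: Cessation-reason codes taken to imply menstruation-ending surgery.
SURGICAL_CESSATION_REASONS = frozenset(
    {CessationReason.SURGERY, CessationReason.HYSTERECTOMY, CessationReason.OOPHORECTOMY}
)

#: Cessation-reason codes that censor the reporting wave outright.
CENSORING_CESSATION_REASONS = frozenset(
    {
        CessationReason.CHEMO_RADIO,
        CessationReason.ABLATION_RESECTION,
        CessationReason.PREGNANCY_BREASTFEEDING,
        CessationReason.OTHER,
        CessationReason.CONTRACEPTION,
    }
)


class Procedure(str, enum.Enum):
    """Reproductive-organ operations from the surgery-history question."""

    HYST_BSO = "hyst_bso"  # hysterectomy + bilateral oophorectomy
    HYST_ONLY = "hyst_only"
    HYST_USO = "hyst_uso"  # hysterectomy + unilateral oophorectomy
    BSO_ONLY = "bso_only"
    USO_ONLY = "uso_only"  # one ovary only: menstruation continues


#: Procedures that end menstruation (unilateral oophorectomy alone does not).
CESSATION_PROCEDURES = frozenset(
    {Procedure.HYST_BSO, Procedure.HYST_ONLY, Procedure.HYST_USO, Procedure.BSO_ONLY}
)


class Provenance(str, enum.Enum):
    """Which stage of the LMP algorithm produced an assigned date."""

    FULL_DATE = "full_date"
    MONTH_YEAR_MID = "month_year_mid"
    YEAR_ONLY_RULE = "year_only_rule"
    BLEEDING_3MO = "bleeding_3mo"
    BLEEDING_12MO = "bleeding_12mo"
    CARRIED_FORWARD = "carried_forward"


class CensorReason(str, enum.Enum):
    POST_SURGERY = "post_surgery"
    SURGERY_PROXY = "surgery_proxy"
    CONTRACEPTION = "contraception"
    HRT = "hrt"
    OTHER_CESSATION = "other_cessation"


class MenopauseStatus(str, enum.Enum):
    POSTMENOPAUSAL = "postmenopausal"
    NOT_CLASSIFIABLE = "not_classifiable"
    PREMENOPAUSAL_AT_LAST_WAVE = "premenopausal_at_last_wave"
    EXCLUDED = "excluded"


class EstimateMethod(str, enum.Enum):
    ALGORITHM = "algorithm"
    SELF_REPORT = "self_report"
    NONE = "none"


class ConfigurationError(ValueError):
    """Malformed column map or missing mandatory columns."""


@dataclass(frozen=True)
class TimepointObservation:
    """One participant-wave record of raw reproductive-health responses."""

    participant_id: str
    wave_label: str
    source_kind: SourceKind
    attendance_month: int
    attendance_year: int
    age_at_attendance: float | None = None
    lmp_day: int | None = None
    lmp_month: int | None = None
    lmp_year: int | None = None
    bled_last_3mo: bool | None = None
    bled_last_12mo: bool | None = None
    cessation_reasons: frozenset[CessationReason] = field(default_factory=frozenset)
    current_contraception: bool | None = None
    current_hrt: bool | None = None
    self_reported_age_at_lmp: float | None = None
    self_reported_age_at_menopause: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.attendance_month <= 12:
            raise ValueError(
                f"attendance_month must be 1-12, got {self.attendance_month!r} "
                f"(participant {self.participant_id}, wave {self.wave_label})"
            )


@dataclass(frozen=True)
class SurgeryReport:
    """One report of a reproductive-organ operation, from any wave.

    A report must carry at least one of: an explicit yes answer, a surgery
    date (month/year) or an age at surgery.
    """

    participant_id: str
    wave_label: str
    procedure: Procedure
    explicit_report: bool = True
    surgery_month: int | None = None
    surgery_year: int | None = None
    surgery_age: float | None = None

    def __post_init__(self) -> None:
        if not self.explicit_report and self.surgery_year is None and self.surgery_age is None:
            raise ValueError(
                "surgery report with neither explicit flag nor date nor age is invalid "
                f"(participant {self.participant_id}, wave {self.wave_label})"
            )


@dataclass(frozen=True)
class AssignedLMP:
    """A resolved LMP calendar date with provenance for one wave."""

    participant_id: str
    wave_label: str
    lmp_date: date
    provenance: Provenance
    rule_tag: str


@dataclass(frozen=True)
class CensorDecision:
    """A wave removed from LMP estimation, with coded reason."""

    participant_id: str
    wave_label: str
    reason: CensorReason


@dataclass(frozen=True)
class MenopauseEstimate:
    """Final per-woman classification and, when postmenopausal, age at FMP."""

    participant_id: str
    status: MenopauseStatus
    age_at_menopause: float | None = None
    fmp_date: date | None = None
    method: EstimateMethod = EstimateMethod.NONE

    def __post_init__(self) -> None:
        has_age = self.age_at_menopause is not None
        if has_age != (self.status is MenopauseStatus.POSTMENOPAUSAL):
            raise ValueError("age_at_menopause present iff status is postmenopausal")
        if (self.method is EstimateMethod.NONE) == has_age:
            raise ValueError("method is none iff no age was assigned")
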