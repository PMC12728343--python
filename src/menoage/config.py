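"""Algorithm and simulation configuration.

Every numeric constant of the LMP/menopause algorithm lives in
:class:`AlgorithmConfig` so that the rules are auditable in one place:
the 45- and 228-day bleeding-history offsets, the ±3/±6 month consistency
buffers, the 31-day future-date cap, the 3-year carry-forward window, the
365-day final-menstrual-period threshold and the self-report tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Any, Mapping


@dataclass(frozen=True)
class AlgorithmConfig:
    #: day substituted for the unreleased day-of-month of attendance dates
    attendance_day_of_month: int = 15
    #: assigned LMP may fall at most this many days after attendance
    future_cap_days: int = 31
    #: no-date fallback when bleeding in last 3 months (midpoint of window)
    bleed3_offset_days: int = 45
    #: no-date fallback when bleeding in last 12 but not 3 months
    bleed12_offset_days: int = 228
    #: reporting-error buffer on the 3-month bleeding window (months)
    buffer_3mo_months: int = 3
    #: wider buffer on the 12-month window (months)
    buffer_12mo_months: int = 6
    #: amenorrhoeic reports require the LMP at least this long before attendance
    min_gap_no_bleed_months: int = 6
    #: maximum gap to the previous timepoint for carry-forward scenario (ii)
    carry_forward_limit_years: int = 3
    #: amenorrhoea longer than this at the last wave defines the FMP
    fmp_threshold_days: int = 365
    #: self-reported age may be at most this much below age at most recent LMP
    self_report_tolerance_years: int = 2
    #: age-at-LMP items must lag current age by at least this much
    min_self_report_lag_years: int = 1

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")
        if self.fmp_threshold_days < 365:
            raise ValueError("fmp_threshold_days below one year is not meaningful")
        if not 1 <= self.attendance_day_of_month <= 28:
            raise ValueError("attendance_day_of_month must be a day every month has")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any] | None) -> "AlgorithmConfig":
        if not mapping:
            return cls()
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown algorithm config keys: {sorted(unknown)}")
        return cls(**{k: int(v) for k, v in mapping.items()})


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for the synthetic cohort generator.

    Defaults emulate the source cohort's structure: up to eight waves at mean
    ages ~47-58, partial response, mixed LMP reporting granularity, recall
    error, hormone-use masking and occasional surgery.
    """

    n_participants: int = 1000
    seed: int = 0
    menopause_age_mean: float = 50.5
    menopause_age_sd: float = 4.0
    #: truncation range for the menopause-age distribution (years)
    menopause_age_range: tuple[float, float] = (30.0, 63.0)
    #: target ages at the successive waves, relative to birth
    wave_age_offsets: tuple[float, ...] = (47.4, 48.6, 49.7, 50.3, 51.3, 51.6, 52.6, 57.7)
    #: which waves are clinic visits (others are postal questionnaires)
    clinic_waves: tuple[int, ...] = (0, 3, 5, 6)
    #: probability a woman responds at any given wave
    response_prob: float = 0.45
    #: reporting granularity of the LMP date when one is given
    date_granularity_probs: Mapping[str, float] = field(
        default_factory=lambda: {"full": 0.60, "month_year": 0.25, "year_only": 0.10, "none": 0.05}
    )
    #: SD of integer-day recall noise added to the true LMP before truncation
    recall_error_sd_days: float = 30.0
    #: probability a woman ever uses hormonal contraception/HRT in follow-up
    hormone_use_prob: float = 0.15
    #: mean episode length of hormone use (years, exponential)
    hormone_episode_mean_years: float = 3.0
    #: probability of menstruation-ending surgery during follow-up
    surgery_prob: float = 0.05
    surgery_age_mean: float = 45.0
    surgery_age_sd: float = 5.0
    #: probability a 3- or 12-month bleeding flag contradicts the truth
    flag_error_prob: float = 0.02
    #: probability a postmenopausal woman answers the self-reported age items
    self_report_prob: float = 0.5
    #: mean cycle length used to place the true LMP before the FMP (days)
    cycle_length_days: int = 28

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be non-negative")
        probs = [self.response_prob, self.hormone_use_prob, self.surgery_prob,
                 self.flag_error_prob, self.self_report_prob]
        probs += list(self.date_granularity_probs.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.date_granularity_probs.values()) - 1.0) > 1e-9:
            raise ValueError("date_granularity_probs must sum to 1")
        if set(self.date_granularity_probs) != {"full", "month_year", "year_only", "none"}:
            raise ValueError("date_granularity_probs keys must be full/month_year/year_only/none")
        if list(self.wave_age_offsets) != sorted(self.wave_age_offsets):
            raise ValueError("wave_age_offsets must be increasing")
        if self.recall_error_sd_days < 0 or self.menopause_age_sd <= 0:
            raise ValueError("scale parameters must be positive")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any] | None) -> "SimulationConfig":
        if not mapping:
            return cls()
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        for key in ("wave_age_offsets", "clinic_waves", "menopause_age_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)
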