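from __future__ import annotations

from datetime import date

import pytest

from menoage import (
    AlgorithmConfig,
    SourceKind,
    TimepointObservation,
    generate_cohort,
    run_pipeline,
)
from menoage.config import SimulationConfig
from menoage.lmp import LmpContext


def make_obs(
    participant_id: str = "p1",
    wave_label: str = "W0",
    month: int = 9,
    year: int = 2012,
    source: SourceKind = SourceKind.QUESTIONNAIRE,
    **kwargs,
) -> TimepointObservation:
    return TimepointObservation(
        participant_id=participant_id,
        wave_label=wave_label,
        source_kind=source,
        attendance_month=month,
        attendance_year=year,
        **kwargs,
    )


def make_ctx(
    attendance: date,
    previous_attendance: date | None = None,
    previous_lmp=None,
    most_recent_lmp=None,
    config: AlgorithmConfig | None = None,
    **obs_kwargs,
) -> LmpContext:
    obs = make_obs(month=attendance.month, year=attendance.year, **obs_kwargs)
    return LmpContext(
        wave=obs,
        attendance_date=attendance,
        previous_attendance_date=previous_attendance,
        previous_assigned_lmp=previous_lmp,
        most_recent_lmp=most_recent_lmp if most_recent_lmp is not None else previous_lmp,
        config=config or AlgorithmConfig(),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """A default-settings synthetic cohort shared by the randomized suites."""
    return generate_cohort(SimulationConfig(n_participants=1000, seed=11))


@pytest.fixture(scope="session")
def default_cohort_result(default_cohort):
    return run_pipeline(
        default_cohort.observations, default_cohort.surgery_reports, collect_audit=False
    )
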