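"""End-to-end orchestration: preprocess, censor, assign LMPs, classify.

Per woman: order and deduplicate waves, derive the birth reference, resolve
surgery, censor affected waves, run the LMP engine over retained waves, then
classify menopausal status and reconcile with self-reports. The
:class:`FlowSummary` partitions every participant into exactly one terminal
category: excluded (surgery without date/age), age assigned (algorithm or
self-report), still menstruating at the last wave, or amenorrhoeic with
insufficient data.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Any, Iterable

import pandas as pd

from .censoring import SurgeryOutcome, SurgeryResolution, censor_waves, resolve_surgery
from .config import AlgorithmConfig
from .derivation import (
    classify_fmp,
    collect_self_report_age,
    derive_birth_reference,
    finalize_estimate,
    validate_self_report,
)
from .lmp import assign_all
from .preprocess import build_trajectory
from .types import (
    AssignedLMP,
    CensorDecision,
    EstimateMethod,
    MenopauseEstimate,
    MenopauseStatus,
    SurgeryReport,
    TimepointObservation,
)


@dataclass
class FlowSummary:
    """Participant counts at each stage of the pipeline."""

    enrolled: int = 0
    responded_any: int = 0
    excluded_surgery_no_date: int = 0
    retained_after_censoring: int = 0
    any_lmp_assigned: int = 0
    age_assigned_total: int = 0
    age_by_method: dict[str, int] = field(
        default_factory=lambda: {"algorithm": 0, "self_report": 0, "both": 0}
    )
    unclassified: dict[str, int] = field(
        default_factory=lambda: {"recent_lmp": 0, "amenorrhoeic_insufficient": 0}
    )

    def to_dict(self) -> dict[str, Any]:
        return {
            "enrolled": self.enrolled,
            "responded_any": self.responded_any,
            "excluded_surgery_no_date": self.excluded_surgery_no_date,
            "retained_after_censoring": self.retained_after_censoring,
            "any_lmp_assigned": self.any_lmp_assigned,
            "age_assigned_total": self.age_assigned_total,
            "age_by_method": dict(self.age_by_method),
            "unclassified": dict(self.unclassified),
        }


@dataclass(frozen=True)
class ParticipantResult:
    estimate: MenopauseEstimate
    lmps: tuple[AssignedLMP, ...]
    censors: tuple[CensorDecision, ...]
    surgery: SurgeryResolution
    had_valid_self_report: bool
    last_retained_bled_12mo: bool | None
    n_retained_waves: int = 0


@dataclass(frozen=True)
class PipelineResult:
    estimates: tuple[MenopauseEstimate, ...]
    lmps: tuple[AssignedLMP, ...]
    censors: tuple[CensorDecision, ...]
    flow: FlowSummary
    audit: tuple[dict, ...]

    def age_histogram(self, bin_width: float = 1.0) -> pd.DataFrame:
        """Age-at-menopause histogram as (bin_low, bin_high, count) rows."""
        ages = [e.age_at_menopause for e in self.estimates if e.age_at_menopause is not None]
        if not ages:
            return pd.DataFrame(columns=["bin_low", "bin_high", "count"])
        lo = int(min(ages) // bin_width) * bin_width
        hi = int(max(ages) // bin_width) * bin_width + bin_width
        edges = []
        x = lo
        while x < hi:
            edges.append((x, x + bin_width))
            x += bin_width
        rows = [
            {
                "bin_low": a,
                "bin_high": b,
                "count": sum(1 for age in ages if a <= age < b),
            }
            for a, b in edges
        ]
        return pd.DataFrame(rows)


def derive_participant(
    waves: list[TimepointObservation],
    surgery_reports: list[SurgeryReport],
    config: AlgorithmConfig | None = None,
    audit: list[dict] | None = None,
) -> ParticipantResult:
    """Run the full algorithm for one woman."""
    config = config or AlgorithmConfig()
    trajectory = build_trajectory(waves, config)
    pid = trajectory.participant_id
    reference = derive_birth_reference(trajectory)
    surgery = resolve_surgery(
        surgery_reports, list(zip(trajectory.waves, trajectory.attendance_dates)), pid
    )
    if surgery.outcome == SurgeryOutcome.EXCLUDE_PARTICIPANT:
        return ParticipantResult(
            MenopauseEstimate(pid, MenopauseStatus.EXCLUDED),
            (), (), surgery, False, None, 0,
        )
    birth = reference.reference_birth_date if reference else None
    censors = censor_waves(trajectory, surgery, birth)
    censored_labels = {c.wave_label for c in censors}
    retained = [
        (w, a)
        for w, a in zip(trajectory.waves, trajectory.attendance_dates)
        if w.wave_label not in censored_labels
    ]
    if not retained:
        return ParticipantResult(
            MenopauseEstimate(pid, MenopauseStatus.NOT_CLASSIFIABLE),
            (), tuple(censors), surgery, False, None, 0,
        )
    lmps = assign_all(trajectory, censors, config, audit)
    last_wave, last_att = retained[-1]
    algorithm = classify_fmp(lmps, trajectory, reference, config, last_attendance=last_att)
    sr = collect_self_report_age([w for w, _ in retained], config)
    valid_sr = sr is not None and validate_self_report(sr, lmps, surgery, reference, config)
    final = finalize_estimate(algorithm, sr if valid_sr else None)
    return ParticipantResult(
        final, tuple(lmps), tuple(censors), surgery, valid_sr,
        last_wave.bled_last_12mo, len(retained),
    )


def run_pipeline(
    observations: Iterable[TimepointObservation],
    surgery_reports: Iterable[SurgeryReport] = (),
    config: AlgorithmConfig | None = None,
    n_enrolled: int | None = None,
    collect_audit: bool = True,
) -> PipelineResult:
    """Run the algorithm over a cohort and assemble the participant flow."""
    config = config or AlgorithmConfig()
    by_pid: dict[str, list[TimepointObservation]] = defaultdict(list)
    for obs in observations:
        by_pid[obs.participant_id].append(obs)
    reports_by_pid: dict[str, list[SurgeryReport]] = defaultdict(list)
    for rep in surgery_reports:
        reports_by_pid[rep.participant_id].append(rep)

    flow = FlowSummary()
    flow.responded_any = len(by_pid)
    flow.enrolled = n_enrolled if n_enrolled is not None else len(by_pid)
    estimates: list[MenopauseEstimate] = []
    lmps: list[AssignedLMP] = []
    censors: list[CensorDecision] = []
    audit: list[dict] | None = [] if collect_audit else None

    for pid in sorted(by_pid):
        res = derive_participant(by_pid[pid], reports_by_pid.get(pid, []), config, audit)
        estimates.append(res.estimate)
        lmps.extend(res.lmps)
        censors.extend(res.censors)
        est = res.estimate
        if est.status is MenopauseStatus.EXCLUDED:
            flow.excluded_surgery_no_date += 1
            continue
        if res.n_retained_waves > 0:
            flow.retained_after_censoring += 1
        if res.lmps:
            flow.any_lmp_assigned += 1
        if est.age_at_menopause is not None:
            flow.age_assigned_total += 1
            if est.method is EstimateMethod.ALGORITHM:
                key = "both" if res.had_valid_self_report else "algorithm"
            else:
                key = "self_report"
            flow.age_by_method[key] += 1
        elif (
            est.status is MenopauseStatus.PREMENOPAUSAL_AT_LAST_WAVE
            or res.last_retained_bled_12mo is True
        ):
            flow.unclassified["recent_lmp"] += 1
        else:
            flow.unclassified["amenorrhoeic_insufficient"] += 1

    return PipelineResult(
        tuple(estimates), tuple(lmps), tuple(censors), flow, tuple(audit or ())
    )
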