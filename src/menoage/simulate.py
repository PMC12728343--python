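"""Synthetic cohort generator and truth-alignment reporting.

Generates long-format observation tables with the statistical structure the
algorithm assumes — up to eight waves per woman at mean ages ~47-58, mixed
LMP reporting granularity (full date / month+year / year-only / none), item
nonresponse, recall error, occasional bleeding-flag contradictions, hormone
episodes that mask natural bleeding, and menstruation-ending surgery —
together with the ground truth needed for recovery testing.

The menopause-age distribution is a truncated normal (default mean 50.5, SD
4, truncated to 30-63 years, bracketing the 50-52-year medians reported for
comparable populations). Menstrual cycles run every 28 days up to the final
menstrual period; the true LMP at any attendance is the most recent cycle
start. Recall noise is drawn from one standard-normal stream and scaled by
``recall_error_sd_days``, so runs with the same seed and different noise
levels are coupled realisations of the same cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimulationConfig
from .dates import DAYS_PER_YEAR, months_before
from .types import (
    CessationReason,
    EstimateMethod,
    MenopauseEstimate,
    Procedure,
    SourceKind,
    SurgeryReport,
    TimepointObservation,
)

_COHORT_BIRTH_CENTER = date(1958, 7, 1)
_COHORT_BIRTH_SD_YEARS = 4.5


@dataclass(frozen=True)
class HormoneEpisode:
    start: date
    end: date


@dataclass(frozen=True)
class TrueTrajectory:
    """Ground truth for one synthetic woman."""

    participant_id: str
    birth_date: date
    true_fmp_date: date
    true_menopause_age: float
    hormone_episodes: tuple[HormoneEpisode, ...] = ()
    surgery_procedure: Procedure | None = None
    surgery_date: date | None = None

    @property
    def natural_fmp_observable(self) -> bool:
        """False when surgery precedes the FMP: no natural FMP can be seen."""
        return self.surgery_date is None or self.surgery_date >= self.true_fmp_date


@dataclass(frozen=True)
class SyntheticCohort:
    observations: tuple[TimepointObservation, ...]
    truths: tuple[TrueTrajectory, ...]
    surgery_reports: tuple[SurgeryReport, ...]


def _true_lmp(d: date, fmp: date, cessation: date, cycle_days: int) -> date:
    """Most recent cycle start at or before ``d`` (cycles anchored at the FMP)."""
    if d >= cessation:
        d = cessation
    if d >= fmp:
        return fmp
    return fmp - timedelta(days=cycle_days * math.ceil((fmp - d).days / cycle_days))


def generate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Generate observations, ground truth and surgery reports."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.menopause_age_range
    a = (lo - cfg.menopause_age_mean) / cfg.menopause_age_sd
    b = (hi - cfg.menopause_age_mean) / cfg.menopause_age_sd
    observations: list[TimepointObservation] = []
    truths: list[TrueTrajectory] = []
    surgery_reports: list[SurgeryReport] = []

    for i in range(cfg.n_participants):
        pid = f"P{i:05d}"
        birth = _COHORT_BIRTH_CENTER + timedelta(
            days=round(rng.normal(0.0, _COHORT_BIRTH_SD_YEARS * DAYS_PER_YEAR))
        )
        meno_age = float(stats.truncnorm.rvs(
            a, b, loc=cfg.menopause_age_mean, scale=cfg.menopause_age_sd, random_state=rng
        ))
        fmp = birth + timedelta(days=round(meno_age * DAYS_PER_YEAR))

        surgery_date = None
        surgery_proc = None
        surgery_undated = False
        if rng.random() < cfg.surgery_prob:
            surg_age = float(np.clip(
                rng.normal(cfg.surgery_age_mean, cfg.surgery_age_sd), 30.0, 60.0
            ))
            surgery_date = birth + timedelta(days=round(surg_age * DAYS_PER_YEAR))
            surgery_proc = Procedure(
                rng.choice([p.value for p in
                            (Procedure.HYST_BSO, Procedure.HYST_ONLY, Procedure.BSO_ONLY)])
            )
            surgery_undated = rng.random() < 0.1

        episodes: list[HormoneEpisode] = []
        if rng.random() < cfg.hormone_use_prob:
            start_age = rng.uniform(45.0, 55.0)
            length = rng.exponential(cfg.hormone_episode_mean_years)
            start = birth + timedelta(days=round(start_age * DAYS_PER_YEAR))
            episodes.append(
                HormoneEpisode(start, start + timedelta(days=round(length * DAYS_PER_YEAR)))
            )

        cessation = min(fmp, surgery_date) if surgery_date else fmp
        truths.append(TrueTrajectory(
            pid, birth, fmp, meno_age, tuple(episodes), surgery_proc, surgery_date,
        ))

        surgery_reported = False
        for k, offset in enumerate(cfg.wave_age_offsets):
            # the recall-noise draw is consumed unconditionally so that runs
            # differing only in recall_error_sd_days stay coupled
            z_recall = rng.standard_normal()
            responded = rng.random() < cfg.response_prob
            jitter = rng.normal(0.0, 0.15)
            if not responded:
                continue
            att = birth + timedelta(days=round((offset + jitter) * DAYS_PER_YEAR))
            wave_label = f"W{k}"
            source = (SourceKind.CLINIC if k in cfg.clinic_waves
                      else SourceKind.QUESTIONNAIRE)
            age_att = (att - birth).days / DAYS_PER_YEAR
            hormones_active = any(ep.start <= att <= ep.end for ep in episodes)

            lmp_true = _true_lmp(att, fmp, cessation, cfg.cycle_length_days)
            b3_true = lmp_true >= months_before(att, 3)
            b12_true = lmp_true >= months_before(att, 12)
            b3: bool | None = b3_true != (rng.random() < cfg.flag_error_prob)
            b12: bool | None = b12_true != (rng.random() < cfg.flag_error_prob)

            reasons: set[CessationReason] = set()
            lmp_day = lmp_month = lmp_year = None
            sr_age_lmp = sr_age_meno = None
            contraception: bool | None = None
            hrt: bool | None = None

            if hormones_active:
                # hormone use masks natural bleeding; the items go unanswered
                contraception = age_att < 50.0
                hrt = not contraception
                b3 = b12 = None
            else:
                if b12 is False:
                    if surgery_date is not None and att >= surgery_date:
                        # undated-surgery women also skip the reason item, so
                        # no attendance-date proxy rescues them from exclusion
                        if not surgery_undated:
                            reasons.add(CessationReason.SURGERY
                                        if surgery_proc is Procedure.BSO_ONLY
                                        else CessationReason.HYSTERECTOMY)
                    elif att >= fmp:
                        reasons.add(CessationReason.MENOPAUSE)
                reported = lmp_true + timedelta(
                    days=round(z_recall * cfg.recall_error_sd_days)
                )
                gran = rng.choice(
                    ["full", "month_year", "year_only", "none"],
                    p=[cfg.date_granularity_probs[g]
                       for g in ("full", "month_year", "year_only", "none")],
                )
                if gran == "full":
                    lmp_day, lmp_month, lmp_year = reported.day, reported.month, reported.year
                elif gran == "month_year":
                    lmp_month, lmp_year = reported.month, reported.year
                elif gran == "year_only":
                    lmp_year = reported.year
                # self-reports: a direct age-at-menopause item at wave 2
                # (questionnaire-U-like) and an age-at-last-period item at
                # later questionnaire waves
                sd_years = cfg.recall_error_sd_days / DAYS_PER_YEAR
                if att > fmp and rng.random() < cfg.self_report_prob:
                    recalled = meno_age + z_recall * sd_years
                    if k == 2:
                        sr_age_meno = float(int(round(recalled)))
                    elif source is SourceKind.QUESTIONNAIRE:
                        sr_age_lmp = float(int(round(recalled)))

            observations.append(TimepointObservation(
                participant_id=pid,
                wave_label=wave_label,
                source_kind=source,
                attendance_month=att.month,
                attendance_year=att.year,
                age_at_attendance=round(age_att, 4),
                lmp_day=lmp_day, lmp_month=lmp_month, lmp_year=lmp_year,
                bled_last_3mo=b3, bled_last_12mo=b12,
                cessation_reasons=frozenset(reasons),
                current_contraception=contraception,
                current_hrt=hrt,
                self_reported_age_at_lmp=sr_age_lmp,
                self_reported_age_at_menopause=sr_age_meno,
            ))

            if (
                surgery_date is not None
                and att >= surgery_date
                and not surgery_reported
                and source is SourceKind.QUESTIONNAIRE
            ):
                surgery_reported = True
                if surgery_undated:
                    surgery_reports.append(SurgeryReport(
                        pid, wave_label, surgery_proc, explicit_report=True,
                    ))
                elif rng.random() < 0.5:
                    surgery_reports.append(SurgeryReport(
                        pid, wave_label, surgery_proc, explicit_report=True,
                        surgery_month=surgery_date.month, surgery_year=surgery_date.year,
                    ))
                else:
                    surgery_reports.append(SurgeryReport(
                        pid, wave_label, surgery_proc, explicit_report=True,
                        surgery_age=round((surgery_date - birth).days / DAYS_PER_YEAR, 1),
                    ))

    return SyntheticCohort(tuple(observations), tuple(truths), tuple(surgery_reports))


def write_truth(truths: tuple[TrueTrajectory, ...] | list[TrueTrajectory], path) -> None:
    rows = [
        {
            "participant_id": t.participant_id,
            "birth_date": t.birth_date.isoformat(),
            "true_fmp_date": t.true_fmp_date.isoformat(),
            "true_menopause_age": repr(t.true_menopause_age),
            "surgery_procedure": t.surgery_procedure.value if t.surgery_procedure else "",
            "surgery_date": t.surgery_date.isoformat() if t.surgery_date else "",
            "hormone_episodes": ";".join(
                f"{e.start.isoformat()}/{e.end.isoformat()}" for e in t.hormone_episodes
            ),
        }
        for t in truths
    ]
    pd.DataFrame(rows, columns=[
        "participant_id", "birth_date", "true_fmp_date", "true_menopause_age",
        "surgery_procedure", "surgery_date", "hormone_episodes",
    ]).to_csv(path, index=False)


def read_truth(path) -> list[TrueTrajectory]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for r in df.itertuples():
        episodes = tuple(
            HormoneEpisode(date.fromisoformat(tok.split("/")[0]),
                           date.fromisoformat(tok.split("/")[1]))
            for tok in r.hormone_episodes.split(";") if tok
        )
        out.append(TrueTrajectory(
            r.participant_id,
            date.fromisoformat(r.birth_date),
            date.fromisoformat(r.true_fmp_date),
            float(r.true_menopause_age),
            episodes,
            Procedure(r.surgery_procedure) if r.surgery_procedure else None,
            date.fromisoformat(r.surgery_date) if r.surgery_date else None,
        ))
    return out


def truth_alignment_report(
    estimates: list[MenopauseEstimate], truths: list[TrueTrajectory]
) -> tuple[pd.DataFrame, dict]:
    """Compare estimates to ground truth.

    Returns a per-participant table (estimated and true age, error, status)
    and a summary dict with classification counts and the mean/SD of the
    estimated ages among classified women. Estimates whose ids are absent
    from the truth are an error.
    """
    truth_by_id = {t.participant_id: t for t in truths}
    unknown = [e.participant_id for e in estimates if e.participant_id not in truth_by_id]
    if unknown:
        raise ValueError(f"estimates for ids not in truth: {unknown[:5]}")
    est_by_id = {e.participant_id: e for e in estimates}
    rows = []
    for t in truths:
        e = est_by_id.get(t.participant_id)
        est_age = e.age_at_menopause if e else None
        rows.append({
            "participant_id": t.participant_id,
            "status": e.status.value if e else "unobserved",
            "method": e.method.value if e else EstimateMethod.NONE.value,
            "estimated_age": est_age,
            "true_age": t.true_menopause_age,
            "natural_fmp_observable": t.natural_fmp_observable,
            "error": (est_age - t.true_menopause_age) if est_age is not None else None,
        })
    df = pd.DataFrame(rows)
    classified = df[df["estimated_age"].notna()]
    errors = classified.loc[classified["natural_fmp_observable"], "error"]
    summary = {
        "n_truth": len(truths),
        "n_classified": int(len(classified)),
        "status_counts": df["status"].value_counts().to_dict(),
        "mean_estimated_age": float(classified["estimated_age"].mean()) if len(classified) else None,
        "sd_estimated_age": float(classified["estimated_age"].std(ddof=1)) if len(classified) > 1 else None,
        "mean_error": float(errors.mean()) if len(errors) else None,
        "median_abs_error": float(errors.abs().median()) if len(errors) else None,
    }
    return df, summary


def noise_free_config(n_participants: int = 2000, seed: int = 0, **overrides) -> SimulationConfig:
    """Study conditions for recovery testing: annual waves, full-date
    reporting at every responded wave, truth-consistent flags, no recall
    error."""
    kwargs = dict(
        n_participants=n_participants,
        seed=seed,
        wave_age_offsets=tuple(float(a) for a in range(47, 59)),
        clinic_waves=(0, 3, 5, 6),
        response_prob=1.0,
        date_granularity_probs={"full": 1.0, "month_year": 0.0, "year_only": 0.0, "none": 0.0},
        recall_error_sd_days=0.0,
        flag_error_prob=0.0,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
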