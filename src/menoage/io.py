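"""Readers and writers for the long-format CSV interchange files.

One row per participant-wave in ``observations.csv``. Tri-state yes/no items
are the literal strings ``yes``/``no``/blank — blank means unanswered and is
distinct from ``no``. Cessation reasons are a semicolon-separated set. Dates
are ISO-8601. Optional surgery columns (``surgery_procedure``,
``surgery_explicit``, ``surgery_month``, ``surgery_year``, ``surgery_age``)
ride on the same row as the wave at which the operation was reported.

A column map (plain dict or YAML file) renames canonical field names to the
columns of a particular file; unmapped fields use their canonical names.
"""

from __future__ import annotations

import json
import logging
from datetime import date
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd
import yaml

from .types import (
    AssignedLMP,
    CensorDecision,
    CensorReason,
    CessationReason,
    ConfigurationError,
    EstimateMethod,
    MenopauseEstimate,
    MenopauseStatus,
    Procedure,
    Provenance,
    SourceKind,
    SurgeryReport,
    TimepointObservation,
)

log = logging.getLogger(__name__)

MANDATORY_FIELDS = ("participant_id", "wave_label", "attendance_month", "attendance_year")

OPTIONAL_FIELDS = (
    "source_kind", "age_at_attendance", "lmp_day", "lmp_month", "lmp_year",
    "bled_last_3mo", "bled_last_12mo", "cessation_reasons",
    "current_contraception", "current_hrt",
    "self_reported_age_at_lmp", "self_reported_age_at_menopause",
)

SURGERY_FIELDS = ("surgery_procedure", "surgery_explicit",
                  "surgery_month", "surgery_year", "surgery_age")


def load_column_map(path: str | Path | None) -> dict[str, str]:
    if path is None:
        return {}
    with open(path) as fh:
        mapping = yaml.safe_load(fh) or {}
    if not isinstance(mapping, dict):
        raise ConfigurationError("column map must be a flat field -> column mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def _tri(value: str) -> bool | None:
    v = value.strip().lower()
    if v == "":
        return None
    if v in ("yes", "y", "true", "1"):
        return True
    if v in ("no", "n", "false", "0"):
        return False
    raise ValueError(f"cannot parse tri-state value {value!r}")


def _opt_int(value: str) -> int | None:
    v = value.strip()
    return int(float(v)) if v else None


def _opt_float(value: str) -> float | None:
    v = value.strip()
    return float(v) if v else None


def _fmt(value: Any) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "yes" if value else "no"
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, date):
        return value.isoformat()
    return str(value)


def _read_table(path: str | Path, column_map: Mapping[str, str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {col: field for field, col in column_map.items() if col in df.columns}
    df = df.rename(columns=rename)
    missing = [f for f in MANDATORY_FIELDS if f not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: mandatory columns missing after applying column map: {missing}"
        )
    return df


def read_observations(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[TimepointObservation]:
    """Read the long-format observations file.

    Rows with an unparseable attendance month/year are rejected with a
    row-level diagnostic; any other partial field is preserved as missing.
    """
    df = _read_table(path, column_map or {})
    out: list[TimepointObservation] = []
    for idx, row in df.iterrows():
        def get(field: str) -> str:
            return str(row[field]) if field in row.index else ""

        try:
            month = int(get("attendance_month"))
            year = int(get("attendance_year"))
            if not 1 <= month <= 12:
                raise ValueError(f"attendance_month {month} outside 1-12")
        except ValueError as exc:
            log.warning("%s row %s: rejected (%s)", path, idx, exc)
            continue
        try:
            reasons = frozenset(
                CessationReason(tok.strip())
                for tok in get("cessation_reasons").split(";")
                if tok.strip()
            )
            obs = TimepointObservation(
                participant_id=get("participant_id"),
                wave_label=get("wave_label"),
                source_kind=SourceKind(get("source_kind") or "questionnaire"),
                attendance_month=month,
                attendance_year=year,
                age_at_attendance=_opt_float(get("age_at_attendance")),
                lmp_day=_opt_int(get("lmp_day")),
                lmp_month=_opt_int(get("lmp_month")),
                lmp_year=_opt_int(get("lmp_year")),
                bled_last_3mo=_tri(get("bled_last_3mo")),
                bled_last_12mo=_tri(get("bled_last_12mo")),
                cessation_reasons=reasons,
                current_contraception=_tri(get("current_contraception")),
                current_hrt=_tri(get("current_hrt")),
                self_reported_age_at_lmp=_opt_float(get("self_reported_age_at_lmp")),
                self_reported_age_at_menopause=_opt_float(get("self_reported_age_at_menopause")),
            )
        except ValueError as exc:
            log.warning("%s row %s: rejected (%s)", path, idx, exc)
            continue
        out.append(obs)
    return out


def read_surgery_reports(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[SurgeryReport]:
    """Extract surgery reports from the surgery columns of the same file."""
    df = _read_table(path, column_map or {})
    out: list[SurgeryReport] = []
    for idx, row in df.iterrows():
        def get(field: str) -> str:
            return str(row[field]) if field in row.index else ""

        proc = get("surgery_procedure").strip()
        if not proc:
            continue
        try:
            out.append(
                SurgeryReport(
                    participant_id=get("participant_id"),
                    wave_label=get("wave_label"),
                    procedure=Procedure(proc),
                    explicit_report=_tri(get("surgery_explicit")) is not False,
                    surgery_month=_opt_int(get("surgery_month")),
                    surgery_year=_opt_int(get("surgery_year")),
                    surgery_age=_opt_float(get("surgery_age")),
                )
            )
        except ValueError as exc:
            log.warning("%s row %s: surgery report rejected (%s)", path, idx, exc)
    return out


def write_observations(
    observations: Iterable[TimepointObservation],
    path: str | Path,
    surgery_reports: Iterable[SurgeryReport] = (),
) -> None:
    """Write observations (plus any surgery reports) as one long-format CSV."""
    surgery_by_wave: dict[tuple[str, str], SurgeryReport] = {
        (r.participant_id, r.wave_label): r for r in surgery_reports
    }
    rows = []
    for o in observations:
        row = {
            "participant_id": o.participant_id,
            "wave_label": o.wave_label,
            "source_kind": o.source_kind.value,
            "attendance_month": o.attendance_month,
            "attendance_year": o.attendance_year,
            "age_at_attendance": _fmt(o.age_at_attendance),
            "lmp_day": _fmt(o.lmp_day),
            "lmp_month": _fmt(o.lmp_month),
            "lmp_year": _fmt(o.lmp_year),
            "bled_last_3mo": _fmt(o.bled_last_3mo),
            "bled_last_12mo": _fmt(o.bled_last_12mo),
            "cessation_reasons": ";".join(sorted(r.value for r in o.cessation_reasons)),
            "current_contraception": _fmt(o.current_contraception),
            "current_hrt": _fmt(o.current_hrt),
            "self_reported_age_at_lmp": _fmt(o.self_reported_age_at_lmp),
            "self_reported_age_at_menopause": _fmt(o.self_reported_age_at_menopause),
        }
        surg = surgery_by_wave.get((o.participant_id, o.wave_label))
        row.update(
            {
                "surgery_procedure": surg.procedure.value if surg else "",
                "surgery_explicit": _fmt(surg.explicit_report) if surg else "",
                "surgery_month": _fmt(surg.surgery_month) if surg else "",
                "surgery_year": _fmt(surg.surgery_year) if surg else "",
                "surgery_age": _fmt(surg.surgery_age) if surg else "",
            }
        )
        rows.append(row)
    columns = list(MANDATORY_FIELDS)[:2] + ["source_kind"] + list(MANDATORY_FIELDS)[2:] + [
        f for f in OPTIONAL_FIELDS if f != "source_kind"
    ] + list(SURGERY_FIELDS)
    pd.DataFrame(rows, columns=columns).sort_values(
        ["participant_id", "attendance_year", "attendance_month", "wave_label"],
        kind="mergesort",
    ).to_csv(path, index=False)


def write_results(
    estimates: Iterable[MenopauseEstimate],
    lmps: Iterable[AssignedLMP],
    censors: Iterable[CensorDecision],
    outdir: str | Path,
    flow_summary: Mapping[str, Any] | None = None,
) -> dict[str, Path]:
    """Write the three result CSVs plus a machine-readable flow summary.

    Row order is deterministic (participant id, then wave order as produced).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "assigned_lmp": outdir / "assigned_lmp.csv",
        "censor_log": outdir / "censor_log.csv",
        "menopause_estimates": outdir / "menopause_estimates.csv",
        "flow_summary": outdir / "flow_summary.json",
    }
    lmp_df = pd.DataFrame(
        [
            {"participant_id": l.participant_id, "wave_label": l.wave_label,
             "lmp_date": l.lmp_date.isoformat(), "provenance": l.provenance.value,
             "rule_tag": l.rule_tag}
            for l in lmps
        ],
        columns=["participant_id", "wave_label", "lmp_date", "provenance", "rule_tag"],
    )
    lmp_df.sort_values(["participant_id", "lmp_date", "wave_label"], kind="mergesort").to_csv(
        paths["assigned_lmp"], index=False
    )
    cen_df = pd.DataFrame(
        [
            {"participant_id": c.participant_id, "wave_label": c.wave_label,
             "reason": c.reason.value}
            for c in censors
        ],
        columns=["participant_id", "wave_label", "reason"],
    )
    cen_df.sort_values(["participant_id", "wave_label"], kind="mergesort").to_csv(
        paths["censor_log"], index=False
    )
    est_df = pd.DataFrame(
        [
            {"participant_id": e.participant_id, "status": e.status.value,
             "age_at_menopause": _fmt(e.age_at_menopause),
             "fmp_date": _fmt(e.fmp_date), "method": e.method.value}
            for e in estimates
        ],
        columns=["participant_id", "status", "age_at_menopause", "fmp_date", "method"],
    )
    est_df.sort_values(["participant_id"], kind="mergesort").to_csv(
        paths["menopause_estimates"], index=False
    )
    with open(paths["flow_summary"], "w") as fh:
        json.dump(flow_summary or {}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def read_assigned_lmps(path: str | Path) -> list[AssignedLMP]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        AssignedLMP(r.participant_id, r.wave_label, date.fromisoformat(r.lmp_date),
                    Provenance(r.provenance), r.rule_tag)
        for r in df.itertuples()
    ]


def read_censor_log(path: str | Path) -> list[CensorDecision]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        CensorDecision(r.participant_id, r.wave_label, CensorReason(r.reason))
        for r in df.itertuples()
    ]


def read_estimates(path: str | Path) -> list[MenopauseEstimate]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        MenopauseEstimate(
            r.participant_id,
            MenopauseStatus(r.status),
            age_at_menopause=_opt_float(r.age_at_menopause),
            fmp_date=date.fromisoformat(r.fmp_date) if r.fmp_date else None,
            method=EstimateMethod(r.method),
        )
        for r in df.itertuples()
    ]
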