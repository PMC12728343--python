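from datetime import date, timedelta

import pytest

from menoage import (
    AssignedLMP,
    EstimateMethod,
    MenopauseEstimate,
    MenopauseStatus,
    Provenance,
    build_trajectory,
    classify_fmp,
    collect_self_report_age,
    derive_birth_reference,
    finalize_estimate,
    validate_self_report,
)
from menoage.censoring import SurgeryOutcome, SurgeryResolution
from menoage.dates import age_at_date
from menoage.derivation import SelfReportAge

from conftest import make_obs


def _lmp(d, wave="W0"):
    return AssignedLMP("p1", wave, d, Provenance.FULL_DATE, "1")


class TestBirthReference:
    def test_single_wave_arithmetic_identity(self):
        traj = build_trajectory([make_obs(month=6, year=2010, age_at_attendance=50.0)])
        ref = derive_birth_reference(traj)
        assert abs((ref.reference_birth_date - date(1960, 6, 15)).days) <= 1

    def test_consistent_waves_agree_within_days(self):
        traj = build_trajectory([
            make_obs(wave_label="W0", month=6, year=2010, age_at_attendance=50.0),
            make_obs(wave_label="W1", month=6, year=2012, age_at_attendance=52.0),
        ])
        ref = derive_birth_reference(traj)
        assert abs((ref.reference_birth_date - date(1960, 6, 15)).days) <= 2

    def test_contradictory_ages_averaged_with_warning(self, caplog):
        traj = build_trajectory([
            make_obs(wave_label="W0", month=6, year=2010, age_at_attendance=50.0),
            make_obs(wave_label="W1", month=6, year=2012, age_at_attendance=55.0),
        ])
        with caplog.at_level("WARNING"):
            ref = derive_birth_reference(traj)
        assert ref is not None
        assert any("birth dates" in r.message for r in caplog.records)

    def test_no_ages_yields_none(self):
        assert derive_birth_reference(build_trajectory([make_obs()])) is None


class TestClassifyFmp:
    def _setup(self, gap_days):
        traj = build_trajectory([make_obs(month=6, year=2014, age_at_attendance=52.0)])
        ref = derive_birth_reference(traj)
        last_att = traj.attendance_dates[-1]
        return [_lmp(last_att - timedelta(days=gap_days))], traj, ref

    def test_amenorrhoea_over_365_days_is_postmenopausal(self):
        lmps, traj, ref = self._setup(400)
        est = classify_fmp(lmps, traj, ref)
        assert est.status is MenopauseStatus.POSTMENOPAUSAL
        assert est.method is EstimateMethod.ALGORITHM
        assert est.fmp_date == lmps[0].lmp_date
        # age round-trips through the birth reference
        assert abs(est.age_at_menopause - age_at_date(ref.reference_birth_date, est.fmp_date)) < 0.01

    def test_365_day_boundary_is_strict(self):
        lmps, traj, ref = self._setup(365)
        assert classify_fmp(lmps, traj, ref).status is MenopauseStatus.PREMENOPAUSAL_AT_LAST_WAVE
        lmps, traj, ref = self._setup(366)
        assert classify_fmp(lmps, traj, ref).status is MenopauseStatus.POSTMENOPAUSAL

    def test_no_assigned_lmp_not_classifiable(self):
        _, traj, ref = self._setup(400)
        assert classify_fmp([], traj, ref).status is MenopauseStatus.NOT_CLASSIFIABLE


class TestSelfReport:
    def test_maximum_of_qualifying_reports(self):
        waves = [
            make_obs(wave_label="T", age_at_attendance=54.0, self_reported_age_at_lmp=50.0),
            make_obs(wave_label="U", age_at_attendance=52.0,
                     self_reported_age_at_menopause=48.0),
        ]
        sr = collect_self_report_age(waves)
        assert sr.age == 50.0 and sr.source == "T"

    def test_age_at_lmp_with_insufficient_lag_disqualified(self):
        waves = [make_obs(age_at_attendance=54.3, self_reported_age_at_lmp=54.0)]
        assert collect_self_report_age(waves) is None

    def test_direct_age_at_menopause_item_qualifies_unconditionally(self):
        waves = [make_obs(age_at_attendance=54.3, self_reported_age_at_menopause=54.0)]
        assert collect_self_report_age(waves).age == 54.0

    def test_no_reports_gives_none(self):
        assert collect_self_report_age([make_obs()]) is None


class TestValidateSelfReport:
    def _fixture(self, recent_lmp_age=52.0):
        traj = build_trajectory([make_obs(month=6, year=2014, age_at_attendance=54.0)])
        ref = derive_birth_reference(traj)
        lmp_date = ref.reference_birth_date + timedelta(days=round(recent_lmp_age * 365.25))
        return [_lmp(lmp_date)], ref

    def test_within_two_years_of_recent_lmp_kept(self):
        lmps, ref = self._fixture(52.0)
        sr = SelfReportAge("p1", 50.0, "T")
        assert validate_self_report(sr, lmps, None, ref) is True

    def test_more_than_two_years_before_recent_lmp_dropped(self):
        lmps, ref = self._fixture(52.0)
        sr = SelfReportAge("p1", 49.0, "T")
        assert validate_self_report(sr, lmps, None, ref) is False

    def test_age_at_or_after_surgery_dropped(self):
        lmps, ref = self._fixture(46.0)
        surgery = SurgeryResolution("p1", SurgeryOutcome.CENSOR_FROM_DATE, surgery_age=47.0)
        assert validate_self_report(SelfReportAge("p1", 47.0, "T"), lmps, surgery, ref) is False
        assert validate_self_report(SelfReportAge("p1", 48.0, "T"), lmps, surgery, ref) is False
        # strictly below the surgery age (and within 2 years of the LMP): kept
        assert validate_self_report(SelfReportAge("p1", 46.0, "T"), lmps, surgery, ref) is True


class TestFinalize:
    def test_algorithm_age_takes_priority(self):
        alg = MenopauseEstimate("p1", MenopauseStatus.POSTMENOPAUSAL, 49.6,
                                date(2010, 1, 1), EstimateMethod.ALGORITHM)
        final = finalize_estimate(alg, SelfReportAge("p1", 48.0, "T"))
        assert final.age_at_menopause == 49.6
        assert final.method is EstimateMethod.ALGORITHM

    def test_self_report_used_when_algorithm_has_no_age(self):
        alg = MenopauseEstimate("p1", MenopauseStatus.NOT_CLASSIFIABLE)
        final = finalize_estimate(alg, SelfReportAge("p1", 48.0, "T"))
        assert final.age_at_menopause == 48.0
        assert final.method is EstimateMethod.SELF_REPORT
        assert final.status is MenopauseStatus.POSTMENOPAUSAL

    def test_neither_source_leaves_status_unchanged(self):
        alg = MenopauseEstimate("p1", MenopauseStatus.PREMENOPAUSAL_AT_LAST_WAVE)
        final = finalize_estimate(alg, None)
        assert final is alg
        assert final.age_at_menopause is None


def test_estimate_invariants_enforced():
    with pytest.raises(ValueError):
        MenopauseEstimate("p1", MenopauseStatus.NOT_CLASSIFIABLE, age_at_menopause=50.0)
    with pytest.raises(ValueError):
        MenopauseEstimate("p1", MenopauseStatus.POSTMENOPAUSAL, age_at_menopause=50.0,
                          method=EstimateMethod.NONE)
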