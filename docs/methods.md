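# Methods

## Problem and scope

The package derives, for each woman in a longitudinal study, a date of last
menstrual period (LMP) at every usable timepoint, and from the repeated LMP
estimates an age at natural menopause. Menopause is diagnosed
retrospectively — 12 months of amenorrhoea after the final menstrual period
(FMP) — so the derivation is a set of deterministic rules over partially
reported dates, bleeding-history items and censoring conditions rather than
a fitted statistical model. Nothing is estimated by optimisation; every
output is reproducible from the inputs and the configuration.

## Date conventions

* Attendance dates are released as month/year only; the day is standardised
  to the 15th (`attendance_day_of_month`). All interval arithmetic happens
  after this standardisation.
* "N months before" is calendar-month subtraction with end-of-month clamping
  (2012-09-15 − 3 months = 2012-06-15); "one year before" is calendar-year
  subtraction. The two agree for 12 months vs 1 year.
* Midpoints are earlier-biased: `a + floor((b − a).days / 2)`. The rules do
  not fix a rounding direction; flooring makes every midpoint deterministic
  and reproducible, and never moves an LMP past the later endpoint.
* Ages and dates are interconverted at 365.25 days/year through a per-woman
  *birth reference*: the mean over waves of (attendance date − age at
  attendance). Waves implying birth dates more than a year apart are flagged
  and averaged anyway.

## Assignment rules and their constants

All constants live in `AlgorithmConfig`:

| parameter | default | meaning |
|---|---|---|
| `future_cap_days` | 31 d | an assigned LMP may follow the standardised attendance by at most this (mid-month standardisation can manufacture up to a 16-day overshoot; a full month covers month-level misreporting) |
| `bleed3_offset_days` | 45 d | no-date fallback, bleeding in last 3 months: midpoint of the 3-month window |
| `bleed12_offset_days` | 228 d | no-date fallback, bleeding in last 12 but not 3 months: midpoint of the 3-to-12-month window |
| `buffer_3mo_months` / `buffer_12mo_months` | 3 / 6 mo | reporting-error buffers in consistency check (a) |
| `min_gap_no_bleed_months` | 6 mo | an amenorrhoeic (no bleeding in 12 months) report requires the LMP at least this far back |
| `carry_forward_limit_years` | 3 y | maximum gap to the previous timepoint for carrying an old LMP into an amenorrhoeic wave |
| `fmp_threshold_days` | 365 d | amenorrhoea strictly longer than this at the last retained wave defines the FMP (366+ days qualifies) |
| `self_report_tolerance_years` | 2 y | a self-reported age may undercut the age at the most recent LMP by at most this |
| `min_self_report_lag_years` | 1 y | age-at-last-period items only count as menopause reports when at least this far below the age at reporting |

Decisions taken where the rules leave room:

* **Consistency check (a)** applies only to day- and month-precision
  reported dates; year-only assignments already embed the bleeding history.
  Its +3-month upper buffer is always intersected with the 31-day future
  cap, so the effective upper bound is attendance + 31 days. A date dropped
  by check (a) is treated as missing and falls through to the
  bleeding-history fallback, exactly like a date invalidated by the future
  cap.
* **Check (c)** (assigned date before the previous timepoint's attendance)
  rejects only when the previous timepoint has its own assignment: the
  estimate most proximal to its reporting period is retained. The rejected
  wave receives the previous assignment by carry-forward, so a carried date
  may legitimately precede the previous attendance; the monotonicity
  invariant (assignment ≥ previous attendance) therefore applies to
  non-carried assignments.
* **Carry-forward** into an amenorrhoeic wave is limited to a 3-year gap to
  the previous timepoint. Follow-up gaps can reach a decade; carrying an old
  LMP across such a gap would look like menopause at the old date when the
  woman may have menstruated throughout. Three years bounds the dating error
  to roughly two years. (One internal description of the algorithm states a
  2-year window; the limit is a config field so either reading is available,
  and the 3-year body-text rule is the default.)
* **Bleeding-flag reconciliation** applies the single logically forced
  recode — a 3-month yes forces the 12-month item to yes — and nothing
  else. A yes is never demoted, and missingness is never turned into
  evidence.
* **Mixed bleeding evidence:** the 228-day fallback requires an explicit
  "no" to the 3-month item; with the 3-month item missing no window can be
  attributed and nothing is assigned.
* **Tied same-month records** of the same kind are broken lexically by wave
  label with a warning; clinic-vs-questionnaire ties keep the clinic record.
* **Surgery:** the earliest dated event wins; dates beat ages (finer
  granularity), and ages convert through the birth reference only when no
  date exists. An explicit operation report with no date or age anywhere
  excludes the woman — unless another report (dated operation or a
  cessation-reason item, whose attendance date serves as proxy) supplies a
  date, in which case the earliest dated event is used. A cessation reason
  of contraception censors the wave like current contraceptive use (same
  masking mechanism). Unilateral oophorectomy alone never triggers
  cessation handling.
* **Impossible reported dates** (e.g. a 31 February) are demoted to
  month+year precision with a warning rather than discarded.
* Emitted ages are continuous (e.g. 49.83 years); users wanting age at last
  birthday should floor them.

## Classification and self-reports

The algorithm path classifies a woman postmenopausal when her most recent
assigned LMP lies > 365 days before her last retained attendance; a carried
date counts as the most recent LMP. With no assigned LMP she is not
classifiable; with a recent LMP she is premenopausal at her last wave. The
self-reported age (maximum across qualifying items) is used only when the
algorithm produces no age, after two validity checks: it may not undercut
the age at the most recent LMP by more than 2 years, and it is void at or
above the surgery age. Fully censored or excluded women receive no
estimate.

The participant flow partitions every read participant into exactly one
terminal category — excluded, age assigned (algorithm-only /
self-report-only / both sources concordant), recent LMP, or amenorrhoeic
with insufficient data — and this partition is asserted in the tests.

## Synthetic cohort

`menoage.simulate.generate_cohort` emulates the structure the algorithm
assumes, with ground truth for recovery testing. Per woman: a birth date
(normal around mid-1958, SD 4.5 years); a menopause age from a truncated
normal (mean 50.5, SD 4, truncated to 30–63 years — bracketing the
50–52-year medians reported for comparable populations); 28-day cycles up to
the FMP, so the true LMP at any date is the most recent cycle start; up to
eight waves at target ages 47.4–57.7 (0.15-year jitter), each responded to
with probability 0.45 (matching a mean of ~3.6 responses over the study
instruments); reporting granularity full / month+year / year-only / none
with probabilities 0.60 / 0.25 / 0.10 / 0.05; integer-day recall noise
(SD 30 days) added to the true LMP before truncation to the reported
granularity; bleeding flags computed from the true LMP and flipped with
probability 0.02; a hormone episode (probability 0.15, exponential length,
mean 3 years) that masks bleeding and sets the current-use flags; surgery
(probability 0.05, age ~ N(45, 5) clipped to 30–60), reported at the first
questionnaire wave after the event with a date or an age — or, for 10% of
surgical women, with neither, exercising the exclusion path. Self-reported
ages are integer-rounded recalled values answered with probability 0.5 once
postmenopausal.

Recall-noise draws come from one standard-normal stream that is consumed
whether or not a date is reported, so cohorts generated from the same seed
at different `recall_error_sd_days` are coupled realisations — the basis of
the monotone-degradation test (error does not shrink as noise grows).

`noise_free_config()` freezes the recovery study conditions: 12 annual waves
(ages 47–58), full response, full-date reporting, no recall noise, no flag
errors. Under these conditions every never-censored woman whose true FMP
lies at least a year before her last wave must be classified postmenopausal
with her age recovered to within 0.5 years (in practice the error is the
≤ ~15-day mid-month standardisation shift, ≈ 0.04 years); under default
noise the median absolute age error stays within a year.

What the generator does **not** model — and hence what passing tests cannot
show about real data: attrition correlated with menopause age, demographic
covariates, instrument-specific skip patterns (e.g. a wave that only asks
for an LMP date from women still menstruating), irregular perimenopausal
bleeding beyond the fixed 28-day cycle, hormone-discontinuation timing, and
systematic (as opposed to zero-mean) recall bias.

## Problem sizes in the test suite

The year-only rules are checked against an independent brute-force
window-intersection oracle on a dense grid (~8,700 attendance × year × flag
combinations); cohort invariants run on 1,000 simulated women and the
recovery suites on 2,000, sizes at which all cohort-level rates are stable
to well under the asserted tolerances. The whole suite runs in a few
seconds on one CPU.

## Known limitations

* The interchange format is long-format CSV with a column map; release
  files of any particular cohort must be reshaped to it upstream.
* Tri-state items are trusted as given; beyond the single forced recode, no
  adjudication of contradictory bleeding histories is attempted.
* Hormone-censored gaps can swallow the menopausal transition entirely;
  such women end as amenorrhoeic-insufficient rather than receiving a
  (necessarily speculative) age.
* The 45- and 228-day offsets are window midpoints, not expectations under
  any bleeding model; with skewed true LMP distributions they are biased
  point imputations, which is the intended, auditable behaviour.
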