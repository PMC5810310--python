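# Methods

## Design

The package implements a nested case–control evaluation of a
differentiated-care exposure on retention in adolescent ART care. The cohort
is every adolescent in the study pool; cases are subjects not retained in
care (LTFU, stopped, or died) at data extraction; controls are drawn by
incidence-density sampling from the risk set at each case's follow-up time.
Because controls are sampled from person-time at risk, the exposure odds
ratio from the sampled set estimates the incidence **rate ratio** of
attrition, without requiring a rare outcome.

Time scale. Matching is on days since ART initiation (the explicit matching
scale of the design); a `days_since_eligibility` option shifts the origin to
the date a subject became eligible for the adolescent service (their tenth
birthday for child initiators). The two origins coincide for adolescent
initiators and differ for child initiators; the default follows the
matching phrase, the alternative is retained as configuration because the
eligibility origin is also defensible.

Risk-set membership. At case time *t*: same initiation-age stratum; under
observation (observation start ≤ *t*); administratively censored subjects
are eligible when their censor time equals *t* (they are retained *at* that
time), while future cases and transferred subjects must have their event or
transfer strictly after *t*. Self-matching is excluded. A future case may
serve as an earlier control and later appear as a case; under the default
no-reuse policy this is the only permitted double appearance.

Replacement policy. `no_reuse_across_cases` (default) matches how matched
sets are usually reported: each subject appears as a control at most once.
`reuse_allowed` is classical risk-set sampling, for which the
OR-estimates-rate-ratio result holds exactly; the consistency checks in the
test suite use it, because with many cases drawn from a finite pool the
no-reuse policy preferentially removes long-surviving (hence
more-often-exposed) subjects from later risk sets and attenuates the
estimate slightly. Shortfalls (risk sets smaller than the ratio) take all
available controls, are logged per case, and are never borrowed across
strata.

## Outcome classification

Precedence: died > stopped > transferred out > LTFU > alive on ART.
A patient is LTFU when the censoring date falls more than a 60-day grace
window after the expected run-out (last visit date + days dispensed).

The LTFU **event time is anchored at the run-out date**, the last day the
patient is known to have had treatment in hand. The grace window is only
the classification criterion. An alternative anchor at run-out + grace is
available (`ltfu_anchor="runout_plus_grace"`), but it dates the event ~2
months after the patient's last information: in risk-set sampling that
systematically compares a case's frozen exposure against controls whose
exposure kept accruing for those two months, and measurably biases the
null — with the grace anchor, simulated null cohorts (rate ratio 1, n=5000,
20 replicates) give a mean crude OR near 0.93; with the run-out anchor,
near 0.97.

## Exposure

A subject is exposed at an index date iff at least two distinct visit dates
fall on session-calendar dates **strictly before** the index. Attendance
before ART initiation (flagged pre-ART rows in the visit table) counts
toward the threshold, and session-date visits count regardless of the
subject's age on that date. The two-visit threshold guards against a single
incidental Saturday visit being read as participation.

## Synthetic cohort generator

The generator emulates the three line lists the analysis consumes, with
defaults fixed to the observed study conditions:

| parameter | default | basis |
|---|---|---|
| initiation-age mix (<10 / 10–14 / 15–19) | 0.431 / 0.337 / 0.232 | study pool mix |
| adopter fraction and delay strata | 302/617; delays 17/30/49/52/31/123 across before-ART / ≤1 mo / 2–3 / 4–12 / 13–24 / >24 mo | attender table |
| session adherence | 0.85 | ~85% of post-adoption visits were session visits |
| baseline attrition hazard | 0.0035 per 30-day cycle | reproduces ≈22% cumulative attrition over ~6 y |
| transfer hazard | 0.0025 per 30-day cycle | reproduces ≈15% documented transfers |
| attrition type split | death 18/135, stop 1/135, remainder LTFU | outcome table |
| refills | 30 d for the first 6 months, then 60 or 90 d | clinic schedule |
| enrollment window | 2004-01-01 – 2015-09-30 | programme period (≥3 months before censor) |
| administrative censor | 2015-12-31 | study end |

Sessions are the first Saturday of each month from March 2010 (monthly
cadence is the programme's schedule; *which* Saturday is otherwise
unspecified, so the first is fixed for determinism, and no skipped months
are simulated). Routine visits falling on weekends shift to the next
Monday — weekday clinic operation — which also guarantees that non-session
visits never collide with the Saturday calendar, so ascertained exposure
equals true exposure exactly. Post-adoption visits snap to the nearest
session date with the adherence probability.

Attrition is simulated on a 30-day discrete grid: per-cycle hazard
h₀·θ^{x(t)}, where x(t)=1 once the subject has attended two sessions
strictly before the cycle start (exposure takes effect the cycle *after*
the second session). The implementation draws the attrition cycle from the
equivalent piecewise-geometric distribution, which makes the hazard
bookkeeping exactly testable by brute-force person-time tabulation. LTFU is
realized as silence — the patient simply stops visiting and nothing is
recorded — which is precisely what the downstream classifier must detect;
deaths and stops are recorded with dates. A ground-truth table (adoption,
exposure onset, attrition, transfer) is emitted for parameter-recovery
tests only.

What the generator does **not** emulate: birthdate imprecision (a config
flag can coarsen birth dates to the year), clinic capacity, session
holidays, pregnancy pathways beyond a baseline exclusion flag, and
adherence biology. Passing tests therefore demonstrate the estimator's
behaviour under the design's assumptions, not robustness to real-world
recording noise.

## Inference

Pearson chi-square on r×c tables without continuity correction; zero
expected counts are an error naming the cell. Crude odds ratios use the
cross-product with Wald intervals on the log scale (z = 1.959964 at
α=0.05, carried at full precision; reports round to 2 dp); zero cells are a
hard error with an opt-in Haldane–Anscombe 0.5 correction — never silent.

The multivariable model is **unconditional** logistic regression adjusted
for the matching factor (initiation age appears as a covariate), not
conditional logistic on matched sets — matching fidelity to how such
analyses are reported when matching is broken and adjusted for. Fitting is
Newton/IRLS with step-halving, convergence on the score max-norm ≤ 1e-8,
and frequency-weight support (grouped and expanded data give identical
fits). Non-reference levels with no cases or no controls are perfectly
predictive; they are dropped along with their rows and reported, and render
as a dash in the effects table. Diverging coefficients or a singular
information matrix raise a separation error with the iteration trace.

## Numerical and reporting choices

* All dates are day-precision `datetime.date`; times are integer days since
  ART initiation; ages are completed years with closed bins ([10,14],
  [15,19]).
* CD4 guideline thresholds are configuration with shipped defaults (250
  cells/µL to 2010, 350 for 2011–2013, 500 for 2014–2015), since the
  analysis depends on era, not on the exact printed threshold.
* Case enumeration orders by event time with patient-id tie-breaks; one
  root seed is split per stage; identical config + seed reproduces
  byte-identical output bundles (logs carry no timestamps).
* Attender-summary delay strata use 30-day blocks (≤30 d ≈ "within 1
  month", 31–90 d ≈ "2–3 months", then 91–365, 366–730, >730) because
  calendar-month cutpoints are ambiguous at day precision.

## Problem sizes

The consistency checks run 50 replicates per rate ratio at n=5,000 patients
(≈2,100 pool subjects, ≈170 cases per replicate); coefficient recovery uses
40 seeds at n=10,000 rows; design-identity checks use one n=5,000 cohort
restricted to its first 135 case events. These sizes give Monte-Carlo
standard errors an order of magnitude below the asserted tolerances while
keeping the full suite around a minute.

## Known limitations

* The crude pooled OR over all matched sets carries a small amalgamation
  bias toward the null when exposure prevalence varies strongly across risk
  sets (the Mantel–Haenszel estimator over matched sets is closer to the
  true rate ratio); the tests bound, rather than remove, this.
* Outcome misclassification at the end of follow-up is inherent to the
  run-out rule: a subject whose attrition falls within the last grace
  window before the censor date is classified alive.
* With recorded real-world data the exposure deduction inherits any
  weekend-visit misrecording; the generator's clean weekday/Saturday split
  makes ascertainment exact by construction.
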