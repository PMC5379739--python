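# Methods

This note documents the measurement definitions, the statistical models, the
synthetic-cohort generator and the numerical choices in `adherekit`, in the
order the pipeline applies them.

## Conventions

All day arithmetic is half-open: the number of days between two dates is
their integer difference, and the cumulative adherence period for a
participant is `[randomisation_date, vl_date)`.  Dates are calendar dates in
local clinic time; electronic-monitor timestamps are timezone-naïve local
clock times (single-site assumption).  Estimates are kept at full precision
internally and rounded only at presentation (one decimal).

## Per-protocol landmark windows

A participant contributes to a landmark analysis only if an HIV-RNA result
falls inside that landmark's window, measured in days from randomisation:
days 84–140 (weeks 12–20) for the week-16 landmark, days 224–448
(weeks 32–64) for week 48.  No outcome imputation is performed.  When
several results qualify, the one closest to the nominal landmark day
(112 or 336) is used, with the earlier date breaking ties; the resulting
estimates are flagged `multiple_vls` so the choice is auditable.  Visit-
linked measures (self-recall, pill count, drug level) use the record inside
the window closest to the chosen viral-load date under the same tie rule.

## The six measures

**3-day self-recall (SR).** 100 × (days answered "yes")/3.  Answers are
per-day full-dosing indicators (the question is asked per day, so a "yes"
day on a twice-daily regimen counts as fully dosed).  A missing answer makes
the estimate absent, never zero.

**Clinic pill count (CPC).** 100 × (tablets dispensed since the last
dispensing − tablets returned) / (days between dispensing and count ×
doses/day), restricted to the anchor drug (efavirenz, nevirapine or
lopinavir/r).  The interval is whatever the dispensing records imply — about
one month at week 16 and two at week 48 under the usual visit schedule — not
a fixed constant.  More tablets returned than dispensed implies undisclosed
stock; the value is computed anyway and flagged.

**Pharmacy refill, average (PR-average).** 100 × (days of anchor-drug supply
dispensed in the period) / (days in care), with days in care truncated at
the end-of-care date when care ended before the viral load.  Early refills
legitimately push this above 100%.

**Pharmacy refill, gaps (PR-gaps).** A daily stock ledger adds each
dispensing's supply on its date and consumes one day of supply per day when
any is on hand; days with no possible supply are medication-free.  Surplus
carries forward without cap — possession accumulates.  The measure is
100 × (period − medication-free days)/period, bounded in [0, 100].  The
ledger is checked exactly against an independent pill-by-pill oracle on
randomized schedules in the test suite.

**Electronic monitoring (EAMD).** A monitor day spans 06:00 to 05:59 the
next morning, so an opening at 03:00 credits the previous calendar day
(boundary: 05:59:59 previous day, 06:00:00 current day).  A day is censored
(dead battery) if it has no heartbeat event or its minimum reported battery
voltage is below the threshold (default 3660 device units, configurable);
otherwise it is adherent iff it contains at least one opening.  Adherence is
adherent days over **non-censored** days in care: removing censored days
from the denominator is a deliberate choice — the stated definition divides
by days in care, but counting dead-battery days would recode device failure
as non-adherence.  The full-denominator variant and the censored fraction
are reported alongside so the alternative is recoverable.

**Drug level (TDM).** Mid-dose efavirenz concentration in mg/L with a
therapeutic-range flag (1–4 mg/L inclusive).  Models consume log₁₀
concentration; undetectable (zero) values are floored at 0.05 mg/L
(configurable) before the transform, since the assay's information content
at zero is "very low", not "minus infinity".

## Outcomes and models

Virological failure: HIV-RNA > 400 copies/ml at week 16, > 40 at week 48.
Genotyping is assessable above 500 copies/ml; resistance means ≥ 1 major
mutation (mutation→drug catalogue supplied as config; a default first-line
table ships with the package) affecting a regimen drug.  In resistance
models, participants who failed above the amplification threshold but whose
sample did not amplify are unknown (dropped); failures below the threshold
and non-failures count as not resistant, since no major mutation was
demonstrable.  This "all participants with failure status" basis, rather
than genotyped-only, keeps the model population per-protocol and is flagged
per cell when events are sparse.

Each measure × landmark × outcome cell gets a univariate logistic model and
a multivariable model adding age, baseline CD4 and baseline log₁₀ HIV-RNA
(specified covariates, no selection).  The adherence predictor is divided by
10 so the exponentiated coefficient is the odds ratio per 10% adherence
increase (drug levels use scale 1 → OR per 1-log increase).  Estimation is
maximum likelihood with Wald intervals; non-convergence, exploding
coefficients or standard errors trigger a Firth-penalised refit (Jeffreys
prior score correction, Newton iterations with step-halving), flagged
`penalized_fallback`.  Analyses are complete-case per measure: a participant
missing self-recall drops out of the self-recall models only, so each row
has its own n.  No multiplicity adjustment is applied across the grid.

AUCs use the placement method (per-event fraction of non-events outranked,
ties half) with DeLong variance for the 95% CI; per fit, the AUC of fitted
probabilities equals the sign-oriented AUC of the raw measure (monotone
invariance, asserted in tests).  Pairwise comparison of measures on common
subjects is the paired DeLong test; "nonparametric comparison" is not
uniquely defined, so a stratified bootstrap (default 2,000 resamples,
seeded) is reported beside it as sensitivity.  Degenerate cells (one outcome
class, constant predictor) are left absent and logged rather than fitted.

## Synthetic cohort generator

The generator produces all eight input streams plus ground-truth daily
dosing for a default cohort of 230 participants followed 336 days (dosing is
simulated 28 days past nominal follow-up so late visits have truth behind
them).  Defaults were chosen once to emulate a high-adherence African
first-line cohort; they are configuration, not fitted values.

* **Dosing** is a two-state (dosing/gap) Markov chain per participant —
  clustered gaps, not coin flips, are what make possession-based and
  event-based measures disagree.  Three latent classes (weights
  0.50/0.28/0.22) have transition parameters giving stationary adherence
  ≈ 0.98 / 0.86 / 0.55; the closed form a/(a+b) is verified against the
  realised chains in tests.
* **Dispensing** is supply-driven: a refill is scheduled when the current
  pack (28-day supplies to the week-16 visit, 56-day after) runs out, with
  class-dependent jitter biased a few days early and occasional 1–4-week
  late episodes.  A per-participant "refill tracking" factor (Beta(2,3))
  adds lateness proportional to how long the pills actually last, which is
  the mechanism by which refill measures carry information about dosing.
* **Measurement biases**: pocket doses the monitor misses (8% of doses),
  dead-battery episodes (alternating renewal, mean 7 days, stationary
  fraction 10% of days; the first dead day emits one low-voltage heartbeat,
  later days none, exercising both censoring paths), optimistic self-report
  (a missed day is reported "yes" with probability 0.85), occasional pill
  dumping (10% of counts return fewer tablets), and a white-coat boost for
  drug levels on the visit eve.  Efavirenz concentration is a deliberately
  simple log-linear function of doses in the prior three days plus a
  between-subject effect — only its rank information matters here, not
  pharmacokinetic realism.
* **Outcomes** follow a logistic link in true cumulative adherence
  (β = ln 0.70 per 10 points) and centred baseline covariates, with
  intercepts set so week-16/48 failure runs near 10%/13%; resistance arises
  only among amplified failures, with probability decreasing in adherence.
  Failure viral loads are drawn log-uniformly above the landmark threshold,
  so a realistic fraction exceeds the 500 copies/ml amplification cutoff.
* **Attrition and visits**: care status frequencies (~81% retained, 7%
  transferred, 3.5% died, 8% lost to follow-up) with end-of-care uniform
  over follow-up; viral loads are drawn at attended clinic visits
  (week-16 availability ≈ 70%, week-48 ≈ 80% of the cohort), and
  visit-linked measures require study-visit attendance (90%).

What the generator does *not* emulate: seasonal or time-trending adherence
(the chain is stationary, so week-16 and week-48 medians are similar, unlike
real cohorts where adherence declines), informative attrition, regimen
switches, assay noise structure, or mutation linkage patterns.  Passing
tests therefore demonstrate that the estimators and models recover known
structure under realistic measurement error — not that the pipeline's
numbers on any real cohort are correct.

## Problem sizes and numerics

Property tests compare the stock ledger with the brute-force oracle on
1,000 random schedules and AUCs with all-pairs concordance up to n = 200.
Stochastic calibration checks use 200 replicates: outcome-layer cohorts of
n = 2,000 for parameter recovery (≤5% relative bias in the log-OR, Wald
coverage ≈ 95%), n = 600 for type-I error (5% ± 3%), and full default
cohorts (n = 230) for the measurement-bias ordering and the electronic-
monitoring-versus-self-report AUC ranking (expected in ≥90% of replicates —
individual seeds can legitimately invert it).  Firth iterations stop when
the step max-norm falls below 1e-10; information matrices are inverted by
pseudo-inverse to tolerate near-collinearity.  All randomness flows from a
single numpy Generator per run; equal seed and config give byte-identical
output files.

## Known limitations

* The pill-return model assumes tablets are returned only from the current
  pack; real patients return accumulated surplus, which the flagged
  `returned_exceeds_dispensed` path admits but the generator does not emit.
* The EAMD denominator decision (exclude censored days) cannot be verified
  against the source definition, which is silent on the point; both
  variants are computed.
* Resistance cells often have <10 events; the Firth fallback keeps them
  estimable but their intervals are wide, and the small-sample flag should
  be taken seriously.
* No real participant-level data are bundled; re-analyses of collected
  cohorts use the documented CSV normal form.
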