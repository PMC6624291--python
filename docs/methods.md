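# Methods

## Scope and data model

`stepladder` reconstructs treatment-step occupancy for asthma patients
from flat primary-care tables (patients, diagnoses, prescriptions,
clinical events, CPRD-GOLD-like schemas, CSV with ISO-8601 dates).  All
intervals are half-open `[start, end)` in whole days; a script issued on
day *d* with duration *k* covers days *d … d+k−1*.  Prescription
coverage, not adherence, is modelled throughout: the algorithm measures
prescribers' intent, and deliberately carries a discontinued category
through a grace period rather than ending exposure at the last covered
day.

## The classification algorithm

**Cleaning.**  Combination products (`ICS/LABA`) are expanded to their
component categories, the ICS daily dose travelling with the ICS
component.  Missing durations are imputed in a fixed order — pack size ÷
tablets-per-day, then the patient's per-category median, then a 30-day
default — and clipped to [1, 183] days; every correction is logged with
the rule applied.  Scripts with unrecognised categories are dropped, with
a log entry.

**Episodes (grace rule).**  Within a patient and category, a script
extends the current episode when `issue − running_coverage_end ≤
grace_days` (90 base case; boundary inclusive — the boundary convention
is not prescribed by the underlying analysis, and the inclusive reading
makes a 90-day gap merge).  Episode coverage ends at the maximum coverage
end of its member scripts and is *extended* by the grace period: a time
point falling in the extension keeps the prior regimen.

**Combination qualification (overlap rule).**  For each pair of
overlapping episodes of different categories, the coverage intersection
(before grace extension) must last at least `overlap_days` (30) for the
categories to count as combined.  When it is shorter, the later-starting
episode (tie-break: the shorter one; identical spans suppress neither)
is omitted from the combined regimen for the whole co-presence of the two
episodes — the intersection of their grace-extended spans.  Suppressing
for the whole co-presence, rather than only the coverage intersection,
is a deliberate choice: it prevents a failed 2-week LABA trial from
surfacing as combination therapy during the trailing grace window, which
would otherwise re-admit exactly the transient exposure the rule exists
to exclude.  OCS never enters category sets; it is carried separately
(below).

**Oral corticosteroids.**  A course with duration strictly below 14 days
*and* strength at least 5 mg is a rescue pack; everything else —
including courses with missing strength, logged with a warning, the
direction that can only promote a patient towards step 5 — is
maintenance.  A continuous-OCS period opens where five rescue courses
fall inside a 183-day window (first issue to the last course's coverage
end) or where any maintenance course exists (its coverage); periods are
extended by the grace period and merged when overlapping.  A literal
consequence, kept as specified: a short prednisolone course *below* 5 mg
strength is maintenance and triggers step 5.

**Regimen timeline.**  A change-point sweep over episode boundaries,
grace ends, suppression bounds, ICS script edges and OCS period edges
produces tiling segments per patient, each holding the category set, the
ICS dose band and the OCS mode.  The ICS band is computed from the mean
daily dose of the scripts covering each day (carried forward through
gaps and grace inside an exposure) against an age-group threshold —
'high' strictly above 400 µg/day BDP-equivalent for children and
800 µg/day for adults, configurable; the guideline's own dose table is
not redistributable, so these are the conventional low/high boundaries.
The sweep is validated against an independent brute-force day-by-day
computation (tests/_oracle.py) for exact agreement of day coverage on
randomized instances.

**Step mapping.**  An ordered rule table, first match wins, validated
total and deterministic by enumerating the full finite regimen space
(2,304 combinations).  Default order: continuous OCS → 5; high ICS → 4;
ICS + ≥2 add-ons (LABA, LAMA, LTRA, theophylline) → 4; ICS + 1 add-on →
3; ICS alone → 2; LTRA/cromone preventer monotherapy → 2; add-on without
ICS → 3 *with an anomaly flag* (observed in real prescribing; must not
crash a cohort run); reliever only → 1; nothing → 0.  Unmatched treated
regimens (e.g. rescue OCS with no other treatment) take a flagged default
of step 1.  LAMA counts as an add-on; step 5 requires only the
continuous-OCS condition, not conjointly high-dose ICS.

**Assignment, censoring, transitions.**  Steps are read *at* each grid
point (point-in-time regimen), not as a maximum over the interval; the
grid steps back 6 calendar months from the reference date, 18 points
(2007-12-01 … 2016-06-01 by default).  Precedence: censored (point before
max(study start, registration start) or after registration end) beats
undiagnosed (point before the first asthma code) beats the segment step;
a diagnosed, uncensored point with no segment is step 0.  Movement within
an interval compares the two endpoint steps, so an excursion that returns
by the closing point counts as stable; an any-change variant is available
behind a flag (`classify_within_interval(..., any_change=True)`) for
comparison.  Transition matrices pool consecutive point pairs over
patients with both endpoints in steps 0–5; the 0→0 cell is reported even
though step-0 rows are conventionally printed without it, so every
non-empty row sums to 100 (±0.1 rounding).

## Cohort rules

Inclusion: ≥1 asthma diagnosis code on or before study end ("active
diagnosis" is not further defined upstream; one-code-ever is the
operationalisation), acceptable-records flag, age 5–80 in completed years
at the reference date (children 5–11, adults 12–80), 12 months'
continuous enrolment *immediately* before the reference date (the
stricter of the two readings; the looser "any 12 continuous months" is
not implemented), and no trial participation.  Exclusions apply in that
fixed order and each patient is counted at the first rule that removes
them, making the exclusion log reproducible.  Covariates: annual review
in one- and two-year windows ending August 2016 under a core or wide
Read-code list (the wide list is a strict superset, so widening is
monotone), ever-flags for spirometry, home peak flow, COPD, eczema,
hayfever and rhinosinusitis, 12-month peak flow, most-recent smoking
status, and the last eosinophil count.  The shipped code lists are toy
stand-ins with the right shape; the licensed QOF dictionaries are out of
scope.

## Synthetic cohort generator

The generator inverts the classifier.  Ground truth first: per patient, a
first-order Markov chain on the grid — 'undiagnosed' before a diagnosis
date drawn inside registration, an initial step from an age-group
distribution at the first diagnosed point, kernel transitions afterwards.
First-order dynamics are the simplest that exercise every cell of a
transition matrix, which is all the recovery and kernel tests need.
Rendering then emits, per diagnosed point with step ≥1, the *minimal*
regimen realising that step: 30-day repeats covering `[t−90, t+30)`
(SABA for step 1; low-dose ICS for 2; +LABA for 3; high-dose ICS+LABA
for 4; plus either five 7-day 5 mg rescue courses inside 60 days or one
30-day maintenance course for 5).  The offsets are load-bearing: coverage
chains across consecutive points with gaps ≤ 63 days (inside grace), while
a category dropped at the next point exhausts coverage + grace ≈ 120 days
before that point arrives, ~182 days later — so with jitter and dropout
at zero, classification recovers the plan exactly, which the tests assert
at 100%.  Alternative routes into each step (LTRA monotherapy, ICS+two
add-ons, …) are exercised by dedicated unit fixtures instead of the
renderer.

Defaults are fixed study conditions, not tuning knobs: the transition
kernels and initial distributions follow published UK primary-care
transition percentages and start-of-study step mixes (rows renormalised
from printed rounding; the unprinted to-step-0 mass assigned to the 0→0
cell), the child fraction (6.2%), smoking split, and comorbidity/review/
spirometry prevalences follow the same study's descriptives, and the
remaining prevalences (peak flow, rhinosinusitis, eosinophil recording)
are plausibility choices.  Noise defaults are mild — ±5 days of issue
jitter, 2% script dropout, 5% late registration, 2% early
deregistration, 1% unacceptable records, 0.5% trial flags.

What the generator does *not* emulate: adherence and collection
behaviour, brand/formulation detail, dose tapering, practice-level
clustering, seasonality, secondary-care prescribing, mortality, and any
correlation between covariates and treatment step.  Passing the recovery
tests therefore demonstrates that the classifier is exact on data obeying
its own assumptions — not that those assumptions hold in real records,
where grace/overlap choices genuinely change results (which is what the
sensitivity variants quantify).

## Sensitivity analysis and statistics

Four one-dimensional variants re-run the whole pipeline: 3-month grid
(same span, 35 points, every 6-month point shared — assignments at shared
points are identical by construction, a property the tests check),
30-day grace, exclusion of patients with any COPD record (applied before
any step assignment), and the wide review-code list.  `diff_resultsets`
aligns every output table on its key columns and reports cell deltas and
the maximum absolute change; variant isolation (each override touches
only the tables it can affect) is asserted in the acceptance suite.
Covariate comparisons across steps use the chi-squared test without
continuity correction for categorical covariates and two-sample t tests
(pooled variance) pairwise for age and eosinophil count; constant
covariates are skipped with a note; no multiple-testing adjustment is
applied, matching the descriptive intent, and the output tables say so in
their notes column.

## Numerical and engineering choices

"2 weeks" is 14 days (strict) and "6 months" is 183 days in all rule
arithmetic; calendar-month arithmetic is used only for the grid.
Same-start overlapping episodes tie-break to suppress the shorter; fully
identical spans suppress neither.  Dates are int64 days internally;
the per-patient sweep is vectorised over boundaries, so the full
default-scale run (10,000 patients × 18 points, ≈0.7 M scripts) simulates
and classifies in well under a minute on one core.  All randomness flows
from one `numpy` Generator seeded per run; identical config + seed
reproduces every output byte (manifests differ only in their timestamp).
Output files are written atomically (temp file + rename), so a failed
stage leaves no truncated tables.  Test and acceptance cohort sizes
(2,000 for exact recovery, 6,000–10,000 for kernel recovery and the
end-to-end run) are chosen so binomial sampling error, not runtime,
dominates the checks.

## Known limitations

The step mapping is a faithful reconstruction of the 2014 guideline
structure, not the licensed original lookup; 2016 BTS/SIGN or GINA
schemes could be expressed in the rule-table config but no such preset is
validated.  Eligibility requires enrolment spanning the reference date,
so loss to follow-up manifests as exclusion rather than right-censoring
within the grid.  The within-interval movement measure is endpoint-based
and understates short excursions (quantifiable via the any-change flag).
Real CPRD birth-date granularity (year only) is finer-grained here for
determinism; age computation would need the same completed-years rule on
mid-year imputed dates in a real extract.
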