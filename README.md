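# stepladder

Classification of primary-care asthma prescribing into **2014 BTS/SIGN
treatment steps**, with longitudinal step-transition analysis and a
synthetic electronic-health-record generator.

## The problem

UK asthma guidelines (BTS/SIGN 2014) organise pharmacological management
as a ladder of five steps — 1: reliever only (SABA/SAMA); 2: regular
preventer (ICS); 3: initial add-on (low-dose ICS + LABA/LTRA/…);
4: persistent poor control (high-dose ICS or multiple add-ons);
5: continuous or frequent oral corticosteroids — plus a study-defined
**step 0** for diagnosed but untreated patients.  Routine primary-care
databases (CPRD-GOLD-style flat tables of patients, diagnoses,
prescriptions and clinical events) record *scripts*, not steps, so
drug-utilisation studies need an explicit algorithm to recover the step a
patient occupies at any date.  `stepladder` implements that algorithm and
everything around it:

* **Exposure episodes** — consecutive same-category scripts belong to one
  continuous exposure while the gap from coverage end to the next issue is
  at most a **90-day grace period**; an episode carries its category for a
  further grace period after coverage ends (a discontinuation gap keeps
  the prior regimen).
* **Combined regimens** — two drug categories count as combined only where
  their coverage overlaps for at least **30 days**; shorter later-starting
  trials are treated as transient and never qualify as combination
  therapy.
* **Oral corticosteroids** — a prednisolone course of **< 14 days at
  ≥ 5 mg** is a rescue pack; **≥ 5 rescue courses within 183 days**, or
  any maintenance course, mark continuous/frequent OCS use (step 5).
* **Step assignment** — a configurable, total, deterministic rule table
  maps each (category set, ICS dose band, OCS mode, age group) to a step;
  steps are evaluated at 18 six-monthly time points (2007-12-01 to
  2016-06-01 by default) with left-censoring before study start or
  registration and an `undiagnosed` status before the first asthma code.
* **Transitions** — within-interval movement (stepped up / down / stable),
  per-time-point step distributions and from-step × to-step transition
  matrices, per age group (children 5–11, adults 12–80).
* **Sensitivity variants** — 3-month grid, 30-day grace, COPD exclusion,
  wide review-code list — each re-runs the whole pipeline under one
  changed assumption and diffs every output table against the base case.

Because the real database is licensed, the package ships a **synthetic
cohort generator**: step trajectories are planned as a first-order Markov
chain on the assessment grid (kernel and marginals shaped like published
UK primary-care estimates) and prescriptions are rendered so that, with
noise switched off, the pipeline provably recovers the planned step at
every diagnosed, uncensored time point.  That recovery property, plus a
brute-force day-by-day oracle for the sequence engine, is what the test
suite leans on.

## Worked example

Simulate 2,000 patients over the ten-year window and classify them:

```python
import stepladder as sl

raw, plan = sl.simulate_raw_tables(sl.GenerationConfig(n_patients=2000, seed=42))
res = sl.run_analysis(raw, sl.StudyConfig(), seed=42)

tm = res.tables["transition_matrix_adult"]
print(tm[["from_step"] + [f"pct_to_{s}" for s in range(6)] + ["row_n"]]
      .round(1).to_string(index=False))
```

```
 from_step  pct_to_0  pct_to_1  pct_to_2  pct_to_3  pct_to_4  pct_to_5  row_n
         0      93.2       4.6       1.6       0.4       0.3       0.0   1667
         1       0.0      88.5       6.7       2.1       2.5       0.1   7206
         2       0.0       7.5      90.2       1.4       0.9       0.0   6093
         3       0.0       5.6       1.9      89.8       2.4       0.3   2799
         4       0.0       5.2       0.8       1.7      91.9       0.5   3829
         5       0.0       4.0       2.3       6.4      13.9      73.4    173
```

Each row pools all consecutive 6-month point pairs: of adults in step 1
at one point, 88.5% are still in step 1 at the next, 6.7% stepped up to
step 2, and so on; step 5 is the least stable step (73.4% remain).  The
unprinted-elsewhere 0→0 cell is reported so every row sums to 100.
The treated adult step distribution at the final point
(`res.tables["distribution_treated_by_timepoint"]`) is 36.1 / 29.8 / 14.1 / 19.3 /
0.7 % across steps 1–5, and 90.0% of adult patient-intervals are stable —
the down-weighted movement and step-1/2 dominance typical of UK
primary-care prescribing.  Of the 2,000 simulated patients, 1,828 pass
the eligibility rules (asthma code, acceptable records, age 5–80,
12 months' enrolment before 2016-06-01, no trial flag).

The same run from a shell, with a sensitivity variant:

```bash
stepladder run --out results/base --seed 42 --n-patients 2000 --variant grace_30d
stepladder print-mapping --out mapping.csv     # regimen -> step truth table
```

All outputs are CSV with ISO-8601 dates; `manifest.json` records the
config snapshot, input digests, seed and output inventory.  A fully
annotated base-case configuration ships at
`src/stepladder/data/default_config.yaml`.

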