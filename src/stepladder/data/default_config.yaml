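# stepladder base-case configuration.
# Every constant of the analysis is auditable here; pass a (partial) copy
# via `stepladder run --config FILE` to override any value.

# ---- study window and anchor ------------------------------------------
study_start: 2006-09-01        # first day of the observation window
study_end: 2016-08-31          # last day of the observation window
reference_date: 2016-06-01     # age, eligibility and covariates evaluated here

# ---- cohort ------------------------------------------------------------
min_age: 5                     # completed years at the reference date
max_age: 80
child_age_max: 11              # 5-11 = child, 12-80 = adult
min_enrolment_days: 365        # continuous enrolment immediately before reference

# ---- assessment grid ---------------------------------------------------
interval_months: 6             # spacing of step-assessment time points
n_time_points: 18              # grid: 2007-12-01 .. 2016-06-01 under defaults

# ---- classification rules ----------------------------------------------
grace_days: 90                 # max gap between same-category scripts before
                               # exposure counts as discontinued
overlap_days: 30               # min concurrent coverage for two categories
                               # to count as a combined regimen
rescue_max_duration_days: 14   # rescue OCS: duration strictly below this ...
rescue_min_strength_mg: 5      # ... at at least this tablet strength
continuous_ocs_min_count: 5    # rescue courses needed inside the window ...
continuous_ocs_window_days: 183  # ... of this many days (or any maintenance
                               # course) for continuous/frequent OCS (step 5)
ics_high_threshold_ug:         # 'high' ICS band: mean daily dose above this
  child: 400.0                 # (BDP-equivalent microgram/day)
  adult: 800.0

# ---- prescription cleaning ---------------------------------------------
default_duration_days: 30      # fallback when duration and pack are missing
min_duration_days: 1           # clip bounds for implausible durations
max_duration_days: 183
tablets_per_day: 1.0           # pack_size -> duration conversion

# ---- covariate windows --------------------------------------------------
review_1y_window: [2015-08-01, 2016-08-31]
review_2y_window: [2014-08-01, 2016-08-31]
review_code_list: qof_core     # qof_core | qof_wide (sensitivity variant)
exclude_copd: false            # sensitivity variant: drop COPD history
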