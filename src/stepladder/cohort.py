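"""Cohort selection and covariate extraction.

Inclusion: an asthma diagnosis code, records flagged acceptable, age 5-80
(completed years) at the reference date, at least 12 months' continuous
enrolment immediately before the reference date, and no trial
participation.  Exclusions are applied in that fixed order and each
patient is counted once, at the first rule that removes them, so the
exclusion log is reproducible.

The shipped Read-like code lists are toy stand-ins (one code per line)
with the same shape as QOF-derived lists; the real licensed dictionaries
are out of scope.  The wide review list is a strict superset of the core
list, so widening it can only add review records.
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd

from .config import StudyConfig
from .tables import RawTables

log = logging.getLogger("stepladder")

EXCLUSION_ORDER = ("no_asthma_code", "not_acceptable", "age_out_of_range",
                   "insufficient_enrolment", "trial_participation")

_CODELIST_FILES = {
    "asthma": "asthma.txt", "review_core": "review_core.txt",
    "review_wide": "review_wide.txt", "spirometry": "spirometry.txt",
    "peakflow": "peakflow.txt", "copd": "copd.txt", "eczema": "eczema.txt",
    "hayfever": "hayfever.txt", "rhinosinusitis": "rhinosinusitis.txt",
    "smoking": "smoking.txt", "eosinophil": "eosinophil.txt",
}

KNOWN_EVENT_CATEGORIES = {
    "review", "spirometry", "peak_flow_home", "peak_flow", "copd", "eczema",
    "hayfever", "rhinosinusitis", "smoking", "eosinophil",
}


def load_codelist(name: str) -> frozenset:
    """Read one packaged code list (one code per line, '#' comments)."""
    text = (resources.files("stepladder") / "codelists"
            / _CODELIST_FILES[name]).read_text()
    return frozenset(line.strip() for line in text.splitlines()
                     if line.strip() and not line.startswith("#"))


def completed_age(birth: pd.Series, at: pd.Timestamp) -> pd.Series:
    """Age in completed years at ``at`` (deterministic from full dates)."""
    age = at.year - birth.dt.year
    before_birthday = ((birth.dt.month > at.month)
                       | ((birth.dt.month == at.month)
                          & (birth.dt.day > at.day)))
    return age - before_birthday.astype(int)


def select_cohort(raw: RawTables, config: StudyConfig
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply inclusion rules; return ``(cohort, exclusion_log)``.

    ``cohort`` holds one row per *input* patient with an
    ``exclusion_reason`` (NA if eligible), the reference-date age and age
    group, first diagnosis date, and the censoring window
    ``[censor_start, censor_end]`` used downstream.  Zero eligible
    patients is a valid, warned outcome.
    """
    ref = pd.Timestamp(config.reference_date)
    pts = raw.patients.copy()
    asthma_codes = load_codelist("asthma")
    diag = raw.diagnoses[raw.diagnoses["code"].isin(asthma_codes)]
    first_diag = diag.groupby("patient_id")["diagnosis_date"].min()
    pts["first_diagnosis_date"] = pts["patient_id"].map(first_diag)

    pts["age_at_reference"] = completed_age(pts["birth_date"], ref)
    pts["age_group"] = np.where(pts["age_at_reference"] <= config.child_age_max,
                                "child", "adult")

    reason = pd.Series(pd.NA, index=pts.index, dtype="string")

    def apply(mask: pd.Series, name: str) -> None:
        hit = mask & reason.isna()
        reason[hit] = name

    apply(pts["first_diagnosis_date"].isna()
          | (pts["first_diagnosis_date"] > pd.Timestamp(config.study_end)),
          "no_asthma_code")
    apply(pts["acceptable_flag"] != 1, "not_acceptable")
    apply((pts["age_at_reference"] < config.min_age)
          | (pts["age_at_reference"] > config.max_age), "age_out_of_range")
    enrol_start = ref - pd.Timedelta(days=config.min_enrolment_days)
    apply((pts["registration_start"] > enrol_start)
          | (pts["registration_end"] < ref), "insufficient_enrolment")
    apply(pts["trial_flag"] == 1, "trial_participation")

    if config.exclude_copd:
        copd_codes = load_codelist("copd")
        ev = raw.clinical_events
        copd_pids = set(ev.loc[(ev["event_category"] == "copd")
                               | ev["code"].isin(copd_codes), "patient_id"])
        apply(pts["patient_id"].isin(copd_pids), "copd_history")

    pts["exclusion_reason"] = reason
    pts["eligible"] = reason.isna()
    pts["censor_start"] = pts["registration_start"].clip(
        lower=pd.Timestamp(config.study_start))
    pts["censor_end"] = pts["registration_end"]

    order = list(EXCLUSION_ORDER) + ["copd_history"]
    counts = reason.value_counts()
    exclusion_log = pd.DataFrame({
        "reason": order,
        "count": [int(counts.get(r, 0)) for r in order]})
    exclusion_log = exclusion_log[exclusion_log["count"] > 0].reset_index(drop=True)
    n_eligible = int(pts["eligible"].sum())
    if n_eligible == 0:
        log.warning("cohort selection left zero eligible patients")
    log.info("cohort selection: %d of %d patients eligible",
             n_eligible, len(pts))
    cols = ["patient_id", "age_at_reference", "age_group",
            "first_diagnosis_date", "censor_start", "censor_end",
            "registration_start", "registration_end",
            "eligible", "exclusion_reason"]
    return pts[cols], exclusion_log


def eligible_age_groups(cohort: pd.DataFrame) -> pd.Series:
    """patient_id -> age group for the eligible patients."""
    elig = cohort[cohort["eligible"]]
    return pd.Series(elig["age_group"].to_numpy(),
                     index=elig["patient_id"].to_numpy())


def compute_covariates(cohort: pd.DataFrame, clinical_events: pd.DataFrame,
                       config: StudyConfig) -> pd.DataFrame:
    """Per-patient covariate flags over the stated look-back windows.

    Review flags use the configured code list ('qof_core'/'qof_wide') over
    the one- and two-year windows; 'ever' flags scan the full history
    before the reference date; smoking status is the most recent smoking
    event before the reference date.  Unknown event categories are warned
    about and ignored.
    """
    ref = pd.Timestamp(config.reference_date)
    elig = cohort[cohort["eligible"]]
    ev = clinical_events[clinical_events["patient_id"].isin(
        set(elig["patient_id"]))].copy()

    unknown = ~ev["event_category"].isin(KNOWN_EVENT_CATEGORIES)
    if unknown.any():
        log.warning("ignoring %d clinical event(s) with unknown category %s",
                    int(unknown.sum()),
                    sorted(ev.loc[unknown, "event_category"].unique())[:5])
        ev = ev[~unknown]

    out = elig[["patient_id", "age_at_reference", "age_group"]].copy()
    out = out.set_index("patient_id")

    review_list = load_codelist(
        "review_core" if config.review_code_list == "qof_core" else "review_wide")
    rev = ev[(ev["event_category"] == "review") & ev["code"].isin(review_list)]
    w1a, w1b = (pd.Timestamp(d) for d in config.review_1y_window)
    w2a, w2b = (pd.Timestamp(d) for d in config.review_2y_window)
    in_1y = rev[(rev["event_date"] >= w1a) & (rev["event_date"] <= w1b)]
    in_2y = rev[(rev["event_date"] >= w2a) & (rev["event_date"] <= w2b)]
    out["review_1y"] = out.index.isin(set(in_1y["patient_id"]))
    out["review_2y"] = out.index.isin(set(in_2y["patient_id"]))

    hist = ev[ev["event_date"] <= ref]
    def ever(category: str) -> pd.Series:
        pids = set(hist.loc[hist["event_category"] == category, "patient_id"])
        return pd.Series(out.index.isin(pids), index=out.index)

    out["spirometry_ever"] = ever("spirometry")
    out["peakflow_home_ever"] = ever("peak_flow_home")
    pf = hist[(hist["event_category"] == "peak_flow")
              & (hist["event_date"] >= ref - pd.Timedelta(days=365))]
    out["peakflow_12m"] = out.index.isin(set(pf["patient_id"]))
    out["copd_ever"] = ever("copd")
    out["eczema_ever"] = ever("eczema")
    out["hayfever_ever"] = ever("hayfever")
    out["rhinosinusitis_ever"] = ever("rhinosinusitis")

    smoke = hist[hist["event_category"] == "smoking"].sort_values("event_date")
    last_smoke = smoke.groupby("patient_id")["value"].last()
    out["smoking_status"] = out.index.map(last_smoke).fillna("unknown")

    eos = hist[hist["event_category"] == "eosinophil"].sort_values("event_date")
    eos_val = pd.to_numeric(eos.groupby("patient_id")["value"].last(),
                            errors="coerce")
    out["eosinophil_recorded"] = out.index.isin(set(eos["patient_id"]))
    out["eosinophil_value"] = out.index.map(eos_val)
    return out.reset_index()
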