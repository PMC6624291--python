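"""Synthetic CPRD-GOLD-like cohort with known step trajectories.

The generator inverts the classification rules: it first plans a
ground-truth treatment step per patient per 6-monthly time point (a
first-order Markov chain over steps 0-5, 'undiagnosed' before the
diagnosis date), then renders prescription records that realise the
planned step at each point under the default step mapping —

* step 1: short-acting reliever scripts only;
* step 2: low-dose ICS repeats with gaps inside the grace period;
* step 3: low-dose ICS plus LABA overlapping >= the overlap period;
* step 4: high-dose ICS plus LABA;
* step 5: the step-4 regimen plus either five rescue prednisolone courses
  (7 days at 5 mg) inside 6 months or one maintenance course;
* step 0: no scripts.

Each point's regimen is a run of 30-day repeats covering [t-90, t+30):
same-category exposure chains across consecutive points (gaps stay inside
the 90-day grace period), while a category dropped at the next point runs
out of grace before that point arrives; with jitter and dropout at zero
the downstream pipeline recovers the plan exactly at every diagnosed,
uncensored point.

Clinical events (reviews, spirometry, comorbidities, smoking, eosinophil
counts) are sampled per configured prevalence inside each patient's
registration window.
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd
from dateutil.relativedelta import relativedelta

from .config import GenerationConfig, UNDIAGNOSED
from .tables import RawTables

log = logging.getLogger("stepladder")

#: BDP-equivalent daily ICS dose (microgram) rendered per age group & band;
#: the high values sit above, the low values below, the band thresholds.
ICS_DOSE_UG = {("child", "low"): 200.0, ("child", "high"): 800.0,
               ("adult", "low"): 400.0, ("adult", "high"): 1600.0}

SUBSTANCE = {"SABA": "salbutamol", "ICS": "beclometasone",
             "LABA": "salmeterol", "OCS": "prednisolone"}

_ASTHMA_CODES = ("H33..", "H330.", "H331.", "H332.", "H333.", "H33z.")
_REVIEW_CORE = "66YJ."
_REVIEW_WIDE_ONLY = "66Y5."
_CATEGORY_CODE = {"spirometry": "33G..", "peak_flow_home": "663U.",
                  "peak_flow": "339A.", "copd": "H3...", "eczema": "M11..",
                  "hayfever": "H17..", "rhinosinusitis": "H13..",
                  "smoking": "137..", "eosinophil": "42K.."}


class EmptyCohortError(ValueError):
    """Requested a synthetic cohort of zero patients."""


def _day(d: dt.date) -> int:
    return np.datetime64(d, "D").astype(int)


def _dates(days: np.ndarray) -> pd.Series:
    return pd.Series(np.asarray(days, dtype="int64")
                     .astype("datetime64[D]").astype("datetime64[ns]"))


def generation_grid(config: GenerationConfig) -> list[dt.date]:
    return [config.reference_date
            - relativedelta(months=config.interval_months * k)
            for k in range(config.n_time_points - 1, -1, -1)]


# --------------------------------------------------------------------------
# Patients + diagnoses
# --------------------------------------------------------------------------

def generate_patients(config: GenerationConfig, rng: np.random.Generator
                      ) -> pd.DataFrame:
    """Internal per-patient frame (superset of the patients table columns).

    Ages at the reference date are uniform on [5, 11] for the child
    fraction and [12, 80] otherwise; registration guarantees >=12 months'
    enrolment before the reference date for the eligible fraction; every
    patient gets one asthma diagnosis at or after registration start.
    """
    n = config.n_patients
    if n == 0:
        raise EmptyCohortError("n_patients is 0: nothing to generate")
    ref = config.reference_date
    ref_day = _day(ref)
    start_day = _day(config.study_start)
    end_day = _day(config.study_end)

    pid = np.array([f"p{i:06d}" for i in range(1, n + 1)])
    is_child = rng.random(n) < config.child_fraction
    age = np.where(is_child, rng.integers(5, 12, n), rng.integers(12, 81, n))

    # birth = reference - age years - u days, u in [0, 364]: completed age
    # at the reference date equals the drawn age exactly
    birth = np.empty(n, dtype="int64")
    for a in np.unique(age):
        base = _day(ref - relativedelta(years=int(a)))
        sel = age == a
        birth[sel] = base - rng.integers(0, 365, int(sel.sum()))
    # note: per-age draws consume rng in age order (deterministic)

    male_p = np.where(is_child, 0.601, 0.449)
    gender = np.where(rng.random(n) < male_p, "M", "F")

    eligible_intended = rng.random(n) < config.eligible_fraction
    reg_start = np.where(
        eligible_intended,
        start_day + rng.integers(-730, 1096, n),
        ref_day - rng.integers(1, 365, n))          # too late to qualify
    dereg = rng.random(n) < config.early_deregistration
    reg_end = np.where(
        dereg,
        np.minimum(reg_start + 365 + rng.integers(0, 1500, n), ref_day - 1),
        end_day + rng.integers(0, 366, n))
    reg_end = np.maximum(reg_end, reg_start + 30)

    acceptable = (rng.random(n) < config.acceptable_fraction).astype(int)
    trial = (rng.random(n) < config.trial_fraction).astype(int)

    diag = reg_start + rng.integers(0, config.diagnosis_lag_max_days + 1, n)
    diag = np.minimum(diag, np.minimum(ref_day - 30, reg_end))
    diag = np.maximum(diag, reg_start)

    return pd.DataFrame({
        "patient_id": pid,
        "birth_date": _dates(birth),
        "gender": gender,
        "registration_start": _dates(reg_start),
        "registration_end": _dates(reg_end),
        "acceptable_flag": acceptable,
        "trial_flag": trial,
        "uts_date": pd.Timestamp(config.study_start),
        "age_group": np.where(is_child, "child", "adult"),
        "diagnosis_date": _dates(diag),
        "_reg_start_day": reg_start,
        "_reg_end_day": reg_end,
        "_diag_day": diag,
    })


def patients_table(internal: pd.DataFrame) -> pd.DataFrame:
    cols = ["patient_id", "birth_date", "gender", "registration_start",
            "registration_end", "acceptable_flag", "trial_flag", "uts_date"]
    return internal[cols].copy()


def diagnoses_table(internal: pd.DataFrame, rng: np.random.Generator
                    ) -> pd.DataFrame:
    codes = np.array(_ASTHMA_CODES)[
        rng.integers(0, len(_ASTHMA_CODES), len(internal))]
    return pd.DataFrame({
        "patient_id": internal["patient_id"].to_numpy(),
        "diagnosis_date": internal["diagnosis_date"].to_numpy(),
        "code": codes})


# --------------------------------------------------------------------------
# Trajectories
# --------------------------------------------------------------------------

def plan_trajectories(internal: pd.DataFrame, config: GenerationConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Ground-truth step per patient per in-registration grid point.

    The first diagnosed point draws from the initial step distribution of
    the patient's age group; later points follow the transition kernel;
    points before the diagnosis date are 'undiagnosed' (-2).  Points
    outside the registration window (or before study start) are absent.
    """
    grid = generation_grid(config)
    grid_days = np.array([_day(t) for t in grid])
    n = len(internal)
    T = len(grid)
    start_day = _day(config.study_start)

    reg_s = internal["_reg_start_day"].to_numpy()
    reg_e = internal["_reg_end_day"].to_numpy()
    diag = internal["_diag_day"].to_numpy()
    is_child = (internal["age_group"] == "child").to_numpy()

    init_cum = {g: np.cumsum(config.initial_step_distribution[g])
                for g in ("child", "adult")}
    kern_cum = {g: np.cumsum(np.asarray(config.transition_kernel[g]), axis=1)
                for g in ("child", "adult")}

    status = np.full((n, T), UNDIAGNOSED, dtype=np.int64)
    in_window = np.zeros((n, T), dtype=bool)
    has_prev = np.zeros(n, dtype=bool)
    prev_step = np.zeros(n, dtype=np.int64)
    for t in range(T):
        day = grid_days[t]
        inw = (reg_s <= day) & (day <= reg_e) & (day >= start_day)
        in_window[:, t] = inw
        diagnosed = inw & (day >= diag)
        u = rng.random(n)
        step_t = np.zeros(n, dtype=np.int64)
        for g, gsel in (("child", is_child), ("adult", ~is_child)):
            newly = diagnosed & ~has_prev & gsel
            if newly.any():
                step_t[newly] = np.searchsorted(init_cum[g], u[newly],
                                                side="right")
            cont = diagnosed & has_prev & gsel
            if cont.any():
                rows = kern_cum[g][prev_step[cont]]
                step_t[cont] = (u[cont, None] > rows).sum(axis=1)
        step_t = np.clip(step_t, 0, 5)
        status[diagnosed, t] = step_t[diagnosed]
        prev_step = np.where(diagnosed, step_t, prev_step)
        has_prev |= diagnosed

    pidx, tidx = np.nonzero(in_window)
    return pd.DataFrame({
        "patient_id": internal["patient_id"].to_numpy()[pidx],
        "age_group": internal["age_group"].to_numpy()[pidx],
        "t_index": tidx,
        "time_point": _dates(grid_days[tidx]).to_numpy(),
        "planned_step": status[pidx, tidx]})


def trajectory_truth_table(plan: pd.DataFrame) -> pd.DataFrame:
    out = plan[["patient_id", "time_point", "planned_step"]].copy()
    out["planned_step"] = out["planned_step"].map(
        lambda s: "undiagnosed" if s == UNDIAGNOSED else str(int(s)))
    return out


# --------------------------------------------------------------------------
# Prescriptions
# --------------------------------------------------------------------------

def _script_templates(config: GenerationConfig) -> pd.DataFrame:
    """One row per script emitted for a (step, route) at offsets from t."""
    dur = config.script_duration_days
    # four repeats ending at t: coverage [t-3*dur, t+dur) chains to the next
    # grid point's coverage with a gap inside the grace period, while a
    # category dropped at the next point still runs out of grace before it
    reg_offsets = (-3 * dur, -2 * dur, -dur, 0)
    rows: list[tuple] = []   # step, route, category, offset, duration, level
    for step in (1, 2, 3, 4, 5):
        if step == 1:
            for off in reg_offsets:
                rows.append((step, "", "SABA", off, dur, ""))
            continue
        rows.append((step, "", "SABA", -dur, dur, ""))
        level = "low" if step in (2, 3) else "high"
        for off in reg_offsets:
            rows.append((step, "", "ICS", off, dur, level))
        if step >= 3:
            for off in reg_offsets:
                rows.append((step, "", "LABA", off, dur, ""))
        if step == 5:
            for off in (-60, -45, -30, -15, 0):
                rows.append((step, "A", "OCS", off, 7, ""))
            rows.append((step, "B", "OCS", -dur, dur, ""))
    return pd.DataFrame(rows, columns=["step", "route", "category",
                                       "offset", "duration", "dose_level"])


def render_prescriptions(plan: pd.DataFrame, internal: pd.DataFrame,
                         config: GenerationConfig, rng: np.random.Generator
                         ) -> pd.DataFrame:
    """Emit prescription records realising each planned step."""
    treated = plan[plan["planned_step"] >= 1].copy()
    if len(treated) == 0:
        return pd.DataFrame(columns=[
            "patient_id", "issue_date", "drug_category", "substance",
            "duration_days", "ics_daily_dose_ug", "ocs_strength_mg",
            "pack_size"])
    treated["route"] = np.where(
        treated["planned_step"] == 5,
        np.where(rng.random(len(treated)) < config.rescue_route_fraction,
                 "A", "B"),
        "")
    templates = _script_templates(config)
    scripts = treated.rename(columns={"planned_step": "step"}).merge(
        templates, on="step", how="inner")
    scripts = scripts[(scripts["route_y"] == "")
                      | (scripts["route_y"] == scripts["route_x"])]

    day = scripts["time_point"].to_numpy().astype("datetime64[D]").astype("int64")
    issue = day + scripts["offset"].to_numpy()
    if config.gap_jitter_days > 0:
        issue = issue + rng.integers(-config.gap_jitter_days,
                                     config.gap_jitter_days + 1, len(scripts))
    reg = internal.set_index("patient_id")
    reg_s = scripts["patient_id"].map(reg["_reg_start_day"]).to_numpy()
    reg_e = scripts["patient_id"].map(reg["_reg_end_day"]).to_numpy()
    issue = np.clip(issue, reg_s, reg_e)

    age_group = scripts["age_group"]
    dose = pd.Series(
        [ICS_DOSE_UG.get((g, lvl), np.nan)
         for g, lvl in zip(age_group, scripts["dose_level"])],
        index=scripts.index)
    out = pd.DataFrame({
        "patient_id": scripts["patient_id"].to_numpy(),
        "issue_date": _dates(issue).to_numpy(),
        "drug_category": scripts["category"].to_numpy(),
        "substance": scripts["category"].map(SUBSTANCE).to_numpy(),
        "duration_days": scripts["duration"].to_numpy(),
        "ics_daily_dose_ug": dose.to_numpy(),
        "ocs_strength_mg": np.where(scripts["category"] == "OCS", 5.0, np.nan),
        "pack_size": scripts["duration"].to_numpy().astype(float),
    })
    if config.script_dropout > 0:
        out = out[rng.random(len(out)) >= config.script_dropout]
    return (out.sort_values(["patient_id", "issue_date", "drug_category"])
            .reset_index(drop=True))


# --------------------------------------------------------------------------
# Clinical events
# --------------------------------------------------------------------------

def render_clinical_events(internal: pd.DataFrame, config: GenerationConfig,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Sample covariate events per configured prevalence.

    Review events fall in the one/two-year review windows (a configurable
    share carrying codes only in the wide QOF list); 'ever' events fall
    anywhere in registration before the reference date; smoking events
    carry the status in the value column.
    """
    n = len(internal)
    ref_day = _day(config.reference_date)
    reg_s = internal["_reg_start_day"].to_numpy()
    reg_e = internal["_reg_end_day"].to_numpy()
    pid = internal["patient_id"].to_numpy()
    is_child = (internal["age_group"] == "child").to_numpy()

    def prev(key: str) -> np.ndarray:
        ch = config.event_prevalences["child"].get(key, 0.0)
        ad = config.event_prevalences["adult"].get(key, 0.0)
        return np.where(is_child, ch, ad)

    def uniform_dates(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        span = np.maximum(hi - lo, 0)
        return lo + (rng.random(n) * (span + 1)).astype("int64")

    frames: list[pd.DataFrame] = []

    def emit(mask: np.ndarray, dates: np.ndarray, code: str, category: str,
             value: np.ndarray | str = "") -> None:
        dates = np.clip(dates, reg_s, reg_e)
        sel = mask & (dates >= reg_s) & (dates <= reg_e)
        if not sel.any():
            return
        vals = value[sel] if isinstance(value, np.ndarray) else value
        frames.append(pd.DataFrame({
            "patient_id": pid[sel], "event_date": _dates(dates[sel]).to_numpy(),
            "code": code, "event_category": category, "value": vals}))

    w1a, w1b = _day(dt.date(2015, 8, 1)), min(_day(dt.date(2016, 5, 31)), ref_day)
    w2a, w2b = _day(dt.date(2014, 8, 1)), _day(dt.date(2015, 7, 31))
    lo1, hi1 = np.maximum(reg_s, w1a), np.minimum(reg_e, w1b)
    lo2, hi2 = np.maximum(reg_s, w2a), np.minimum(reg_e, w2b)
    emit(rng.random(n) < prev("review_1y"), uniform_dates(lo1, hi1),
         _REVIEW_CORE, "review")
    emit(rng.random(n) < prev("review_2y_extra"), uniform_dates(lo2, hi2),
         _REVIEW_CORE, "review")
    emit(rng.random(n) < prev("review_wide_only"), uniform_dates(lo1, hi1),
         _REVIEW_WIDE_ONLY, "review")

    hist_lo, hist_hi = reg_s, np.minimum(reg_e, ref_day)
    for key, category in (("spirometry", "spirometry"),
                          ("peakflow_home", "peak_flow_home"),
                          ("copd", "copd"), ("eczema", "eczema"),
                          ("hayfever", "hayfever"),
                          ("rhinosinusitis", "rhinosinusitis")):
        emit(rng.random(n) < prev(key), uniform_dates(hist_lo, hist_hi),
             _CATEGORY_CODE[category], category)
    emit(rng.random(n) < prev("peakflow_12m"),
         uniform_dates(np.maximum(reg_s, ref_day - 365), hist_hi),
         _CATEGORY_CODE["peak_flow"], "peak_flow")

    p_cur, p_ex, p_nev = prev("smoking_current"), prev("smoking_ex"), \
        prev("smoking_never")
    u = rng.random(n)
    smoker_status = np.select(
        [u < p_cur, u < p_cur + p_ex, u < p_cur + p_ex + p_nev],
        ["current", "ex", "never"], default="")
    emit(smoker_status != "", uniform_dates(hist_lo, hist_hi),
         _CATEGORY_CODE["smoking"], "smoking", value=smoker_status)

    eos_mask = rng.random(n) < prev("eosinophil")
    eos_val = np.char.mod("%.0f", rng.lognormal(5.4, 0.6, n))
    emit(eos_mask, uniform_dates(hist_lo, hist_hi),
         _CATEGORY_CODE["eosinophil"], "eosinophil", value=eos_val)

    if not frames:
        return pd.DataFrame(columns=["patient_id", "event_date", "code",
                                     "event_category", "value"])
    events = pd.concat(frames, ignore_index=True)
    return (events.sort_values(["patient_id", "event_date", "event_category"])
            .reset_index(drop=True))


# --------------------------------------------------------------------------
# Top-level
# --------------------------------------------------------------------------

def simulate_raw_tables(config: GenerationConfig
                        ) -> tuple[RawTables, pd.DataFrame]:
    """Generate a full validated RawTables plus the ground-truth plan."""
    rng = np.random.default_rng(config.seed)
    internal = generate_patients(config, rng)
    diagnoses = diagnoses_table(internal, rng)
    plan = plan_trajectories(internal, config, rng)
    prescriptions = render_prescriptions(plan, internal, config, rng)
    events = render_clinical_events(internal, config, rng)
    raw = RawTables(patients=patients_table(internal),
                    diagnoses=diagnoses,
                    prescriptions=prescriptions,
                    clinical_events=events,
                    trajectory_truth=trajectory_truth_table(plan))
    log.info("simulated %d patients, %d prescriptions, %d clinical events",
             len(internal), len(prescriptions), len(events))
    return raw, plan
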