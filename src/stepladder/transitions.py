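"""Time-point grid, per-point step assignment, movement and transitions.

Steps are assigned *at* each grid date (point-in-time regimen; a grace
extension carries the prior step), with left-censoring before the study
start or the patient's registration and an 'undiagnosed' status before the
first asthma diagnosis.  Movement within an interval compares the steps at
its two bounding points; transition matrices pool consecutive point pairs.
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd
from dateutil.relativedelta import relativedelta

from .config import (CENSORED, STEPS, UNDIAGNOSED, ConfigError, StudyConfig,
                     status_label)
from .steps import StepMappingConfig, default_mapping, map_regimen_to_step
from .sequence import bits_to_categories

log = logging.getLogger("stepladder")


def build_time_point_grid(config: StudyConfig) -> list[dt.date]:
    """Grid of assessment dates, anchored at the reference date.

    Steps back ``interval_months`` calendar months, ``n_time_points``
    points in total, returned in increasing order.  Under the defaults
    this is 18 points from 2007-12-01 to 2016-06-01.
    """
    if config.n_time_points < 2:
        raise ConfigError("n_time_points must be >= 2")
    ref = config.reference_date
    return [ref - relativedelta(months=config.interval_months * k)
            for k in range(config.n_time_points - 1, -1, -1)]


def refine_grid_config(config: StudyConfig, interval_months: int) -> StudyConfig:
    """Config whose grid covers the same span at a finer spacing.

    Used by the 3-month sensitivity variant: every base point is also a
    point of the refined grid.
    """
    base_span = config.interval_months * (config.n_time_points - 1)
    if base_span % interval_months:
        raise ConfigError(
            f"interval {interval_months} months does not tile the "
            f"{base_span}-month study span")
    return config.replace(interval_months=interval_months,
                          n_time_points=base_span // interval_months + 1)


# --------------------------------------------------------------------------
# Step per segment, assignment per time point
# --------------------------------------------------------------------------

def attach_steps(segments: pd.DataFrame, age_groups: pd.Series,
                 mapping: StepMappingConfig | None = None) -> pd.DataFrame:
    """Add ``step`` and ``anomaly`` columns to a segment table."""
    if mapping is None:
        mapping = default_mapping()
    segments = segments.copy()
    if len(segments) == 0:
        segments["step"] = pd.Series(dtype="int64")
        segments["anomaly"] = pd.Series(dtype=bool)
        return segments
    group = segments["patient_id"].map(age_groups)
    cache: dict[tuple, tuple[int, bool]] = {}
    steps = np.empty(len(segments), dtype=np.int64)
    anomalies = np.empty(len(segments), dtype=bool)
    keys = zip(segments["cat_bits"].to_numpy(), segments["ics_dose_band"],
               segments["ocs_mode"], group)
    for i, key in enumerate(keys):
        hit = cache.get(key)
        if hit is None:
            bits, band, mode, grp = key
            hit = map_regimen_to_step(bits_to_categories(bits), band, mode,
                                      grp, mapping)
            cache[key] = hit
        steps[i], anomalies[i] = hit
    segments["step"] = steps
    segments["anomaly"] = anomalies
    return segments


def assign_steps(segments: pd.DataFrame, cohort: pd.DataFrame,
                 config: StudyConfig,
                 grid: list[dt.date] | None = None) -> pd.DataFrame:
    """One status per eligible patient per grid point.

    Status precedence: censored (point outside max(study start,
    registration start) .. registration end) beats undiagnosed (point
    before first diagnosis) beats the step of the segment containing the
    point; a diagnosed, uncensored point covered by no segment is step 0.

    ``cohort`` needs patient_id, first_diagnosis_date, censor_start,
    censor_end (from cohort selection).  Returns a long table with
    ``status_code`` (ints; -1 censored, -2 undiagnosed) and ``status``.
    """
    if grid is None:
        grid = build_time_point_grid(config)
    grid_ts = pd.to_datetime(grid)
    pts = cohort[["patient_id", "first_diagnosis_date",
                  "censor_start", "censor_end", "age_group"]].copy()
    frame = pts.loc[pts.index.repeat(len(grid_ts))].reset_index(drop=True)
    frame["t_index"] = np.tile(np.arange(len(grid_ts)), len(pts))
    frame["time_point"] = np.tile(grid_ts.values, len(pts))

    frame["patient_id"] = frame["patient_id"].astype(object)
    if len(segments):
        seg = segments.sort_values(["patient_id", "start"])[
            ["patient_id", "start", "end", "step"]]
        seg = seg.assign(patient_id=seg["patient_id"].astype(object))
        frame = frame.sort_values(["time_point", "patient_id"], kind="stable")
        merged = pd.merge_asof(
            frame.sort_values("time_point"),
            seg.rename(columns={"start": "seg_start"}).sort_values("seg_start"),
            left_on="time_point", right_on="seg_start", by="patient_id",
            direction="backward")
        inside = merged["end"].notna() & (merged["time_point"] < merged["end"])
        merged["step"] = merged["step"].where(inside, 0)
    else:
        merged = frame.copy()
        merged["step"] = 0
    merged["step"] = merged["step"].fillna(0).astype("int64")

    status = merged["step"].to_numpy().copy()
    undiag = merged["time_point"] < merged["first_diagnosis_date"]
    status[undiag.to_numpy()] = UNDIAGNOSED
    censored = ((merged["time_point"] < merged["censor_start"])
                | (merged["time_point"] > merged["censor_end"]))
    status[censored.to_numpy()] = CENSORED
    merged["status_code"] = status
    merged["status"] = [status_label(s) for s in status]
    out = merged[["patient_id", "age_group", "t_index", "time_point",
                  "status_code", "status"]]
    return out.sort_values(["patient_id", "t_index"]).reset_index(drop=True)


# --------------------------------------------------------------------------
# Movement and transitions
# --------------------------------------------------------------------------

def _paired(assignments: pd.DataFrame) -> pd.DataFrame:
    """Consecutive-point pairs with both statuses in 0..5."""
    a = assignments.sort_values(["patient_id", "t_index"])
    prev = a.groupby("patient_id", sort=False)["status_code"].shift()
    pair = a.assign(prev_status=prev)
    pair = pair[(pair["prev_status"] >= 0) & (pair["status_code"] >= 0)]
    return pair.astype({"prev_status": "int64"})


def classify_within_interval(assignments: pd.DataFrame,
                             segments: pd.DataFrame | None = None,
                             any_change: bool = False) -> pd.DataFrame:
    """Label each patient-interval stepped_up / stepped_down / stable.

    The primary rule compares the steps at the interval's two endpoints;
    intra-interval excursions that return by the closing point count as
    stable.  With ``any_change=True`` an interval whose endpoints agree is
    still flagged as movement when any segment strictly inside it sits at
    a different step (direction from the largest excursion, up winning
    ties).  Endpoints that are censored or undiagnosed are excluded.
    """
    pair = _paired(assignments)
    up = pair["status_code"] > pair["prev_status"]
    down = pair["status_code"] < pair["prev_status"]
    cls = np.where(up, "stepped_up", np.where(down, "stepped_down", "stable"))
    out = pair[["patient_id", "age_group", "t_index", "time_point",
                "prev_status", "status_code"]].copy()
    out["movement"] = cls
    if any_change and segments is not None and len(segments):
        stable = out[out["movement"] == "stable"]
        seg = segments[["patient_id", "start", "end", "step"]]
        joined = stable.merge(seg, on="patient_id", how="left")
        # previous grid date: look up from the assignment table itself
        prev_dates = (assignments[["patient_id", "t_index", "time_point"]]
                      .rename(columns={"time_point": "prev_point"}))
        prev_dates = prev_dates.assign(t_index=prev_dates["t_index"] + 1)
        joined = joined.merge(prev_dates, on=["patient_id", "t_index"], how="left")
        t_curr = joined["time_point"]
        intersects = ((joined["start"] < t_curr)
                      & (joined["end"] > joined["prev_point"]))
        exc = joined[intersects & (joined["step"] != joined["status_code"])]
        if len(exc):
            agg = exc.groupby(["patient_id", "t_index"])["step"].agg(["max", "min"])
            out = out.merge(agg, left_on=["patient_id", "t_index"],
                            right_index=True, how="left")
            ex_up = out["max"].notna() & (out["max"] > out["status_code"]) \
                & (out["movement"] == "stable")
            ex_down = out["min"].notna() & (out["min"] < out["status_code"]) \
                & (out["movement"] == "stable") & ~ex_up
            out.loc[ex_up, "movement"] = "stepped_up"
            out.loc[ex_down, "movement"] = "stepped_down"
            out = out.drop(columns=["max", "min"])
    return out.reset_index(drop=True)


def movement_by_timepoint(movement: pd.DataFrame) -> pd.DataFrame:
    """Per age group and interval-closing point: movement counts and %."""
    tab = (movement.groupby(["age_group", "t_index", "time_point", "movement"])
           .size().unstack(fill_value=0).reset_index())
    for col in ("stepped_up", "stepped_down", "stable"):
        if col not in tab.columns:
            tab[col] = 0
    tab["n"] = tab[["stepped_up", "stepped_down", "stable"]].sum(axis=1)
    for col in ("stepped_up", "stepped_down", "stable"):
        tab[f"pct_{col}"] = np.where(
            tab["n"] > 0, 100.0 * tab[col] / tab["n"], np.nan)
    return tab


def compute_transition_matrix(assignments: pd.DataFrame,
                              age_group: str | None = None,
                              t_index: int | None = None) -> pd.DataFrame:
    """From-step x to-step counts and row percentages over steps 0-5.

    Pools all consecutive grid-point pairs (restrict with ``t_index`` = the
    closing point's index, or ``age_group``).  Rows with zero count get
    missing percentages rather than zeros.  Unlike the usual presentation
    that omits it, the staying-in-step-0 cell is reported, so every
    non-empty row sums to 100 within rounding.
    """
    pair = _paired(assignments)
    if age_group is not None:
        pair = pair[pair["age_group"] == age_group]
    if t_index is not None:
        pair = pair[pair["t_index"] == t_index]
    counts = (pair.groupby(["prev_status", "status_code"]).size()
              .unstack(fill_value=0)
              .reindex(index=list(STEPS), columns=list(STEPS), fill_value=0))
    counts.index.name = "from_step"
    counts.columns.name = "to_step"
    row_n = counts.sum(axis=1)
    pct = counts.div(row_n.where(row_n > 0), axis=0) * 100.0
    out = counts.add_prefix("n_to_")
    out = out.join(pct.add_prefix("pct_to_"))
    out["row_n"] = row_n
    return out.reset_index()


def transition_flows(assignments: pd.DataFrame) -> pd.DataFrame:
    """Pooled edge list (age_group, from_step, to_step, count)."""
    pair = _paired(assignments)
    return (pair.groupby(["age_group", "prev_status", "status_code"])
            .size().rename("count").reset_index()
            .rename(columns={"prev_status": "from_step",
                             "status_code": "to_step"}))


def compute_step_distribution(assignments: pd.DataFrame,
                              treated_only: bool = False) -> pd.DataFrame:
    """Share of patients per status at each time point.

    Censored and undiagnosed patients never enter the denominator;
    ``treated_only`` additionally drops step 0 (the untreated-but-
    diagnosed group), matching the "of those who were treated" view.
    """
    a = assignments
    tab = (a.groupby(["age_group", "t_index", "time_point", "status_code"])
           .size().rename("count").reset_index())
    in_step = tab["status_code"] >= (1 if treated_only else 0)
    denom = (tab[in_step].groupby(["age_group", "t_index"])["count"]
             .sum().rename("denominator"))
    tab = tab.merge(denom, left_on=["age_group", "t_index"],
                    right_index=True, how="left")
    tab["pct"] = np.where(
        in_step & (tab["denominator"] > 0),
        100.0 * tab["count"] / tab["denominator"], np.nan)
    if (denom == 0).any():
        log.warning("empty step-distribution denominator at some time points")
    tab["status"] = tab["status_code"].map(status_label)
    return tab
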