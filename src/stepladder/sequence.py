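"""Prescription sequences: cleaning, episodes, OCS rules, regimen timeline.

This module turns raw prescription rows into a piecewise-constant combined
regimen per patient, applying the classification assumptions of the
analysis:

* **grace period** — consecutive same-category scripts whose gap (next
  issue minus current coverage end) is at most ``grace_days`` belong to one
  continuous exposure episode; an episode carries its category for a
  further ``grace_days`` after coverage ends (discontinuation gaps keep the
  prior regimen);
* **overlap period** — two categories count as *combined* only where their
  coverage (before grace extension) intersects for at least
  ``overlap_days``; a shorter, later-starting transient exposure is
  omitted from the combined regimen for the whole co-presence of the two
  episodes;
* **rescue packs** — an oral corticosteroid script of less than 14 days'
  duration at >=5 mg strength is a rescue course; anything else is
  maintenance;
* **continuous/frequent OCS** — at least ``continuous_ocs_min_count``
  rescue courses inside a ``continuous_ocs_window_days`` window, or any
  maintenance course, opens a continuous-OCS period (extended by the grace
  period and merged when overlapping).

All intervals are half-open ``[start, end)`` in days.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import StudyConfig

log = logging.getLogger("stepladder")

#: bit assigned to each category for fast set algebra
CATEGORY_BITS = {c: 1 << i for i, c in enumerate(
    ("SABA", "SAMA", "ICS", "LABA", "LAMA", "LTRA", "THEOPHYLLINE",
     "CROMONE", "OCS"))}
_ICS_BIT = CATEGORY_BITS["ICS"]
_OCS_BIT = CATEGORY_BITS["OCS"]

_BAND_CODES = {0: "none", 1: "low", 2: "high"}
_OCS_CODES = {0: "none", 1: "rescue_only", 2: "continuous"}


def _days(series: pd.Series) -> np.ndarray:
    return series.values.astype("datetime64[D]").astype("int64")


def _to_dates(days: np.ndarray) -> pd.Series:
    return pd.Series(days.astype("datetime64[D]"))


def bits_to_categories(bits: int) -> frozenset:
    return frozenset(c for c, b in CATEGORY_BITS.items() if bits & b)


# --------------------------------------------------------------------------
# Cleaning
# --------------------------------------------------------------------------

def normalize_prescriptions(rx: pd.DataFrame, config: StudyConfig
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clean raw prescriptions; return ``(clean, corrections)``.

    Combination products written as e.g. ``ICS/LABA`` are expanded to one
    row per component, the ICS daily dose travelling with the ICS row.
    Missing durations are imputed from pack information
    (``pack_size / tablets_per_day``), else the per-category median of the
    patient's other scripts, else a configured default; durations are
    clipped to ``[min_duration_days, max_duration_days]``.  Every
    correction is logged with the rule applied.
    """
    corrections: list[dict] = []
    rx = rx.copy().reset_index(drop=True)
    rx["drug_category"] = rx["drug_category"].astype(str).str.strip().str.upper()

    # expand combination products (components separated by '/')
    is_combo = rx["drug_category"].str.contains("/", regex=False)
    if is_combo.any():
        combo = rx[is_combo]
        parts = combo["drug_category"].str.split("/")
        expanded = combo.loc[combo.index.repeat(parts.str.len())].copy()
        expanded["drug_category"] = np.concatenate(parts.to_numpy())
        # the ICS dose belongs to the ICS component only
        expanded.loc[expanded["drug_category"] != "ICS", "ics_daily_dose_ug"] = np.nan
        rx = pd.concat([rx[~is_combo], expanded], ignore_index=True)

    known = rx["drug_category"].isin(CATEGORY_BITS)
    for _, row in rx[~known].iterrows():
        corrections.append({"patient_id": row["patient_id"],
                            "issue_date": row["issue_date"],
                            "rule": "dropped_unknown_category",
                            "detail": row["drug_category"]})
    rx = rx[known].reset_index(drop=True)

    dur = pd.to_numeric(rx["duration_days"], errors="coerce")
    missing = dur.isna()
    # rule 1: pack arithmetic
    from_pack = missing & rx["pack_size"].notna() & (rx["pack_size"] > 0)
    if from_pack.any():
        dur.loc[from_pack] = rx.loc[from_pack, "pack_size"] / config.tablets_per_day
        for i in np.flatnonzero(from_pack.to_numpy()):
            corrections.append({"patient_id": rx.at[i, "patient_id"],
                                "issue_date": rx.at[i, "issue_date"],
                                "rule": "duration_from_pack",
                                "detail": f"pack_size={rx.at[i, 'pack_size']:g}"})
    # rule 2: per patient-category median of the other scripts
    missing = dur.isna()
    if missing.any():
        med = dur.groupby([rx["patient_id"], rx["drug_category"]]).transform("median")
        from_med = missing & med.notna()
        dur.loc[from_med] = med[from_med]
        for i in np.flatnonzero(from_med.to_numpy()):
            corrections.append({"patient_id": rx.at[i, "patient_id"],
                                "issue_date": rx.at[i, "issue_date"],
                                "rule": "duration_from_median",
                                "detail": f"median={med.iloc[i]:g}"})
    # rule 3: configured default
    missing = dur.isna()
    if missing.any():
        dur.loc[missing] = config.default_duration_days
        for i in np.flatnonzero(missing.to_numpy()):
            corrections.append({"patient_id": rx.at[i, "patient_id"],
                                "issue_date": rx.at[i, "issue_date"],
                                "rule": "duration_default",
                                "detail": f"default={config.default_duration_days}"})
    dur = dur.round()
    clipped = (dur < config.min_duration_days) | (dur > config.max_duration_days)
    if clipped.any():
        for i in np.flatnonzero(clipped.to_numpy()):
            corrections.append({"patient_id": rx.at[i, "patient_id"],
                                "issue_date": rx.at[i, "issue_date"],
                                "rule": "duration_clipped",
                                "detail": f"was={dur.iloc[i]:g}"})
        dur = dur.clip(config.min_duration_days, config.max_duration_days)
    rx["duration_days"] = dur.astype("int64")
    rx["end_date"] = rx["issue_date"] + pd.to_timedelta(rx["duration_days"], unit="D")

    corr = pd.DataFrame(corrections,
                        columns=["patient_id", "issue_date", "rule", "detail"])
    rx = rx.sort_values(["patient_id", "drug_category", "issue_date"],
                        kind="stable").reset_index(drop=True)
    return rx, corr


# --------------------------------------------------------------------------
# OCS classification
# --------------------------------------------------------------------------

def classify_ocs_prescriptions(rx: pd.DataFrame, config: StudyConfig
                               ) -> pd.DataFrame:
    """Label OCS rows 'rescue' or 'maintenance' (column ``ocs_class``).

    Rescue requires duration strictly below ``rescue_max_duration_days``
    *and* strength at least ``rescue_min_strength_mg``.  Missing strength
    defaults to maintenance — the conservative direction, since any
    maintenance course triggers the continuous-OCS rule — with a warning.
    """
    rx = rx.copy()
    rx["ocs_class"] = pd.NA
    is_ocs = rx["drug_category"] == "OCS"
    strength = pd.to_numeric(rx["ocs_strength_mg"], errors="coerce")
    rescue = (is_ocs
              & (rx["duration_days"] < config.rescue_max_duration_days)
              & (strength >= config.rescue_min_strength_mg))
    rx.loc[is_ocs, "ocs_class"] = "maintenance"
    rx.loc[rescue, "ocs_class"] = "rescue"
    n_missing = int((is_ocs & strength.isna()).sum())
    if n_missing:
        log.warning("%d OCS prescription(s) with missing strength classified "
                    "as maintenance", n_missing)
    return rx


# --------------------------------------------------------------------------
# Episodes
# --------------------------------------------------------------------------

def build_category_episodes(rx: pd.DataFrame, grace_days: int
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge same-category scripts into exposure episodes.

    Two consecutive scripts of one category belong to the same episode iff
    ``next issue - running coverage end <= grace_days`` (boundary
    inclusive).  Returns ``(episodes, rx)`` where ``rx`` gains an
    ``episode_id`` column.
    """
    rx = rx.sort_values(["patient_id", "drug_category", "issue_date"],
                        kind="stable").reset_index(drop=True)
    if len(rx) == 0:
        episodes = pd.DataFrame(columns=[
            "patient_id", "category", "episode_id", "start_date",
            "coverage_end", "grace_end"])
        rx["episode_id"] = pd.Series(dtype="int64")
        return episodes, rx
    keys = [rx["patient_id"], rx["drug_category"]]
    grp = rx.groupby(keys, sort=False)
    running_end = grp["end_date"].cummax()
    prev_end = running_end.groupby(keys, sort=False).shift()
    gap = (rx["issue_date"] - prev_end).dt.days
    new_episode = gap.isna() | (gap > grace_days)
    rx["episode_id"] = new_episode.cumsum().astype("int64") - 1

    episodes = (rx.groupby("episode_id", sort=True)
                  .agg(patient_id=("patient_id", "first"),
                       category=("drug_category", "first"),
                       start_date=("issue_date", "min"),
                       coverage_end=("end_date", "max"))
                  .reset_index())
    episodes["grace_end"] = episodes["coverage_end"] + pd.Timedelta(days=grace_days)
    return episodes, rx


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/touching [start, end) intervals per patient."""
    if len(df) == 0:
        return df
    df = df.sort_values(["patient_id", "start", "end"]).reset_index(drop=True)
    prev_end = (df.groupby("patient_id", sort=False)["end"]
                  .apply(lambda s: s.cummax().shift())
                  .reset_index(drop=True))
    new_run = prev_end.isna() | (df["start"] > prev_end)
    run = new_run.cumsum()
    return (df.groupby(run)
              .agg(patient_id=("patient_id", "first"),
                   start=("start", "min"), end=("end", "max"))
              .reset_index(drop=True))


def detect_continuous_ocs(rx: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Continuous-OCS periods per patient as [start, end) dates.

    A period opens where a window of ``continuous_ocs_window_days`` holds
    at least ``continuous_ocs_min_count`` rescue courses (the period spans
    the first issue to the coverage end of the qualifying run), or where
    any maintenance course exists (spanning its coverage).  Periods are
    extended by the grace period and merged when overlapping.
    """
    ocs = rx[rx["drug_category"] == "OCS"]
    pieces: list[pd.DataFrame] = []
    maint = ocs[ocs["ocs_class"] == "maintenance"]
    if len(maint):
        pieces.append(pd.DataFrame({
            "patient_id": maint["patient_id"].to_numpy(),
            "start": maint["issue_date"].to_numpy(),
            "end": (maint["end_date"]
                    + pd.Timedelta(days=config.grace_days)).to_numpy()}))
    rescue = ocs[ocs["ocs_class"] == "rescue"].sort_values(
        ["patient_id", "issue_date"])
    k = config.continuous_ocs_min_count
    if len(rescue):
        counts = rescue.groupby("patient_id")["issue_date"].transform("size")
        rescue = rescue[counts >= k]
    for pid, grp in rescue.groupby("patient_id", sort=False):
        iss = _days(grp["issue_date"])
        ends = _days(grp["end_date"])
        rows = []
        for i in range(len(iss) - k + 1):
            if iss[i + k - 1] - iss[i] <= config.continuous_ocs_window_days:
                rows.append((iss[i], ends[i:i + k].max() + config.grace_days))
        if rows:
            arr = np.array(rows)
            pieces.append(pd.DataFrame({
                "patient_id": pid,
                "start": _to_dates(arr[:, 0]).to_numpy(),
                "end": _to_dates(arr[:, 1]).to_numpy()}))
    if not pieces:
        return pd.DataFrame(columns=["patient_id", "start", "end"])
    periods = pd.concat(pieces, ignore_index=True)
    return _merge_intervals(periods)


# --------------------------------------------------------------------------
# Regimen timeline
# --------------------------------------------------------------------------

def _patient_segments(starts, cov_ends, grace_ends, cat_bits,
                      ics_iss, ics_end, ics_dose,
                      ocs_starts, ocs_ends,
                      overlap_days: int, high_threshold: float):
    """Piecewise-constant regimen for one patient (all inputs int days).

    ``starts/cov_ends/grace_ends/cat_bits`` describe the non-OCS *and* OCS
    episodes (OCS episodes carry the OCS bit and only feed ocs_mode);
    ``ocs_starts/ends`` are the continuous-OCS periods.  Returns parallel
    lists (seg_start, seg_end, bits, band_code, ocs_code).
    """
    n = len(starts)
    # ---- overlap qualification: suppress transient later-starting episodes
    supp: list[tuple[int, int, int]] = []  # (episode index, start, end)
    if n > 1:
        non_ocs = np.flatnonzero((cat_bits & _OCS_BIT) == 0)
        s, ce, ge, cb = (starts[non_ocs], cov_ends[non_ocs],
                         grace_ends[non_ocs], cat_bits[non_ocs])
        ov_s = np.maximum(s[:, None], s[None, :])
        ov_e = np.minimum(ce[:, None], ce[None, :])
        ov = ov_e - ov_s
        cand = ((ov > 0) & (ov < overlap_days)
                & (cb[:, None] != cb[None, :]))
        for i, j in zip(*np.nonzero(np.triu(cand, 1))):
            if s[j] > s[i]:
                later, other = j, i
            elif s[i] > s[j]:
                later, other = i, j
            else:
                li, lj = ce[i] - s[i], ce[j] - s[j]
                if li == lj:
                    continue    # identical spans: suppress neither
                later, other = (i, j) if li < lj else (j, i)
            e = min(ge[later], ge[other])
            if e > s[later]:
                supp.append((int(non_ocs[later]), int(s[later]), int(e)))

    # ---- elementary boundaries
    parts = [starts, grace_ends]
    if len(ics_iss):
        parts += [ics_iss, ics_end]
    if len(ocs_starts):
        parts += [ocs_starts, ocs_ends]
    if supp:
        sup_arr = np.array([(a, b) for _, a, b in supp], dtype=np.int64)
        parts += [sup_arr[:, 0], sup_arr[:, 1]]
    bounds = np.unique(np.concatenate(parts))
    if len(bounds) < 2:
        return [], [], [], [], []
    d = bounds[:-1]                                  # probe day per interval
    active = (starts[None, :] <= d[:, None]) & (d[:, None] < grace_ends[None, :])
    for idx, a, b in supp:
        active[(d >= a) & (d < b), idx] = False
    bits = np.bitwise_or.reduce(np.where(active, cat_bits[None, :], 0), axis=1)

    # ---- ICS dose band (mean daily dose of covering scripts, carried
    # forward through gaps and grace within the exposure)
    band = np.zeros(len(d), dtype=np.int8)
    has_ics = (bits & _ICS_BIT) != 0
    if has_ics.any() and len(ics_iss):
        cover = (ics_iss[None, :] <= d[:, None]) & (d[:, None] < ics_end[None, :])
        cnt = cover.sum(axis=1)
        dose = np.zeros(len(d))
        np.divide(cover @ ics_dose, cnt, out=dose, where=cnt > 0)
        covered_idx = np.where(cnt > 0, np.arange(len(d)), -1)
        last = np.maximum.accumulate(covered_idx)
        dose = np.where(cnt > 0, dose, np.where(last >= 0, dose[np.maximum(last, 0)], 0.0))
        band[has_ics] = np.where(dose[has_ics] > high_threshold, 2, 1)

    # ---- OCS mode
    ocs_code = np.zeros(len(d), dtype=np.int8)
    has_ocs_bit = (bits & _OCS_BIT) != 0
    ocs_code[has_ocs_bit] = 1
    if len(ocs_starts):
        cont = ((ocs_starts[None, :] <= d[:, None])
                & (d[:, None] < ocs_ends[None, :])).any(axis=1)
        ocs_code[cont] = 2
    bits = bits & ~_OCS_BIT                          # OCS carried by ocs_code

    # ---- drop empty intervals, merge adjacent equal ones
    keep = (bits != 0) | (ocs_code != 0)
    seg_s, seg_e, seg_b, seg_band, seg_o = [], [], [], [], []
    for i in np.flatnonzero(keep):
        b0, b1 = int(bounds[i]), int(bounds[i + 1])
        if (seg_e and seg_e[-1] == b0 and seg_b[-1] == bits[i]
                and seg_band[-1] == band[i] and seg_o[-1] == ocs_code[i]):
            seg_e[-1] = b1
        else:
            seg_s.append(b0); seg_e.append(b1)
            seg_b.append(int(bits[i])); seg_band.append(int(band[i]))
            seg_o.append(int(ocs_code[i]))
    return seg_s, seg_e, seg_b, seg_band, seg_o


def build_regimen_timeline(episodes: pd.DataFrame, rx: pd.DataFrame,
                           ocs_periods: pd.DataFrame, config: StudyConfig,
                           age_groups: pd.Series) -> pd.DataFrame:
    """Sweep each patient's episodes into tiling regimen segments.

    ``age_groups`` maps patient_id -> 'child'/'adult' (the ICS dose-band
    threshold differs by age group).  Only patients present in
    ``age_groups`` are swept.  Returns one row per segment with half-open
    dates, the category set, the ICS dose band and the OCS mode.
    """
    ics_rx = rx[rx["drug_category"] == "ICS"]
    ep_by_pid = {pid: g for pid, g in episodes.groupby("patient_id", sort=False)} \
        if len(episodes) else {}
    ics_by_pid = {pid: g for pid, g in ics_rx.groupby("patient_id", sort=False)} \
        if len(ics_rx) else {}
    ocs_by_pid = {pid: g for pid, g in ocs_periods.groupby("patient_id", sort=False)} \
        if len(ocs_periods) else {}

    out: dict[str, list] = {"patient_id": [], "start": [], "end": [],
                            "cat_bits": [], "band_code": [], "ocs_code": []}
    empty = pd.DataFrame()
    for pid, group in age_groups.items():
        eps = ep_by_pid.get(pid)
        if eps is None or len(eps) == 0:
            continue
        ics = ics_by_pid.get(pid, empty)
        ocs = ocs_by_pid.get(pid, empty)
        threshold = config.ics_high_threshold_ug[group]
        seg_s, seg_e, seg_b, seg_band, seg_o = _patient_segments(
            _days(eps["start_date"]), _days(eps["coverage_end"]),
            _days(eps["grace_end"]),
            eps["category"].map(CATEGORY_BITS).to_numpy(dtype=np.int64),
            _days(ics["issue_date"]) if len(ics) else np.empty(0, np.int64),
            _days(ics["end_date"]) if len(ics) else np.empty(0, np.int64),
            ics["ics_daily_dose_ug"].to_numpy(dtype=float) if len(ics)
            else np.empty(0),
            _days(ocs["start"]) if len(ocs) else np.empty(0, np.int64),
            _days(ocs["end"]) if len(ocs) else np.empty(0, np.int64),
            config.overlap_days, threshold)
        out["patient_id"].extend([pid] * len(seg_s))
        out["start"].extend(seg_s)
        out["end"].extend(seg_e)
        out["cat_bits"].extend(seg_b)
        out["band_code"].extend(seg_band)
        out["ocs_code"].extend(seg_o)

    segments = pd.DataFrame(out)
    if len(segments) == 0:
        return pd.DataFrame(columns=["patient_id", "start", "end", "cat_bits",
                                     "categories", "ics_dose_band", "ocs_mode"])
    segments["categories"] = segments["cat_bits"].map(
        lambda b: "|".join(sorted(bits_to_categories(b))))
    segments["ics_dose_band"] = segments["band_code"].map(_BAND_CODES)
    segments["ocs_mode"] = segments["ocs_code"].map(_OCS_CODES)
    segments["start"] = pd.to_datetime(np.asarray(
        segments["start"], dtype="int64").astype("datetime64[D]")).astype("datetime64[ns]")
    segments["end"] = pd.to_datetime(np.asarray(
        segments["end"], dtype="int64").astype("datetime64[D]")).astype("datetime64[ns]")
    return segments.drop(columns=["band_code", "ocs_code"])
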