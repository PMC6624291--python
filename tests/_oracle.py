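"""Independent day-by-day oracle for exposure episodes and regimens.

Everything here works on literal boolean day arrays — scripts are painted
onto a calendar, gaps are filled day-wise, overlaps are measured by
counting days — so it shares no code with the event/interval sweep in
``stepladder.sequence``.  Tests compare the two routes for exact
agreement of day coverage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def daily_category_exposure(scripts: pd.DataFrame, grace_days: int,
                            day0: int, ndays: int) -> dict[str, np.ndarray]:
    """Category -> bool array of episode-coverage days (gap-filled <= grace).

    ``scripts`` needs columns drug_category, issue (int day), end (int day).
    """
    out: dict[str, np.ndarray] = {}
    for cat, grp in scripts.groupby("drug_category"):
        cover = np.zeros(ndays, dtype=bool)
        for iss, end in zip(grp["issue"], grp["end"]):
            cover[max(iss - day0, 0):max(end - day0, 0)] = True
        runs = _runs(cover)
        filled = cover.copy()
        for (s1, e1), (s2, e2) in zip(runs, runs[1:]):
            if s2 - e1 <= grace_days:
                filled[e1:s2] = True
        out[cat] = filled
    return out


def daily_regimen(scripts: pd.DataFrame, *, grace_days: int, overlap_days: int,
                  rescue_max_duration: int, rescue_min_strength: float,
                  ocs_min_count: int, ocs_window: int,
                  high_threshold: float, day0: int, ndays: int
                  ) -> tuple[list[frozenset], list[str], list[str]]:
    """Per-day (category set, ICS band, OCS mode) for one patient.

    Implements, day-wise: grace-filled episode coverage, grace extension,
    pairwise overlap qualification (a later-starting episode whose
    coverage intersection with an earlier episode of another category is
    shorter than the overlap period is hidden for the whole co-presence of
    the two episodes), the rescue/maintenance OCS split, the
    continuous-OCS rule, and the ICS dose band from the mean daily dose of
    covering scripts carried forward through gaps.
    """
    coverage = daily_category_exposure(scripts, grace_days, day0, ndays)
    episodes: list[tuple[str, int, int]] = []   # (category, start, end)
    presence: dict[str, np.ndarray] = {}
    for cat, cov in coverage.items():
        pres = np.zeros(ndays, dtype=bool)
        for s, e in _runs(cov):
            episodes.append((cat, s, e))
            pres[s:min(e + grace_days, ndays)] = True
        presence[cat] = pres

    # overlap qualification
    hidden = {cat: np.zeros(ndays, dtype=bool) for cat in coverage}
    eps = [e for e in episodes if e[0] != "OCS"]
    for i in range(len(eps)):
        for j in range(len(eps)):
            ci, si, ei = eps[i]
            cj, sj, ej = eps[j]
            if i == j or ci == cj:
                continue
            ov = min(ei, ej) - max(si, sj)
            if not (0 < ov < overlap_days):
                continue
            if (sj > si) or (sj == si and (ej - sj) < (ei - si)):
                a, b = sj, min(min(ei, ej) + grace_days, ndays)
                hidden[cj][a:b] = True

    # OCS classification + continuous periods
    cont = np.zeros(ndays, dtype=bool)
    ocs = scripts[scripts["drug_category"] == "OCS"]
    if len(ocs):
        dur = ocs["end"] - ocs["issue"]
        strength = pd.to_numeric(ocs["strength"], errors="coerce")
        is_rescue = (dur < rescue_max_duration) & (strength >= rescue_min_strength)
        for iss, end in zip(ocs.loc[~is_rescue, "issue"], ocs.loc[~is_rescue, "end"]):
            cont[max(iss - day0, 0):min(end - day0 + grace_days, ndays)] = True
        resc = ocs[is_rescue].sort_values("issue")
        iss = resc["issue"].to_numpy()
        ends = resc["end"].to_numpy()
        for i in range(len(iss) - ocs_min_count + 1):
            j = i + ocs_min_count - 1
            if iss[j] - iss[i] <= ocs_window:
                a = max(iss[i] - day0, 0)
                b = min(ends[i:j + 1].max() - day0 + grace_days, ndays)
                cont[a:b] = True

    # ICS day dose with carry-forward
    ics = scripts[scripts["drug_category"] == "ICS"]
    dose = np.zeros(ndays)
    if len(ics):
        total = np.zeros(ndays)
        count = np.zeros(ndays)
        for iss, end, d in zip(ics["issue"], ics["end"], ics["dose"]):
            a, b = max(iss - day0, 0), max(end - day0, 0)
            total[a:b] += d
            count[a:b] += 1
        covered = count > 0
        dose[covered] = total[covered] / count[covered]
        last = 0.0
        for i in range(ndays):
            if covered[i]:
                last = dose[i]
            else:
                dose[i] = last

    cats_by_day: list[frozenset] = []
    band_by_day: list[str] = []
    ocs_by_day: list[str] = []
    for d in range(ndays):
        cats = frozenset(c for c, p in presence.items()
                         if c != "OCS" and p[d] and not hidden[c][d])
        if "ICS" in cats:
            band = "high" if dose[d] > high_threshold else "low"
        else:
            band = "none"
        ocs_pres = presence.get("OCS")
        if cont[d]:
            mode = "continuous"
        elif ocs_pres is not None and ocs_pres[d]:
            mode = "rescue_only"
        else:
            mode = "none"
        cats_by_day.append(cats)
        band_by_day.append(band)
        ocs_by_day.append(mode)
    return cats_by_day, band_by_day, ocs_by_day


def segments_to_daily(segments: pd.DataFrame, day0: int, ndays: int
                      ) -> tuple[list[frozenset], list[str], list[str]]:
    """Expand one patient's segment table to per-day attributes."""
    cats = [frozenset()] * ndays
    band = ["none"] * ndays
    mode = ["none"] * ndays
    for _, row in segments.iterrows():
        s = max(int(row["start_day"]) - day0, 0)
        e = min(int(row["end_day"]) - day0, ndays)
        cset = frozenset(row["categories"].split("|")) if row["categories"] else frozenset()
        for d in range(s, e):
            cats[d] = cset
            band[d] = row["ics_dose_band"]
            mode[d] = row["ocs_mode"]
    return cats, band, mode
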