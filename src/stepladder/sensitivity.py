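"""Sensitivity variants, result-set diffing, covariate-by-step summaries.

Four one-dimensional variants of the base case are supported, each
changing exactly one assumption: a 3-month assessment interval, a 30-day
grace period, exclusion of patients with any COPD history, and the wide
QOF asthma-review code list.  ``diff_resultsets`` quantifies how far each
variant moves every output table from the base case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import StudyConfig
from .pipeline import ResultSet, TABLE_KEYS, run_analysis
from .tables import RawTables
from .transitions import refine_grid_config

log = logging.getLogger("stepladder")

#: variant name -> config override description
VARIANTS = {
    "interval_3m": "3-month assessment interval over the same span",
    "grace_30d": "grace period reduced from 90 to 30 days",
    "exclude_copd": "exclude patients with any COPD record",
    "wide_review_codes": "wide QOF review code list",
}


def variant_config(base: StudyConfig, name: str) -> StudyConfig:
    if name == "interval_3m":
        return refine_grid_config(base, 3)
    if name == "grace_30d":
        return base.replace(grace_days=30)
    if name == "exclude_copd":
        return base.replace(exclude_copd=True)
    if name == "wide_review_codes":
        return base.replace(review_code_list="qof_wide")
    raise ValueError(f"unknown variant {name!r}; valid: {sorted(VARIANTS)}")


def run_variant(raw: RawTables, base: StudyConfig, name: str,
                seed: int | None = None) -> ResultSet:
    """Re-run the full pipeline under one overridden assumption."""
    cfg = variant_config(base, name)
    log.info("sensitivity variant %s: %s", name, VARIANTS[name])
    return run_analysis(raw, cfg, seed=seed)


# --------------------------------------------------------------------------
# Diffing
# --------------------------------------------------------------------------

@dataclass
class DiffReport:
    """Per-table comparison of two result sets."""

    summary: pd.DataFrame          # table, max_abs_delta, n_cells_changed, ...
    deltas: dict[str, pd.DataFrame]

    def max_abs_delta(self, table: str) -> float:
        row = self.summary[self.summary["table"] == table]
        return float(row["max_abs_delta"].iloc[0]) if len(row) else float("nan")


def _diff_table(ta: pd.DataFrame, tb: pd.DataFrame, keys: list[str]
                ) -> tuple[pd.DataFrame, float, int, bool]:
    num_cols = [c for c in ta.columns
                if c not in keys and pd.api.types.is_numeric_dtype(ta[c])
                and c in tb.columns]
    a = ta.set_index(keys)[num_cols]
    b = tb.set_index(keys)[num_cols]
    idx = a.index.union(b.index)
    shape_changed = not a.index.equals(b.index)
    a, b = a.reindex(idx), b.reindex(idx)
    delta = b - a
    av, bv = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
    both = ~np.isnan(av) & ~np.isnan(bv)
    max_abs = float(np.abs(bv - av)[both].max()) if both.any() else 0.0
    changed = (both & (np.abs(bv - av) > 1e-12)) | (np.isnan(av) != np.isnan(bv))
    return delta.reset_index(), max_abs, int(changed.sum()), shape_changed


def diff_resultsets(a: ResultSet, b: ResultSet) -> DiffReport:
    """Cell-level deltas (b minus a) for every diffable shared table."""
    rows = []
    deltas: dict[str, pd.DataFrame] = {}
    for name, keys in TABLE_KEYS.items():
        if name not in a.tables or name not in b.tables:
            continue
        delta, max_abs, n_changed, shape_changed = _diff_table(
            a.tables[name], b.tables[name], keys)
        deltas[name] = delta
        rows.append({"table": name, "max_abs_delta": max_abs,
                     "n_cells_changed": n_changed,
                     "shape_changed": shape_changed})
    return DiffReport(summary=pd.DataFrame(rows), deltas=deltas)


# --------------------------------------------------------------------------
# Covariates by step
# --------------------------------------------------------------------------

def summarize_covariates_by_step(covariates: pd.DataFrame,
                                 assignments: pd.DataFrame,
                                 t_index: int | None = None
                                 ) -> dict[str, pd.DataFrame]:
    """Descriptive covariate table by treatment step, with test statistics.

    Uses each patient's step at the chosen time point (default: the last
    grid point, the reference-era end).  Categorical covariates get a
    proportion per step and a chi-squared test across steps (no continuity
    correction); continuous covariates (age, eosinophil count) get
    mean/SD per step and pairwise two-sample t statistics.  No
    multiple-testing correction is applied (stated in the notes column),
    matching the descriptive intent of the analysis.
    """
    if t_index is None:
        t_index = int(assignments["t_index"].max())
    at_ref = assignments[(assignments["t_index"] == t_index)
                         & (assignments["status_code"] >= 0)]
    merged = covariates.merge(
        at_ref[["patient_id", "status_code"]], on="patient_id")
    merged = merged.rename(columns={"status_code": "step"})

    bool_cols = [c for c in merged.columns if merged[c].dtype == bool]
    cat_cols = bool_cols + ["smoking_status"]
    cont_cols = [c for c in ("age_at_reference", "eosinophil_value")
                 if c in merged.columns]

    by_step_rows, test_rows, pairwise_rows = [], [], []
    steps_present = sorted(merged["step"].unique())
    note = "no multiplicity correction applied"
    for col in cat_cols:
        for step, sub in merged.groupby("step"):
            if col in bool_cols:
                by_step_rows.append({"covariate": col, "level": "true",
                                     "step": step, "n": int(sub[col].sum()),
                                     "pct": 100.0 * sub[col].mean()})
            else:
                for level, cnt in sub[col].value_counts().items():
                    by_step_rows.append({"covariate": col, "level": level,
                                         "step": step, "n": int(cnt),
                                         "pct": 100.0 * cnt / len(sub)})
        table = pd.crosstab(merged["step"], merged[col])
        table = table.loc[:, table.sum(axis=0) > 0]
        if len(steps_present) < 2 or table.shape[1] < 2:
            test_rows.append({"covariate": col, "test": "chi2",
                              "statistic": np.nan, "df": np.nan,
                              "p_value": np.nan,
                              "note": "skipped: constant or single group"})
            continue
        res = stats.chi2_contingency(table.to_numpy(), correction=False)
        test_rows.append({"covariate": col, "test": "chi2",
                          "statistic": float(res.statistic),
                          "df": float(res.dof), "p_value": float(res.pvalue),
                          "note": note})
    for col in cont_cols:
        groups = {}
        for step, sub in merged.groupby("step"):
            vals = pd.to_numeric(sub[col], errors="coerce").dropna()
            groups[step] = vals
            by_step_rows.append({"covariate": col, "level": "mean",
                                 "step": step, "n": len(vals),
                                 "pct": float(vals.mean()) if len(vals) else np.nan})
            by_step_rows.append({"covariate": col, "level": "sd",
                                 "step": step, "n": len(vals),
                                 "pct": float(vals.std(ddof=1))
                                 if len(vals) > 1 else np.nan})
        steps_avail = [s for s, v in groups.items() if len(v) > 1]
        for i, sa in enumerate(steps_avail):
            for sb in steps_avail[i + 1:]:
                t, p = stats.ttest_ind(groups[sa], groups[sb])
                pairwise_rows.append({"covariate": col, "step_a": sa,
                                      "step_b": sb, "t_statistic": float(t),
                                      "p_value": float(p), "note": note})
    return {
        "covariates_by_step": pd.DataFrame(
            by_step_rows, columns=["covariate", "level", "step", "n", "pct"]),
        "covariate_tests": pd.DataFrame(
            test_rows, columns=["covariate", "test", "statistic", "df",
                                "p_value", "note"]),
        "covariate_pairwise_t": pd.DataFrame(
            pairwise_rows, columns=["covariate", "step_a", "step_b",
                                    "t_statistic", "p_value", "note"]),
    }
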