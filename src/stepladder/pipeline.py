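"""End-to-end pipeline: simulate/load -> select -> sequence -> assign -> report.

``run_analysis`` executes the full classification on in-memory raw tables
and returns a :class:`ResultSet` of output tables; ``run_pipeline`` adds
file IO, stage logging, sensitivity variants and an atomically written
run manifest, so one command reproduces the whole study.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import (compute_covariates, eligible_age_groups, select_cohort)
from .config import GenerationConfig, StudyConfig
from .sequence import (build_category_episodes, build_regimen_timeline,
                       classify_ocs_prescriptions, detect_continuous_ocs,
                       normalize_prescriptions)
from .steps import assert_valid_mapping, default_mapping
from .tables import RawTables, atomic_write_csv, read_raw_tables, \
    write_raw_tables
from .transitions import (assign_steps, attach_steps, build_time_point_grid,
                          classify_within_interval, compute_step_distribution,
                          compute_transition_matrix, movement_by_timepoint,
                          transition_flows)

log = logging.getLogger("stepladder")

#: key columns per output table, used when diffing result sets
TABLE_KEYS: dict[str, list[str]] = {
    "distribution_by_timepoint": ["age_group", "t_index", "status_code"],
    "distribution_treated_by_timepoint": ["age_group", "t_index", "status_code"],
    "movement_by_timepoint": ["age_group", "t_index"],
    "transition_matrix_child": ["from_step"],
    "transition_matrix_adult": ["from_step"],
    "flows": ["age_group", "from_step", "to_step"],
    "covariate_prevalence": ["age_group", "covariate", "level"],
    "exclusions": ["reason"],
}


@dataclass
class ResultSet:
    """Output tables of one full pipeline run plus provenance metadata."""

    tables: dict[str, pd.DataFrame]
    config: StudyConfig
    config_hash: str
    seed: int | None = None
    version: str = ""
    created: str = ""
    # intermediate products kept for downstream checks
    cohort: pd.DataFrame | None = field(default=None, repr=False)
    covariates: pd.DataFrame | None = field(default=None, repr=False)
    assignments: pd.DataFrame | None = field(default=None, repr=False)
    segments: pd.DataFrame | None = field(default=None, repr=False)


def covariate_prevalence(covariates: pd.DataFrame) -> pd.DataFrame:
    """Per age group: share of patients with each covariate flag/level."""
    rows = []
    bool_cols = [c for c in covariates.columns
                 if covariates[c].dtype == bool]
    for group, sub in covariates.groupby("age_group"):
        n = len(sub)
        for col in bool_cols:
            rows.append({"age_group": group, "covariate": col, "level": "true",
                         "n": int(sub[col].sum()),
                         "pct": 100.0 * sub[col].mean() if n else float("nan")})
        for level, cnt in sub["smoking_status"].value_counts().items():
            rows.append({"age_group": group, "covariate": "smoking_status",
                         "level": level, "n": int(cnt),
                         "pct": 100.0 * cnt / n})
    return pd.DataFrame(rows, columns=["age_group", "covariate", "level",
                                       "n", "pct"])


def run_analysis(raw: RawTables, config: StudyConfig,
                 seed: int | None = None,
                 any_change_movement: bool = False) -> ResultSet:
    """Run the whole classification on in-memory tables."""
    mapping = config.step_mapping or default_mapping()
    assert_valid_mapping(mapping)

    cohort, exclusions = select_cohort(raw, config)
    age_groups = eligible_age_groups(cohort)
    covariates = compute_covariates(cohort, raw.clinical_events, config)

    eligible_ids = set(age_groups.index)
    rx = raw.prescriptions[raw.prescriptions["patient_id"].isin(eligible_ids)]
    rx, corrections = normalize_prescriptions(rx, config)
    rx = classify_ocs_prescriptions(rx, config)
    episodes, rx = build_category_episodes(rx, config.grace_days)
    ocs_periods = detect_continuous_ocs(rx, config)
    segments = build_regimen_timeline(episodes, rx, ocs_periods, config,
                                      age_groups)
    segments = attach_steps(segments, age_groups, mapping)
    log.info("sequence engine: %d prescriptions -> %d episodes -> %d segments",
             len(rx), len(episodes), len(segments))

    grid = build_time_point_grid(config)
    eligible = cohort[cohort["eligible"]]
    assignments = assign_steps(segments, eligible, config, grid)
    movement = classify_within_interval(assignments, segments,
                                        any_change=any_change_movement)
    tables = {
        "cohort": cohort,
        "exclusions": exclusions,
        "covariates": covariates,
        "corrections": corrections,
        "episodes": episodes,
        "regimen_segments": segments,
        "ocs_periods": ocs_periods,
        "assignments": assignments,
        "distribution_by_timepoint": compute_step_distribution(assignments, False),
        "distribution_treated_by_timepoint": compute_step_distribution(assignments, True),
        "movement_by_timepoint": movement_by_timepoint(movement),
        "transition_matrix_child": compute_transition_matrix(assignments, "child"),
        "transition_matrix_adult": compute_transition_matrix(assignments, "adult"),
        "flows": transition_flows(assignments),
        "covariate_prevalence": covariate_prevalence(covariates),
    }
    from .sensitivity import summarize_covariates_by_step
    tables.update(summarize_covariates_by_step(covariates, assignments))
    return ResultSet(tables=tables, config=config,
                     config_hash=config.config_hash(), seed=seed,
                     version=__version__,
                     created=dt.datetime.now().isoformat(timespec="seconds"),
                     cohort=cohort, covariates=covariates,
                     assignments=assignments, segments=segments)


# --------------------------------------------------------------------------
# File-level pipeline with manifest
# --------------------------------------------------------------------------

class _WarningCounter(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record: logging.LogRecord) -> None:
        self.count += 1


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tables(result: ResultSet, out_dir: Path) -> dict[str, str]:
    written = {}
    for name, table in result.tables.items():
        path = out_dir / f"{name}.csv"
        atomic_write_csv(table, path)
        written[name] = str(path.relative_to(out_dir))
    return written


def run_pipeline(config: StudyConfig, input_source, output_dir,
                 gen_config: GenerationConfig | None = None,
                 seed: int | None = None,
                 variants: list[str] | None = None) -> dict:
    """Execute the stage sequence and write all outputs plus manifest.json.

    ``input_source`` is a directory of raw CSV tables or the string
    ``'simulate'`` (the synthetic generator then uses ``gen_config``,
    defaulting to ``GenerationConfig(seed=seed)``).  Returns the manifest.
    """
    from .sensitivity import VARIANTS, diff_resultsets, run_variant
    from .simulate import simulate_raw_tables

    counter = _WarningCounter()
    log.addHandler(counter)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    outputs: dict[str, str] = {}
    input_digests: dict[str, str] = {}
    try:
        if input_source == "simulate":
            if gen_config is None:
                gen_config = GenerationConfig(seed=seed or 0)
            elif seed is not None:
                gen_config = gen_config.replace(seed=seed)
            raw, _plan = simulate_raw_tables(gen_config)
            stages.append("simulate")
            sim_dir = out / "input"
            for name, path in write_raw_tables(raw, sim_dir).items():
                outputs[f"input/{name}"] = str(path.relative_to(out))
                input_digests[path.name] = _digest(path)
        else:
            src = Path(input_source)
            raw = read_raw_tables(src)
            stages.append("load")
            for f in sorted(src.glob("*.csv")):
                input_digests[f.name] = _digest(f)

        result = run_analysis(raw, config, seed=seed)
        stages += ["select", "sequence", "map", "assign", "transitions"]
        outputs.update(_write_tables(result, out))

        if variants:
            stages.append("sensitivity")
            for name in variants:
                if name not in VARIANTS:
                    raise ValueError(
                        f"unknown variant {name!r}; valid: {sorted(VARIANTS)}")
                vres = run_variant(raw, config, name, seed=seed)
                vdir = out / "results" / name
                for tname, rel in _write_tables(vres, vdir).items():
                    outputs[f"results/{name}/{tname}"] = f"results/{name}/{rel}"
                report = diff_resultsets(result, vres)
                atomic_write_csv(report.summary, out / "diffs" / f"{name}.csv")
                outputs[f"diffs/{name}"] = f"diffs/{name}.csv"

        stages.append("report")
        manifest = {
            "config": config.to_dict(),
            "config_hash": result.config_hash,
            "generation_config": gen_config.to_dict() if gen_config else None,
            "seed": seed,
            "stages": stages,
            "input_digests": input_digests,
            "outputs": sorted(outputs.values()),
            "warnings": counter.count,
            "version": __version__,
            "created": dt.datetime.now().isoformat(timespec="seconds"),
        }
        fd, tmp = tempfile.mkstemp(dir=out, suffix=".tmp")
        with os.fdopen(fd, "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        os.replace(tmp, out / "manifest.json")
        return manifest
    finally:
        log.removeHandler(counter)
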