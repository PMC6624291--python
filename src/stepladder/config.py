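"""Study and simulation configuration.

All of the tunable constants of the analysis live here: the study window,
the classification rule parameters (grace period, overlap period, rescue-pack
definition, continuous-OCS rule), the time-point grid shape, and the
parameters of the synthetic cohort generator.  Every date is a
``datetime.date``; durations are integer days unless the field name says
months.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

log = logging.getLogger("stepladder")

#: Treatment steps of the 2014 BTS/SIGN ladder plus the study-defined step 0
#: (diagnosed but untreated).  Integers 0..5 everywhere.
STEPS = (0, 1, 2, 3, 4, 5)

#: Sentinel status codes used alongside steps in assignment tables.
CENSORED = -1
UNDIAGNOSED = -2

STATUS_LABELS = {CENSORED: "censored", UNDIAGNOSED: "undiagnosed"}


def status_label(code: int) -> str:
    return STATUS_LABELS.get(int(code), str(int(code)))


class ConfigError(ValueError):
    """Raised when a configuration fails validation."""


def _as_date(value: Any) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    if isinstance(value, str):
        return dt.date.fromisoformat(value)
    raise ConfigError(f"not a date: {value!r}")


# --------------------------------------------------------------------------
# Study configuration (classification + cohort rules)
# --------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Parameters of the cohort definition and the step-classification rules.

    Defaults reproduce the base case of the analysis: a ten-year study
    window ending 2016-08-31, a reference date of 2016-06-01 at which age
    and covariates are evaluated, and the standard rule constants — a
    90-day grace period before a same-category gap counts as
    discontinuation, a 30-day minimum overlap before two categories count
    as combined, rescue oral steroids defined as courses shorter than 14
    days at >=5 mg, and the continuous-OCS rule (>=5 rescue courses inside
    183 days, or any maintenance course).
    """

    study_start: dt.date = dt.date(2006, 9, 1)
    study_end: dt.date = dt.date(2016, 8, 31)
    reference_date: dt.date = dt.date(2016, 6, 1)
    min_age: int = 5
    max_age: int = 80
    child_age_max: int = 11
    min_enrolment_days: int = 365
    interval_months: int = 6
    n_time_points: int = 18
    grace_days: int = 90
    overlap_days: int = 30
    rescue_max_duration_days: int = 14      # exclusive bound
    rescue_min_strength_mg: float = 5.0
    continuous_ocs_min_count: int = 5
    continuous_ocs_window_days: int = 183
    # ICS daily-dose band thresholds (BDP-equivalent microgram/day); a mean
    # daily dose strictly above the threshold is the 'high' band.
    ics_high_threshold_ug: dict[str, float] = field(
        default_factory=lambda: {"child": 400.0, "adult": 800.0})
    # prescription cleaning
    default_duration_days: int = 30
    min_duration_days: int = 1
    max_duration_days: int = 183
    tablets_per_day: float = 1.0
    # covariate windows (annual-review windows of the base case)
    review_1y_window: tuple[dt.date, dt.date] = (
        dt.date(2015, 8, 1), dt.date(2016, 8, 31))
    review_2y_window: tuple[dt.date, dt.date] = (
        dt.date(2014, 8, 1), dt.date(2016, 8, 31))
    review_code_list: str = "qof_core"      # 'qof_core' | 'qof_wide'
    exclude_copd: bool = False
    # step mapping: None means the shipped default rule table
    step_mapping: Any = None

    def __post_init__(self) -> None:
        self.study_start = _as_date(self.study_start)
        self.study_end = _as_date(self.study_end)
        self.reference_date = _as_date(self.reference_date)
        self.review_1y_window = tuple(_as_date(d) for d in self.review_1y_window)
        self.review_2y_window = tuple(_as_date(d) for d in self.review_2y_window)
        self.validate()

    def validate(self) -> None:
        if not (self.study_start < self.reference_date <= self.study_end):
            raise ConfigError(
                "require study_start < reference_date <= study_end, got "
                f"{self.study_start} / {self.reference_date} / {self.study_end}")
        if not (self.grace_days >= self.overlap_days > 0):
            raise ConfigError(
                f"require grace_days >= overlap_days > 0, got "
                f"{self.grace_days} / {self.overlap_days}")
        for name in ("min_enrolment_days", "interval_months", "n_time_points",
                     "rescue_max_duration_days", "continuous_ocs_min_count",
                     "continuous_ocs_window_days", "default_duration_days",
                     "min_duration_days", "max_duration_days"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_time_points < 2:
            raise ConfigError("n_time_points must be >= 2")
        if not (0 < self.min_age <= self.child_age_max < self.max_age):
            raise ConfigError("require 0 < min_age <= child_age_max < max_age")
        if self.review_code_list not in ("qof_core", "qof_wide"):
            raise ConfigError(
                f"review_code_list must be 'qof_core' or 'qof_wide', "
                f"got {self.review_code_list!r}")

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, dt.date):
                v = v.isoformat()
            elif isinstance(v, tuple):
                v = [x.isoformat() if isinstance(x, dt.date) else x for x in v]
            elif f.name == "step_mapping" and v is not None:
                v = v.to_dict() if hasattr(v, "to_dict") else v
            d[f.name] = v
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def replace(self, **changes) -> "StudyConfig":
        return dataclasses.replace(self, **changes)


# --------------------------------------------------------------------------
# Generator configuration
# --------------------------------------------------------------------------

# Default 6x6 step transition kernels (rows = from-step 0..5, columns =
# to-step 0..5), one per age group.  Entries follow the printed pooled
# transition percentages of the source cohort; the unreported mass of each
# row (transitions into step 0) is assigned to the step-0 column and rows
# are renormalised to sum to one.
_CHILD_KERNEL = [
    # to:   0      1      2      3      4      5
    [0.967, 0.018, 0.012, 0.001, 0.002, 0.000],   # from 0
    [0.000, 0.840, 0.123, 0.011, 0.024, 0.001],   # from 1
    [0.000, 0.091, 0.879, 0.016, 0.013, 0.001],   # from 2
    [0.000, 0.081, 0.101, 0.786, 0.029, 0.003],   # from 3
    [0.000, 0.080, 0.027, 0.012, 0.879, 0.003],   # from 4 (rescaled)
    [0.000, 0.155, 0.116, 0.049, 0.090, 0.591],   # from 5 (rescaled)
]
_ADULT_KERNEL = [
    [0.924, 0.043, 0.025, 0.003, 0.005, 0.000],
    [0.000, 0.881, 0.069, 0.021, 0.027, 0.002],
    [0.000, 0.076, 0.900, 0.014, 0.009, 0.001],
    [0.000, 0.054, 0.018, 0.903, 0.022, 0.003],
    [0.000, 0.052, 0.008, 0.019, 0.914, 0.007],
    [0.000, 0.052, 0.020, 0.041, 0.120, 0.768],
]

# Initial (first diagnosed time point) step distributions, shaped like the
# start-of-study step mix: children ~3% untreated with treated mass mostly
# in steps 1-2; adults ~12% untreated with more step 3-4 use.
_CHILD_INIT = [0.032, 0.568, 0.286, 0.036, 0.070, 0.009]
_ADULT_INIT = [0.120, 0.314, 0.280, 0.100, 0.175, 0.011]

#: Per-covariate event prevalences used by the synthetic generator, keyed by
#: age group.  Values follow the cohort descriptives of the source study
#: where printed; the remainder are plausibility choices (see docs).
DEFAULT_EVENT_PREVALENCES: dict[str, dict[str, float]] = {
    "child": {
        "review_1y": 0.188, "review_2y_extra": 0.146, "review_wide_only": 0.022,
        "spirometry": 0.022, "peakflow_home": 0.05, "peakflow_12m": 0.05,
        "copd": 0.002, "eczema": 0.183, "hayfever": 0.098,
        "rhinosinusitis": 0.03, "eosinophil": 0.10,
        "smoking_current": 0.0, "smoking_ex": 0.0, "smoking_never": 0.0,
    },
    "adult": {
        "review_1y": 0.148, "review_2y_extra": 0.119, "review_wide_only": 0.016,
        "spirometry": 0.183, "peakflow_home": 0.08, "peakflow_12m": 0.10,
        "copd": 0.068, "eczema": 0.130, "hayfever": 0.168,
        "rhinosinusitis": 0.05, "eosinophil": 0.35,
        "smoking_current": 0.387, "smoking_ex": 0.133, "smoking_never": 0.480,
    },
}


def _normalize_rows(rows: list[list[float]]) -> list[list[float]]:
    # printed percentages round to 99.9-100.1 per row; rescale exactly
    out = []
    for row in rows:
        s = sum(row)
        out.append([x / s for x in row])
    return out


def _kernels_default() -> dict[str, list[list[float]]]:
    return {"child": _normalize_rows(_CHILD_KERNEL),
            "adult": _normalize_rows(_ADULT_KERNEL)}


def _init_default() -> dict[str, list[float]]:
    return {"child": _normalize_rows([_CHILD_INIT])[0],
            "adult": _normalize_rows([_ADULT_INIT])[0]}


@dataclass
class GenerationConfig:
    """Parameters of the synthetic CPRD-GOLD-like cohort generator.

    Trajectories are first-order Markov chains on the 6-monthly time-point
    grid; ``initial_step_distribution`` and ``transition_kernel`` are keyed
    by age group ('child'/'adult').  ``gap_jitter_days`` spreads script
    issue dates; ``script_dropout`` drops individual scripts — both default
    to a small, realistic level and are set to zero for exact-recovery
    checks.
    """

    n_patients: int = 1000
    study_start: dt.date = dt.date(2006, 9, 1)
    study_end: dt.date = dt.date(2016, 8, 31)
    reference_date: dt.date = dt.date(2016, 6, 1)
    child_fraction: float = 0.062           # 40,096 / 647,308 in the source cohort
    initial_step_distribution: dict[str, list[float]] = field(
        default_factory=_init_default)
    transition_kernel: dict[str, list[list[float]]] = field(
        default_factory=_kernels_default)
    event_prevalences: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(p) for g, p in
                                 DEFAULT_EVENT_PREVALENCES.items()})
    gap_jitter_days: int = 5
    script_dropout: float = 0.02
    eligible_fraction: float = 0.95
    early_deregistration: float = 0.02
    acceptable_fraction: float = 0.99
    trial_fraction: float = 0.005
    diagnosis_lag_max_days: int = 1825      # diagnosis offset after registration
    rescue_route_fraction: float = 0.7      # step-5 realised via rescue packs
    script_duration_days: int = 30
    interval_months: int = 6
    n_time_points: int = 18
    seed: int = 0

    def __post_init__(self) -> None:
        self.study_start = _as_date(self.study_start)
        self.study_end = _as_date(self.study_end)
        self.reference_date = _as_date(self.reference_date)
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        if not (self.study_start < self.reference_date <= self.study_end):
            raise ConfigError("require study_start < reference_date <= study_end")
        for name in ("child_fraction", "script_dropout", "eligible_fraction",
                     "early_deregistration", "acceptable_fraction",
                     "trial_fraction", "rescue_route_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for group in ("child", "adult"):
            init = np.asarray(self.initial_step_distribution[group], float)
            if init.shape != (6,) or abs(init.sum() - 1.0) > 1e-9 or (init < 0).any():
                raise ConfigError(
                    f"initial_step_distribution[{group!r}] must be a length-6 "
                    "probability vector")
            kern = np.asarray(self.transition_kernel[group], float)
            if kern.shape != (6, 6) or (kern < 0).any():
                raise ConfigError(
                    f"transition_kernel[{group!r}] must be a 6x6 non-negative matrix")
            bad = np.abs(kern.sum(axis=1) - 1.0) > 1e-9
            if bad.any():
                raise ConfigError(
                    f"transition_kernel[{group!r}] rows {np.where(bad)[0].tolist()} "
                    "do not sum to 1")
            for prev in self.event_prevalences[group].values():
                if not (0.0 <= prev <= 1.0):
                    raise ConfigError("event prevalences must be in [0, 1]")
        if self.gap_jitter_days < 0 or self.script_duration_days <= 0:
            raise ConfigError("gap_jitter_days >= 0 and script_duration_days > 0")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for k in ("study_start", "study_end", "reference_date"):
            d[k] = d[k].isoformat()
        return d

    def replace(self, **changes) -> "GenerationConfig":
        return dataclasses.replace(self, **changes)
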