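"""CPRD-GOLD-like raw tables: container, schema validation, CSV round trip.

Four flat tables — patients, diagnoses, prescriptions, clinical_events —
with ISO-8601 dates.  Reading validates the schema eagerly and raises
:class:`SchemaError` naming the file, column or row at fault; writing is
atomic per file (write to a temp name, then rename).
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

TABLE_FILES = {
    "patients": "patients.csv",
    "diagnoses": "diagnoses.csv",
    "prescriptions": "prescriptions.csv",
    "clinical_events": "clinical_events.csv",
}

#: column name -> kind ('date', 'str', 'num')
SCHEMAS: dict[str, dict[str, str]] = {
    "patients": {
        "patient_id": "str", "birth_date": "date", "gender": "str",
        "registration_start": "date", "registration_end": "date",
        "acceptable_flag": "num", "trial_flag": "num", "uts_date": "date",
    },
    "diagnoses": {
        "patient_id": "str", "diagnosis_date": "date", "code": "str",
    },
    "prescriptions": {
        "patient_id": "str", "issue_date": "date", "drug_category": "str",
        "substance": "str", "duration_days": "num",
        "ics_daily_dose_ug": "num", "ocs_strength_mg": "num",
        "pack_size": "num",
    },
    "clinical_events": {
        "patient_id": "str", "event_date": "date", "code": "str",
        "event_category": "str", "value": "str",
    },
}

#: columns that may contain missing values
NULLABLE = {
    ("prescriptions", "duration_days"), ("prescriptions", "ics_daily_dose_ug"),
    ("prescriptions", "ocs_strength_mg"), ("prescriptions", "pack_size"),
    ("clinical_events", "value"), ("clinical_events", "code"),
}


class SchemaError(ValueError):
    """A raw table violates its schema."""


@dataclass
class RawTables:
    """The four validated raw tables plus (optionally) the ground-truth plan."""

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    clinical_events: pd.DataFrame
    trajectory_truth: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for name in TABLE_FILES:
            setattr(self, name, validate_table(getattr(self, name), name))
        self._check_referential_integrity()

    def _check_referential_integrity(self) -> None:
        known = set(self.patients["patient_id"])
        for name in ("diagnoses", "prescriptions", "clinical_events"):
            tab = getattr(self, name)
            if len(tab) == 0:
                continue
            missing = set(tab["patient_id"]) - known
            if missing:
                some = sorted(missing)[:5]
                raise SchemaError(
                    f"{name}: unresolvable patient_id values {some} "
                    f"({len(missing)} total)")

    def tables(self):
        return {name: getattr(self, name) for name in TABLE_FILES}


def validate_table(df: pd.DataFrame, name: str, source: str = "") -> pd.DataFrame:
    """Coerce one raw table to its schema, raising on violations."""
    schema = SCHEMAS[name]
    where = f" in {source}" if source else ""
    missing_cols = [c for c in schema if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{name}{where}: missing column(s) {missing_cols}")
    df = df[list(schema)].copy()
    for col, kind in schema.items():
        if kind == "date":
            parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
            bad = parsed.isna() & df[col].notna()
            if bad.any():
                row = int(bad.idxmax())
                raise SchemaError(
                    f"{name}{where}: malformed date in column {col!r} at row "
                    f"{row}: {df[col].iloc[row]!r}")
            if parsed.isna().any():
                row = int(parsed.isna().idxmax())
                raise SchemaError(
                    f"{name}{where}: missing date in column {col!r} at row {row}")
            df[col] = parsed
        elif kind == "num":
            df[col] = pd.to_numeric(df[col], errors="coerce")
            if (name, col) not in NULLABLE and df[col].isna().any():
                row = int(df[col].isna().idxmax())
                raise SchemaError(
                    f"{name}{where}: non-numeric or missing value in column "
                    f"{col!r} at row {row}")
        else:
            df[col] = df[col].astype("string").replace("", pd.NA)
            if (name, col) not in NULLABLE and df[col].isna().any():
                row = int(df[col].isna().idxmax())
                raise SchemaError(
                    f"{name}{where}: missing value in column {col!r} at row {row}")
    return df.reset_index(drop=True)


def atomic_write_csv(df: pd.DataFrame, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            out.to_csv(fh, index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_raw_tables(tables: RawTables, destination) -> dict[str, Path]:
    """Write the four tables (and the truth table, if present) as CSV."""
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, fname in TABLE_FILES.items():
        path = dest / fname
        atomic_write_csv(getattr(tables, name), path)
        written[name] = path
    if tables.trajectory_truth is not None:
        path = dest / "trajectory_truth.csv"
        atomic_write_csv(tables.trajectory_truth, path)
        written["trajectory_truth"] = path
    return written


def read_raw_tables(source) -> RawTables:
    """Read and validate the four tables from a directory of CSV files."""
    src = Path(source)
    frames = {}
    for name, fname in TABLE_FILES.items():
        path = src / fname
        if not path.exists():
            raise SchemaError(f"missing input file: {path}")
        raw = pd.read_csv(path, dtype=str)
        frames[name] = validate_table(raw, name, source=str(path))
    truth_path = src / "trajectory_truth.csv"
    truth = None
    if truth_path.exists():
        truth = pd.read_csv(truth_path, dtype={"patient_id": str})
        truth["time_point"] = pd.to_datetime(truth["time_point"])
    return RawTables(**frames, trajectory_truth=truth)
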