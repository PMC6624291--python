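"""Shared fixtures: hand-built raw tables and reusable simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import stepladder as sl


def patient_row(pid="p1", birth="1980-06-15", reg_start="2005-01-01",
                reg_end="2017-06-01", acceptable=1, trial=0,
                uts="2006-09-01") -> dict:
    return {"patient_id": pid, "birth_date": birth, "gender": "F",
            "registration_start": reg_start, "registration_end": reg_end,
            "acceptable_flag": acceptable, "trial_flag": trial,
            "uts_date": uts}


def rx_row(pid="p1", date="2015-01-01", cat="ICS", dur=30, dose=np.nan,
           strength=np.nan, pack=np.nan) -> dict:
    return {"patient_id": pid, "issue_date": date, "drug_category": cat,
            "substance": "x", "duration_days": dur,
            "ics_daily_dose_ug": dose, "ocs_strength_mg": strength,
            "pack_size": pack}


def event_row(pid="p1", date="2015-09-15", code="66YJ.", category="review",
              value="") -> dict:
    return {"patient_id": pid, "event_date": date, "code": code,
            "event_category": category, "value": value}


def toy_raw(patients, diagnoses=None, prescriptions=None, events=None
            ) -> sl.RawTables:
    """Validated RawTables from lists of row dicts.

    Every patient gets a default asthma diagnosis at registration start
    unless explicit diagnosis rows are supplied.
    """
    pats = pd.DataFrame(patients)
    if diagnoses is None:
        diagnoses = [{"patient_id": p["patient_id"],
                      "diagnosis_date": p["registration_start"],
                      "code": "H33.."} for p in patients]
    diag = pd.DataFrame(diagnoses,
                        columns=["patient_id", "diagnosis_date", "code"])
    rx = pd.DataFrame(prescriptions or [],
                      columns=list(rx_row()))
    ev = pd.DataFrame(events or [], columns=list(event_row()))
    from stepladder.tables import validate_table
    return sl.RawTables(patients=validate_table(pats, "patients"),
                        diagnoses=validate_table(diag, "diagnoses"),
                        prescriptions=validate_table(rx, "prescriptions"),
                        clinical_events=validate_table(ev, "clinical_events"))


@pytest.fixture(scope="session")
def study_config() -> sl.StudyConfig:
    return sl.StudyConfig()


@pytest.fixture(scope="session")
def noise_free_sim():
    """400 synthetic patients with jitter and dropout at zero, plus plan."""
    cfg = sl.GenerationConfig(n_patients=400, seed=5, gap_jitter_days=0,
                              script_dropout=0.0)
    raw, plan = sl.simulate_raw_tables(cfg)
    return cfg, raw, plan


@pytest.fixture(scope="session")
def noise_free_result(noise_free_sim, study_config):
    _, raw, _ = noise_free_sim
    return sl.run_analysis(raw, study_config, seed=5)


@pytest.fixture(scope="session")
def noisy_sim():
    """1,000 synthetic patients under the generator's default noise."""
    cfg = sl.GenerationConfig(n_patients=1000, seed=9)
    raw, plan = sl.simulate_raw_tables(cfg)
    return cfg, raw, plan


@pytest.fixture(scope="session")
def noisy_result(noisy_sim, study_config):
    _, raw, _ = noisy_sim
    return sl.run_analysis(raw, study_config, seed=9)
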