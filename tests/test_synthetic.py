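"""Synthetic cohort generator: determinism, plan invariants, rendering."""

import numpy as np
import pandas as pd
import pytest

import stepladder as sl
from stepladder.config import UNDIAGNOSED
from stepladder.simulate import (EmptyCohortError, generate_patients,
                                 generation_grid, plan_trajectories,
                                 render_prescriptions, simulate_raw_tables)
from stepladder.cohort import completed_age
from stepladder.tables import SchemaError, read_raw_tables, write_raw_tables


def gen(n=100, **kw) -> sl.GenerationConfig:
    kw.setdefault("seed", 1)
    return sl.GenerationConfig(n_patients=n, **kw)


class TestGeneratePatients:
    def test_child_fraction_controls_ages(self):
        cfg = gen(400, child_fraction=0.5)
        internal = generate_patients(cfg, np.random.default_rng(cfg.seed))
        age = completed_age(internal["birth_date"],
                            pd.Timestamp(cfg.reference_date))
        n_child = int(((age >= 5) & (age <= 11)).sum())
        assert abs(n_child - 200) < 60          # binomial spread
        assert ((age >= 5) & (age <= 80)).all()
        assert (internal["age_group"] == "child").sum() == n_child

    def test_zero_child_fraction(self):
        cfg = gen(200, child_fraction=0.0)
        internal = generate_patients(cfg, np.random.default_rng(cfg.seed))
        age = completed_age(internal["birth_date"],
                            pd.Timestamp(cfg.reference_date))
        assert (age >= 12).all()

    def test_zero_patients_is_an_error(self):
        with pytest.raises(EmptyCohortError):
            generate_patients(gen(0), np.random.default_rng(0))

    def test_every_patient_has_one_diagnosis_after_registration(self):
        raw, _ = simulate_raw_tables(gen(150))
        diag = raw.diagnoses.merge(raw.patients, on="patient_id")
        assert len(diag) == 150
        assert (diag["diagnosis_date"] >= diag["registration_start"]).all()

    def test_eligible_fraction_enrolment_guarantee(self):
        cfg = gen(300, eligible_fraction=1.0, early_deregistration=0.0)
        internal = generate_patients(cfg, np.random.default_rng(cfg.seed))
        ref = pd.Timestamp(cfg.reference_date)
        ok = ((internal["registration_start"]
               <= ref - pd.Timedelta(days=365))
              & (internal["registration_end"] >= ref))
        assert ok.all()


class TestDeterminism:
    def test_same_seed_gives_byte_identical_tables(self, tmp_path):
        for run in ("a", "b"):
            raw, _ = simulate_raw_tables(gen(120, seed=42))
            write_raw_tables(raw, tmp_path / run)
        for f in (tmp_path / "a").iterdir():
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_different_seeds_differ(self):
        a, _ = simulate_raw_tables(gen(50, seed=1))
        b, _ = simulate_raw_tables(gen(50, seed=2))
        assert not a.prescriptions.equals(b.prescriptions)


class TestPlanTrajectories:
    def test_identity_kernel_freezes_steps(self):
        ident = {g: np.eye(6).tolist() for g in ("child", "adult")}
        cfg = gen(150, transition_kernel=ident)
        internal = generate_patients(cfg, np.random.default_rng(cfg.seed))
        plan = plan_trajectories(internal, cfg, np.random.default_rng(1))
        diagnosed = plan[plan["planned_step"] >= 0]
        per_patient = diagnosed.groupby("patient_id")["planned_step"].nunique()
        assert (per_patient == 1).all()

    def test_absorbing_kernel_sends_everyone_to_step2(self):
        absorbing = np.zeros((6, 6))
        absorbing[:, 2] = 1.0
        cfg = gen(150, transition_kernel={g: absorbing.tolist()
                                          for g in ("child", "adult")})
        internal = generate_patients(cfg, np.random.default_rng(cfg.seed))
        plan = plan_trajectories(internal, cfg, np.random.default_rng(1))
        later = (plan[plan["planned_step"] >= 0]
                 .groupby("patient_id").apply(
                     lambda g: g.sort_values("t_index")["planned_step"].iloc[1:],
                     include_groups=False))
        assert (later == 2).all()

    def test_undiagnosed_only_before_diagnosis(self):
        cfg = gen(200)
        internal = generate_patients(cfg, np.random.default_rng(cfg.seed))
        plan = plan_trajectories(internal, cfg, np.random.default_rng(1))
        merged = plan.merge(internal[["patient_id", "diagnosis_date"]],
                            on="patient_id")
        undiag = merged[merged["planned_step"] == UNDIAGNOSED]
        diag = merged[merged["planned_step"] >= 0]
        assert (undiag["time_point"] < undiag["diagnosis_date"]).all()
        assert (diag["time_point"] >= diag["diagnosis_date"]).all()

    def test_plan_points_inside_registration(self):
        cfg = gen(200, early_deregistration=0.3)
        internal = generate_patients(cfg, np.random.default_rng(cfg.seed))
        plan = plan_trajectories(internal, cfg, np.random.default_rng(1))
        merged = plan.merge(internal, on="patient_id")
        assert (merged["time_point"] >= merged["registration_start"]).all()
        assert (merged["time_point"] <= merged["registration_end"]).all()

    def test_empirical_transitions_match_kernel(self):
        """With n=4,000 the planned transition frequencies sit within 3
        binomial standard errors of the kernel entries."""
        kern = np.asarray(sl.GenerationConfig().transition_kernel["adult"])
        cfg = gen(4000, child_fraction=0.0, seed=3)
        internal = generate_patients(cfg, np.random.default_rng(cfg.seed))
        plan = plan_trajectories(internal, cfg, np.random.default_rng(3))
        diag = plan[plan["planned_step"] >= 0].sort_values(
            ["patient_id", "t_index"])
        prev = diag.groupby("patient_id")["planned_step"].shift()
        pairs = diag.assign(prev=prev).dropna(subset=["prev"])
        for s in range(6):
            row = pairs[pairs["prev"] == s]
            n = len(row)
            if n < 50:
                continue
            emp = np.bincount(row["planned_step"], minlength=6) / n
            se = np.sqrt(kern[s] * (1 - kern[s]) / n)
            assert (np.abs(emp - kern[s]) <= 3 * se + 1e-12).all()


class TestRenderPrescriptions:
    def grid_plan(self, steps, cfg):
        """Single adult patient planned through the given steps."""
        internal = generate_patients(cfg, np.random.default_rng(cfg.seed))
        internal = internal.iloc[:1].copy()
        grid = generation_grid(cfg)
        return internal, pd.DataFrame({
            "patient_id": internal["patient_id"].iloc[0],
            "age_group": internal["age_group"].iloc[0],
            "t_index": range(len(steps)),
            "time_point": pd.to_datetime(grid[:len(steps)]),
            "planned_step": steps})

    def cfg(self):
        return gen(1, child_fraction=0.0, gap_jitter_days=0,
                   script_dropout=0.0, eligible_fraction=1.0,
                   early_deregistration=0.0)

    def test_step0_plan_emits_no_scripts(self):
        cfg = self.cfg()
        internal, plan = self.grid_plan([0] * 18, cfg)
        rx = render_prescriptions(plan, internal, cfg, np.random.default_rng(0))
        assert len(rx) == 0

    def test_step2_plan_emits_only_ics_and_reliever(self):
        cfg = self.cfg()
        internal, plan = self.grid_plan([2] * 18, cfg)
        rx = render_prescriptions(plan, internal, cfg, np.random.default_rng(0))
        assert set(rx["drug_category"]) <= {"ICS", "SABA"}
        ics = rx[rx["drug_category"] == "ICS"].sort_values("issue_date")
        gaps = ics["issue_date"].diff().dt.days.dropna()
        covered_gap = gaps - cfg.script_duration_days
        assert (covered_gap <= 90).all()

    def test_step5_rescue_route_scripts_match_rescue_definition(self):
        cfg = self.cfg().replace(rescue_route_fraction=1.0)
        internal, plan = self.grid_plan([5], cfg)
        rx = render_prescriptions(plan, internal, cfg, np.random.default_rng(0))
        ocs = rx[rx["drug_category"] == "OCS"]
        assert len(ocs) == 5
        assert (ocs["duration_days"] < 14).all()
        assert (ocs["ocs_strength_mg"] >= 5).all()
        span = (ocs["issue_date"].max() - ocs["issue_date"].min()).days
        assert span <= 183


class TestRoundTrip:
    def test_write_then_read_equal(self, tmp_path):
        raw, _ = simulate_raw_tables(gen(60))
        write_raw_tables(raw, tmp_path)
        back = read_raw_tables(tmp_path)
        for name, table in raw.tables().items():
            got = getattr(back, name)
            pd.testing.assert_frame_equal(
                table.reset_index(drop=True), got, check_dtype=False)

    def test_missing_column_is_schema_error(self, tmp_path):
        raw, _ = simulate_raw_tables(gen(10))
        write_raw_tables(raw, tmp_path)
        rx = pd.read_csv(tmp_path / "prescriptions.csv")
        rx.drop(columns=["issue_date"]).to_csv(
            tmp_path / "prescriptions.csv", index=False)
        with pytest.raises(SchemaError, match="issue_date"):
            read_raw_tables(tmp_path)

    def test_unresolvable_patient_is_schema_error(self, tmp_path):
        raw, _ = simulate_raw_tables(gen(10))
        write_raw_tables(raw, tmp_path)
        rx = pd.read_csv(tmp_path / "prescriptions.csv")
        rx.loc[0, "patient_id"] = "ghost"
        rx.to_csv(tmp_path / "prescriptions.csv", index=False)
        with pytest.raises(SchemaError, match="ghost"):
            read_raw_tables(tmp_path)

    def test_empty_prescriptions_table_is_valid(self, tmp_path):
        raw, _ = simulate_raw_tables(gen(10))
        write_raw_tables(raw, tmp_path)
        rx = pd.read_csv(tmp_path / "prescriptions.csv")
        rx.iloc[0:0].to_csv(tmp_path / "prescriptions.csv", index=False)
        back = read_raw_tables(tmp_path)
        assert len(back.prescriptions) == 0

    def test_referential_integrity_of_generated_tables(self):
        raw, _ = simulate_raw_tables(gen(80))
        pids = set(raw.patients["patient_id"])
        for tab in (raw.diagnoses, raw.prescriptions, raw.clinical_events):
            assert set(tab["patient_id"]) <= pids
        ev = raw.clinical_events.merge(raw.patients, on="patient_id")
        assert (ev["event_date"] >= ev["registration_start"]).all()
        assert (ev["event_date"] <= ev["registration_end"]).all()
        rx = raw.prescriptions.merge(raw.patients, on="patient_id")
        assert (rx["issue_date"] >= rx["registration_start"]).all()
        assert (rx["issue_date"] <= rx["registration_end"]).all()
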