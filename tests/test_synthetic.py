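"""Synthetic cohort generator: determinism, structure, ground truth."""

import numpy as np
import pandas as pd
import pytest

import dietchange as dc
from dietchange import instrument as ins
from dietchange.synthetic import ConfigurationError


class TestConfigValidation:
    def test_nonpositive_n_rejected(self):
        with pytest.raises(ConfigurationError):
            dc.SimulationConfig(n_subjects=0)

    def test_bad_probabilities_rejected(self):
        with pytest.raises(ConfigurationError):
            dc.SimulationConfig(age_group_probs={40: 0.6, 50: 0.6})
        with pytest.raises(ConfigurationError):
            dc.SimulationConfig(sex_ratio_f=1.2)

    def test_bad_violation_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            dc.SimulationConfig(qc_violation_rates={"ffq_missing": 1.5})
        with pytest.raises(ConfigurationError):
            dc.SimulationConfig(qc_violation_rates={"teleportation": 0.1})


class TestDeterminism:
    def test_identical_seeds_byte_identical(self, tmp_path):
        cfg = dc.SimulationConfig(n_subjects=100, seed=7)
        a = dc.generate_cohort(cfg)
        b = dc.generate_cohort(cfg)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        dc.synthetic.write_cohort(a, p1, cfg)
        dc.synthetic.write_cohort(b, p2, cfg)
        assert p1.read_bytes() == p2.read_bytes()
        assert (p1.parent / "a.tsv.meta.json").read_bytes() == \
            (p2.parent / "b.tsv.meta.json").read_bytes()

    def test_different_seeds_differ(self):
        a = dc.generate_cohort(dc.SimulationConfig(n_subjects=50, seed=1))
        b = dc.generate_cohort(dc.SimulationConfig(n_subjects=50, seed=2))
        assert not a.equals(b)

    def test_reference_tables_deterministic(self):
        t1 = dc.generate_food_composition_table(4).densities
        t2 = dc.generate_food_composition_table(4).densities
        assert t1.equals(t2)
        d1 = dc.generate_dii_reference(4).table
        d2 = dc.generate_dii_reference(4).table
        assert d1.equals(d2)


class TestCohortStructure:
    def test_two_visits_per_subject_with_valid_interval(self, cohort):
        counts = cohort.groupby("subject_id")["visit"].nunique()
        assert (counts == 2).all()
        wide = cohort.pivot(index="subject_id", columns="visit", values="exam_date")
        yrs = (pd.to_datetime(wide[2]) - pd.to_datetime(wide[1])).dt.days / 365.25
        assert yrs.between(9, 11).all()

    def test_device_flag_matches_exam_date(self, cohort):
        dates = pd.to_datetime(cohort["exam_date"])
        expected = np.where(dates < pd.Timestamp("2009-09-09"),
                            "Reflotron", "enzymatic")
        assert (cohort["device"] == expected).all()

    def test_codes_on_nine_level_scale(self, cohort):
        codes = cohort[list(ins.FFQ_COLUMNS)]
        assert codes.min().min() >= 0 and codes.max().max() <= 8

    def test_between_visit_code_correlation(self):
        cfg = dc.SimulationConfig(n_subjects=1500, seed=5)
        coh = dc.generate_cohort(cfg)
        v1 = coh[coh.visit == 1].set_index("subject_id")
        v2 = coh[coh.visit == 2].set_index("subject_id")
        rs = [v1[c].corr(v2.loc[v1.index, c]) for c in ins.FFQ_COLUMNS[:20]]
        # latent rho 0.5 discretised: observed code correlation nearby
        assert 0.25 < np.mean(rs) < 0.6


class TestFoodCompositionTable:
    def test_atwater_energy_identity(self, fct):
        d = fct.densities
        atwater = 4 * d["protein_g"] + 4 * d["carb_g"] + 9 * d["fat_g"]
        assert np.allclose(d["energy_kcal"], atwater)

    def test_pure_sugar_arithmetic(self):
        # 100 g carbohydrate, no fat or protein -> 400 kcal per 100 g
        assert 4 * 0 + 4 * 100 + 9 * 0 == 400

    def test_validation_rejects_sucrose_above_carb(self, fct):
        bad = fct.densities.copy()
        bad.loc["milk", "sucrose_g"] = bad.loc["milk", "carb_g"] + 1
        with pytest.raises(ValueError, match="sucrose"):
            dc.FoodCompositionTable(bad)

    def test_roundtrip_tsv(self, fct, tmp_path):
        p = tmp_path / "fct.tsv"
        fct.to_tsv(p)
        again = dc.FoodCompositionTable.from_tsv(p)
        assert np.allclose(again.densities, fct.densities)


class TestDiiReference:
    def test_thirty_parameters_with_merged_caffeine_and_tea(self, dii_ref):
        params = dii_ref.parameters
        assert len(params) == 30
        assert params.count("caffeine") == 1
        assert params.count("tea") == 1

    def test_positive_means_and_sds(self, dii_ref):
        assert (dii_ref.table["global_mean"] > 0).all()
        assert (dii_ref.table["global_sd"] > 0).all()

    def test_signed_effect_weights(self, dii_ref):
        w = dii_ref.table["effect_weight"]
        assert (w != 0).all()
        assert w.loc["fatty_fish"] < 0        # anti-inflammatory
        assert w.loc["sausage"] > 0           # pro-inflammatory


class TestViolationInjection:
    def test_zero_rates_leave_cohort_unchanged(self, cohort):
        cfg = dc.SimulationConfig(n_subjects=300, seed=11)
        out, ledger = dc.inject_qc_violations(cohort, cfg)
        assert out.equals(cohort)
        assert all(len(v) == 0 for v in ledger.values())

    def test_full_missingness_rate_blanks_every_subject(self):
        cfg = dc.SimulationConfig(n_subjects=60, seed=8,
                                  qc_violation_rates={"ffq_missing": 1.0})
        coh = dc.generate_cohort(cfg)
        out, ledger = dc.inject_qc_violations(coh, cfg)
        assert len(ledger["ffq_missing"]) == 60
        blanks = out[list(ins.FFQ_COLUMNS)].isna().sum(axis=1)
        per_subject = blanks.groupby(out["subject_id"]).max()
        assert (per_subject / ins.N_ITEMS > 0.10).all()

    def test_ledger_reproducible_under_same_seed(self, cohort):
        cfg = dc.SimulationConfig(
            n_subjects=300, seed=11,
            qc_violation_rates={"ffq_missing": 0.05, "interval": 0.03})
        _, l1 = dc.inject_qc_violations(cohort, cfg)
        _, l2 = dc.inject_qc_violations(cohort, cfg)
        assert l1 == l2


class TestGroundTruth:
    def test_null_effects_give_null_betas(self, fct, dii_ref):
        cfg = dc.SimulationConfig(n_subjects=2000, seed=13)
        coh = dc.generate_cohort(cfg, dc.TrueEffects())
        frame = dc.build_change_frame(dc.calibrate_cohort(
            dc.score_cohort(dc.process_records(coh, fct), dii_ref)))
        for sex in ("F", "M"):
            fit = dc.fit_outcome_model(frame[frame.sex == sex],
                                       dc.ModelSpec("bmi"))
            assert (fit.betas.abs() < 3.9 * fit.ses).all()

    def test_injected_effect_recovered_downstream(self, fct, dii_ref):
        # 0.2 units of serum cholesterol per 10% trans-fat change = 0.02 per %
        eff = dc.TrueEffects(betas={("tfa_epct", "chol"): 0.02})
        cfg = dc.SimulationConfig(n_subjects=5000, seed=1)
        coh = dc.generate_cohort(cfg, eff)
        frame = dc.build_change_frame(dc.calibrate_cohort(
            dc.score_cohort(dc.process_records(coh, fct), dii_ref)))
        spec = dc.ModelSpec("chol", exposures=dc.analysis.JOINT_EXPOSURES_TFA)
        for sex in ("F", "M"):
            fit = dc.fit_outcome_model(frame[frame.sex == sex], spec)
            b, se = fit.betas["tfa_epct"], fit.ses["tfa_epct"]
            assert abs(b - 0.02) < 3 * se
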