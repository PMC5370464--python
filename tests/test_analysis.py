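"""Percent-change exposures, adjusted means, collinearity and outcome models."""

import numpy as np
import pandas as pd
import pytest

import dietchange as dc
from dietchange.analysis import (
    JOINT_EXPOSURES, AnalysisError, ModelSpec, sensitivity_models)
from helpers import (
    build_design_like_package, normal_equations, simulate_change_frame)


class TestPercentChange:
    def test_basic_arithmetic(self):
        assert dc.percent_change(50, 55) == pytest.approx(10.0)
        assert dc.percent_change(1.0, 0.5) == pytest.approx(-50.0)

    def test_zero_baseline_flagged(self):
        out = dc.percent_change(np.array([0.0, 2.0]), np.array([1.0, 3.0]))
        assert np.isnan(out[0]) and out[1] == pytest.approx(50.0)


class TestModelSpec:
    def test_cholesterol_and_transfat_cannot_cooccur(self):
        with pytest.raises(AnalysisError, match="separate"):
            ModelSpec("bmi", exposures=("chol_epct", "tfa_epct"))

    def test_unknown_outcome_rejected(self):
        with pytest.raises(AnalysisError):
            ModelSpec("weight")


class TestFitOutcomeModel:
    def test_betas_and_ses_match_normal_equations(self):
        rng = np.random.default_rng(30)
        frame = simulate_change_frame(rng, 80)
        spec = ModelSpec("bmi", exposures=("pufa_epct", "sucrose_epct"))
        fit = dc.fit_outcome_model(frame, spec)
        numeric = ["pct_pufa_epct", "pct_sucrose_epct", "bmi1",
                   "exam_year1", "age1"]
        X = build_design_like_package(frame, numeric,
                                      ["education", "smoking", "activity"])
        beta, se = normal_equations(X, frame["bmi2"])
        named = dict(zip(X.columns, beta))
        named_se = dict(zip(X.columns, se))
        assert fit.betas["pufa_epct"] == pytest.approx(
            named["pct_pufa_epct"], abs=1e-10)
        assert fit.betas["sucrose_epct"] == pytest.approx(
            named["pct_sucrose_epct"], abs=1e-10)
        assert fit.ses["pufa_epct"] == pytest.approx(
            named_se["pct_pufa_epct"], abs=1e-10)

    def test_zero_variance_exposures_error_names_terms(self):
        rng = np.random.default_rng(31)
        frame = simulate_change_frame(rng, 60)
        for exp in JOINT_EXPOSURES:
            frame[f"pct_{exp}"] = 1.0
        with pytest.raises(AnalysisError, match="rank deficient"):
            dc.fit_outcome_model(frame, ModelSpec("bmi"))

    def test_listwise_deletion_counted(self):
        rng = np.random.default_rng(32)
        frame = simulate_change_frame(rng, 100)
        frame.loc[:9, "pct_pufa_epct"] = np.nan
        fit = dc.fit_outcome_model(frame, ModelSpec("bmi"))
        assert fit.n_dropped == 10
        assert fit.n_used == 90

    def test_r2_decomposition_ordering_and_construction(self):
        rng = np.random.default_rng(33)
        # outcome driven purely by tracking: diet R^2 near zero
        frame = simulate_change_frame(rng, 2000, betas={})
        r2_full, r2_diet = dc.r2_decomposition(frame, ModelSpec("bmi"))
        assert 0 <= r2_diet <= r2_full <= 100
        assert r2_diet < 2.0 and r2_full > 60.0
        # outcome driven purely by diet: the two R^2 approach each other
        frame2 = simulate_change_frame(
            rng, 2000, betas={"pufa_epct": 0.5}, tracking=0.0, resid_sd=0.5)
        f2, d2 = dc.r2_decomposition(frame2, ModelSpec("bmi"))
        assert d2 > 0.9 * f2


class TestCollinearityScreen:
    def test_independent_exposures_single_model(self):
        rng = np.random.default_rng(34)
        frame = simulate_change_frame(rng, 5000)
        report = dc.collinearity_screen(frame, JOINT_EXPOSURES)
        assert not report.needs_split()
        assert report.model_variants == [tuple(JOINT_EXPOSURES)]

    def test_constructed_r06_pair_splits(self):
        rng = np.random.default_rng(35)
        frame = simulate_change_frame(rng, 4000)
        z = frame["pct_chol_epct"].to_numpy()
        frame["pct_tfa_epct"] = 0.6 * z + np.sqrt(1 - 0.36) * rng.normal(
            0, z.std(), size=len(frame))
        report = dc.collinearity_screen(
            frame, ("chol_epct", "tfa_epct", "sucrose_epct"))
        pairs = [(a, b) for a, b, _ in report.flagged_pairs]
        assert ("chol_epct", "tfa_epct") in pairs
        assert ("chol_epct", "sucrose_epct") in [
            tuple(v) for v in report.model_variants]
        assert ("tfa_epct", "sucrose_epct") in [
            tuple(v) for v in report.model_variants]
        r = report.correlations.loc["chol_epct", "tfa_epct"]
        assert 0.5 < r < 0.7

    def test_self_correlation_forces_split(self):
        rng = np.random.default_rng(36)
        frame = simulate_change_frame(rng, 500)
        frame["pct_hds"] = frame["pct_chol_epct"]
        report = dc.collinearity_screen(frame, ("chol_epct", "hds"))
        assert report.needs_split()
        assert report.correlations.loc["chol_epct", "hds"] == pytest.approx(1.0)

    def test_constant_exposure_reported(self):
        rng = np.random.default_rng(37)
        frame = simulate_change_frame(rng, 200)
        frame["pct_hds"] = 0.0
        report = dc.collinearity_screen(frame, ("chol_epct", "hds"))
        assert "hds" in report.constant_exposures


class TestAdjustedStratumMeans:
    def test_balanced_covariates_reduce_to_raw_means(self):
        # identical covariate values in both strata: adjustment is a no-op
        cov = np.tile(np.linspace(-1, 1, 50), 2)
        stratum = np.repeat(["a", "b"], 50)
        rng = np.random.default_rng(38)
        y = 1.0 + 2.0 * (stratum == "b") + 0.7 * cov + rng.normal(0, 0.1, 100)
        df = pd.DataFrame({"y": y, "g": stratum, "cov": cov})
        adj = dc.adjusted_stratum_means(df, "y", ["g"], numeric_covariates=["cov"])
        raw = df.groupby("g")["y"].mean()
        assert adj.loc["a", "adjusted_mean"] == pytest.approx(raw["a"], abs=1e-9)
        assert adj.loc["b", "adjusted_mean"] == pytest.approx(raw["b"], abs=1e-9)

    def test_confounded_shift_recovered_within_ci(self):
        rng = np.random.default_rng(39)
        n = 2000
        stratum = rng.choice(["a", "b"], size=n)
        # confounder piles up in stratum b and inflates its raw mean
        cov = rng.normal(0, 1, n) + 1.5 * (stratum == "b")
        true_shift = 2.0
        y = true_shift * (stratum == "b") + 1.0 * cov + rng.normal(0, 1, n)
        df = pd.DataFrame({"y": y, "g": stratum, "cov": cov})
        raw_diff = df[df.g == "b"]["y"].mean() - df[df.g == "a"]["y"].mean()
        assert raw_diff > true_shift + 0.5      # confounding visible
        adj = dc.adjusted_stratum_means(df, "y", ["g"], numeric_covariates=["cov"])
        adj_diff = adj.loc["b", "adjusted_mean"] - adj.loc["a", "adjusted_mean"]
        halfwidth = 2 * np.hypot(adj.loc["a", "se"], adj.loc["b", "se"])
        assert abs(adj_diff - true_shift) < halfwidth

    def test_single_stratum_equals_prediction_average(self):
        rng = np.random.default_rng(40)
        df = pd.DataFrame({"y": rng.normal(5, 1, 300),
                           "g": "only", "cov": rng.normal(0, 1, 300)})
        adj = dc.adjusted_stratum_means(df, "y", ["g"], numeric_covariates=["cov"])
        # with the stratum fixed, the marginal prediction average is ybar
        assert adj.loc["only", "adjusted_mean"] == pytest.approx(
            df["y"].mean(), abs=1e-9)


class TestSensitivity:
    def test_change_outcome_preserves_beta_signs(self):
        rng = np.random.default_rng(41)
        frame = simulate_change_frame(
            rng, 4000, betas={"chol_epct": 0.05, "wholegrain_per2000": -0.05})
        spec = ModelSpec("bmi")
        main = dc.fit_outcome_model(frame, spec)
        for mode in ("change-outcome-absolute", "change-outcome-percent"):
            sens = sensitivity_models(frame, spec, mode)
            for exp in ("chol_epct", "wholegrain_per2000"):
                assert np.sign(sens.fit.betas[exp]) == np.sign(main.betas[exp])

    def test_independent_baseline_bmi_leaves_betas(self):
        rng = np.random.default_rng(42)
        frame = simulate_change_frame(rng, 4000, betas={"chol_epct": 0.05},
                                      outcome="sbp", tracking=0.5, resid_sd=10)
        frame["bmi1"] = rng.normal(25, 4, len(frame))  # independent of everything
        spec = ModelSpec("sbp")
        sens = sensitivity_models(frame, spec, "adjust-baseline-bmi")
        assert abs(sens.delta_beta["chol_epct"]) < 2 * sens.fit.ses["chol_epct"]

    def test_mediating_bmi_change_attenuates_beta(self):
        rng = np.random.default_rng(43)
        n = 4000
        frame = simulate_change_frame(rng, n, betas={}, outcome="sbp",
                                      tracking=0.5, resid_sd=5)
        # exposure -> BMI change -> SBP: the whole effect flows through BMI
        bmi_change = 0.1 * frame["pct_chol_epct"] + rng.normal(0, 1, n)
        frame["bmi1"] = rng.normal(25, 4, n)
        frame["bmi2"] = frame["bmi1"] + bmi_change
        frame["sbp_mmhg2"] = frame["sbp_mmhg2"] + 2.0 * bmi_change
        spec = ModelSpec("sbp")
        main = dc.fit_outcome_model(frame, spec)
        sens = sensitivity_models(frame, spec, "adjust-bmi-change")
        assert abs(sens.fit.betas["chol_epct"]) < 0.5 * abs(main.betas["chol_epct"])

    def test_unknown_mode_rejected(self):
        rng = np.random.default_rng(44)
        frame = simulate_change_frame(rng, 100)
        with pytest.raises(AnalysisError):
            sensitivity_models(frame, ModelSpec("bmi"), "leave-one-out")
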