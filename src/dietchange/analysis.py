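"""Percent-change exposure models for cardio-metabolic outcomes.

The core analysis regresses a cardio-metabolic risk factor at the second
visit (BMI, serum cholesterol, triglycerides or systolic blood pressure) on
ten-year percent changes in dietary exposures — whole grain (g/2000 kcal),
PUFA, cholesterol, trans-fat and sucrose (all E%), or the Healthy Diet Score
and Dietary Inflammatory Index in separate models — adjusted for the baseline
value of the risk factor, year of study participation, age, education,
smoking status and physical activity at the first visit.  Sexes are always
modelled separately.  Because percent changes in dietary cholesterol and
trans-fatty acids are strongly correlated, a collinearity screen splits any
exposure pair with |r| above a threshold into separate model variants.
Model R^2 is reported both for the fully adjusted model and for a model
containing only the dietary exposure terms, to quantify the share of outcome
variation the diet changes themselves explain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg

from . import qc

logger = logging.getLogger(__name__)

#: canonical joint-model exposures; cholesterol and trans fat never co-occur
JOINT_EXPOSURES = ("wholegrain_per2000", "pufa_epct", "chol_epct", "sucrose_epct")
JOINT_EXPOSURES_TFA = ("wholegrain_per2000", "pufa_epct", "tfa_epct", "sucrose_epct")
OUTCOME_COLUMNS = {"bmi": "bmi", "chol": "chol_mmol_l",
                   "trig": "trig_mmol_l", "sbp": "sbp_mmhg"}
CATEGORICAL_COVARIATES = ("education", "smoking", "activity")


class AnalysisError(ValueError):
    pass


def percent_change(x1, x2):
    """100 * (x2 - x1) / x1; NaN where the baseline is zero (flagged, not dropped)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (x2 - x1) / x1
    out = np.where(np.isclose(x1, 0.0), np.nan, out)
    if out.ndim == 0:
        return float(out)
    return out


def build_change_frame(long_df: pd.DataFrame,
                       exposures=("wholegrain_per2000", "pufa_epct", "chol_epct",
                                  "tfa_epct", "sucrose_epct", "hds", "dii")
                       ) -> pd.DataFrame:
    """Reshape a processed, scored, calibrated long cohort table to one row
    per subject with visit-1/2 outcomes, percent-change exposures and
    baseline covariates."""
    v1 = long_df[long_df["visit"] == 1].set_index("subject_id")
    v2 = long_df[long_df["visit"] == 2].set_index("subject_id")
    common = v1.index.intersection(v2.index)
    v1, v2 = v1.loc[common], v2.loc[common]
    out = pd.DataFrame(index=common)
    out["sex"] = v1["sex"]
    out["age_group"] = v1["age_group"]
    out["age1"] = v1["age"]
    out["exam_year1"] = v1["exam_year"].astype(float)
    for c in CATEGORICAL_COVARIATES:
        out[c] = v1[c]
    for visit, v in ((1, v1), (2, v2)):
        out[f"bmi{visit}"] = qc.compute_bmi(v["weight_kg"], v["height_cm"])
        out[f"chol_mmol_l{visit}"] = v["chol_mmol_l"]
        out[f"trig_mmol_l{visit}"] = v["trig_mmol_l"]
        out[f"sbp_mmhg{visit}"] = v["sbp_mmhg"]
    for exp in exposures:
        out[f"pct_{exp}"] = percent_change(v1[exp], v2[exp])
    return out.reset_index()


@dataclass
class ModelSpec:
    """One outcome-model specification (fitted within one sex)."""

    outcome: str                                   # bmi | chol | trig | sbp
    exposures: tuple[str, ...] = JOINT_EXPOSURES
    covariates: tuple[str, ...] = ("baseline", "exam_year1", "age1",
                                   "education", "smoking", "activity")
    alpha: float = 0.05

    def __post_init__(self):
        if self.outcome not in OUTCOME_COLUMNS:
            raise AnalysisError(f"unknown outcome {self.outcome!r}")
        if {"chol_epct", "tfa_epct"} <= set(self.exposures):
            raise AnalysisError(
                "cholesterol and trans-fat percent changes are collinear and "
                "must be placed in separate model variants")


@dataclass
class FitResult:
    outcome: str
    exposures: tuple[str, ...]
    betas: pd.Series
    ses: pd.Series
    pvalues: pd.Series
    r2_full: float          # percent
    r2_diet_only: float     # percent
    n_used: int
    n_dropped: int
    params: pd.Series = field(repr=False, default=None)
    bse: pd.Series = field(repr=False, default=None)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": self.betas, "se": self.ses, "p": self.pvalues})


def _build_design(df: pd.DataFrame, numeric: list[str], categorical: list[str],
                  levels: dict | None = None):
    """Design matrix with a constant, numeric columns and reference-coded
    indicators (reference = most frequent level).  ``levels`` fixes the level
    layout so counterfactual frames reproduce identical columns."""
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    for col in numeric:
        X[col] = df[col].astype(float)
    levels = levels or {}
    out_levels = {}
    for col in categorical:
        if col in levels:
            ref, others = levels[col]
        else:
            counts = df[col].value_counts()
            ref = counts.index[0]
            others = [lv for lv in sorted(df[col].dropna().unique()) if lv != ref]
        out_levels[col] = (ref, others)
        for lv in others:
            X[f"{col}[{lv}]"] = (df[col] == lv).astype(float)
    return X, out_levels


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, r, piv = linalg.qr(arr, mode="economic", pivoting=True)
        aliased = [X.columns[j] for j in piv[rank:]]
        raise AnalysisError(f"design is rank deficient; aliased terms: {aliased}")


def fit_outcome_model(frame: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """OLS of the visit-2 outcome on percent-change exposures and covariates.

    ``frame`` is a per-subject change frame for a single sex.  Complete cases
    only (listwise deletion on every used column, with the dropped count
    logged and reported).  The diet-only R^2 comes from a refit on the same
    rows using just the exposure terms and an intercept.
    """
    ocol = OUTCOME_COLUMNS[spec.outcome]
    ycol = f"{ocol}2"
    exp_cols = [f"pct_{e}" for e in spec.exposures]
    numeric = list(exp_cols)
    categorical = []
    for cov in spec.covariates:
        if cov == "baseline":
            numeric.append(f"{ocol}1")
        elif cov in CATEGORICAL_COVARIATES:
            categorical.append(cov)
        else:
            numeric.append(cov)
    used = [ycol] + numeric + categorical
    sub = frame[used].dropna()
    n_dropped = len(frame) - len(sub)
    if n_dropped:
        logger.info("listwise deletion dropped %d of %d rows", n_dropped, len(frame))
    if len(sub) <= len(numeric) + 3:
        raise AnalysisError("too few complete cases to fit the model")

    X, _ = _build_design(sub, numeric, categorical)
    _check_rank(X)
    res = sm.OLS(sub[ycol].to_numpy(dtype=float), X).fit()
    diet = X[["const"] + exp_cols]
    res_diet = sm.OLS(sub[ycol].to_numpy(dtype=float), diet).fit()

    betas = res.params[exp_cols]
    betas.index = list(spec.exposures)
    ses = res.bse[exp_cols]
    ses.index = list(spec.exposures)
    pvals = res.pvalues[exp_cols]
    pvals.index = list(spec.exposures)
    return FitResult(
        outcome=spec.outcome, exposures=spec.exposures,
        betas=betas, ses=ses, pvalues=pvals,
        r2_full=100.0 * float(res.rsquared),
        r2_diet_only=100.0 * float(res_diet.rsquared),
        n_used=int(res.nobs), n_dropped=n_dropped,
        params=res.params, bse=res.bse,
    )


def r2_decomposition(frame: pd.DataFrame, spec: ModelSpec) -> tuple[float, float]:
    """(R^2 full, R^2 diet-only), both in percent, on the same fitted rows."""
    fit = fit_outcome_model(frame, spec)
    return fit.r2_full, fit.r2_diet_only


@dataclass
class CollinearityReport:
    correlations: pd.DataFrame
    flagged_pairs: list
    model_variants: list
    constant_exposures: list

    def needs_split(self) -> bool:
        return bool(self.flagged_pairs)


def collinearity_screen(frame: pd.DataFrame, exposures: tuple[str, ...],
                        threshold: float = 0.3) -> CollinearityReport:
    """Pairwise correlation screen of percent-change exposures.

    Any pair with |r| >= threshold is split: one model variant per member of
    each offending pair, each variant excluding the other member.  Constant
    exposures (undefined correlation) are reported, not silently dropped.
    """
    if len(exposures) < 2:
        raise AnalysisError("need at least two exposures to screen")
    cols = [f"pct_{e}" for e in exposures]
    data = frame[cols].dropna()
    constant = [e for e, c in zip(exposures, cols) if data[c].nunique() <= 1]
    corr = data.corr()
    corr.index = corr.columns = list(exposures)
    flagged = []
    for i, a in enumerate(exposures):
        for b in exposures[i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) >= threshold:
                flagged.append((a, b, float(r)))
    if flagged:
        variants = []
        for a, b, _ in flagged:
            variants.append(tuple(e for e in exposures if e != b))
            variants.append(tuple(e for e in exposures if e != a))
    else:
        variants = [tuple(exposures)]
    return CollinearityReport(corr, flagged, variants, constant)


def adjusted_stratum_means(df: pd.DataFrame, value: str,
                           strata: list[str],
                           numeric_covariates: list[str] = (),
                           categorical_covariates: list[str] = (),
                           ci_level: float = 0.95) -> pd.DataFrame:
    """Covariate-adjusted means per stratum with model-based CIs.

    Fits an OLS of ``value`` on stratum indicators plus covariates, then
    reports each stratum's marginal prediction averaged over the observed
    covariate distribution (so strata are compared at a common covariate
    mix).  Empty strata are omitted with a warning.
    """
    work = df[[value] + list(strata) + list(numeric_covariates)
              + list(categorical_covariates)].dropna().copy()
    if work.empty:
        raise AnalysisError("no complete cases for adjusted means")
    work["_stratum"] = work[list(strata)].astype(str).agg("|".join, axis=1)
    if work["_stratum"].nunique() < 1:
        raise AnalysisError("no populated strata")
    X, levels = _build_design(
        work, list(numeric_covariates),
        ["_stratum"] + list(categorical_covariates))
    _check_rank(X)
    res = sm.OLS(work[value].to_numpy(dtype=float), X).fit()
    from scipy import stats as sps
    tcrit = sps.t.ppf(0.5 + ci_level / 2, df=res.df_resid)

    rows = []
    for stratum in sorted(work["_stratum"].unique()):
        cf = work.copy()
        cf["_stratum"] = stratum
        Xcf, _ = _build_design(cf, list(numeric_covariates),
                               ["_stratum"] + list(categorical_covariates),
                               levels=levels)
        w = Xcf.to_numpy(dtype=float).mean(axis=0)
        mean = float(w @ res.params.to_numpy())
        se = float(np.sqrt(w @ res.cov_params().to_numpy() @ w))
        rows.append({
            "stratum": stratum, "n": int((work["_stratum"] == stratum).sum()),
            "adjusted_mean": mean, "se": se,
            "ci_low": mean - tcrit * se, "ci_high": mean + tcrit * se,
        })
    return pd.DataFrame(rows).set_index("stratum")


SENSITIVITY_MODES = ("change-outcome-absolute", "change-outcome-percent",
                     "adjust-baseline-bmi", "adjust-bmi-change")


@dataclass
class SensitivityResult:
    mode: str
    fit: FitResult
    delta_beta: pd.Series
    delta_p: pd.Series


def sensitivity_models(frame: pd.DataFrame, spec: ModelSpec,
                       mode: str) -> SensitivityResult:
    """Refit the outcome model under one sensitivity modification.

    change-outcome-absolute / change-outcome-percent replace the visit-2
    outcome with its 10-year change (absolute or percent); adjust-baseline-bmi
    adds baseline BMI as a covariate; adjust-bmi-change adds the 10-year BMI
    change (a potential mediator).  Reports the refit alongside the shift in
    betas and p-values relative to the main model.
    """
    if mode not in SENSITIVITY_MODES:
        raise AnalysisError(f"unknown sensitivity mode {mode!r}")
    main = fit_outcome_model(frame, spec)
    work = frame.copy()
    ocol = OUTCOME_COLUMNS[spec.outcome]
    covariates = spec.covariates
    if mode == "change-outcome-absolute":
        work[f"{ocol}2"] = frame[f"{ocol}2"] - frame[f"{ocol}1"]
    elif mode == "change-outcome-percent":
        work[f"{ocol}2"] = percent_change(frame[f"{ocol}1"], frame[f"{ocol}2"])
    elif mode == "adjust-baseline-bmi":
        covariates = tuple(covariates) + ("bmi1",)
    elif mode == "adjust-bmi-change":
        work["bmi_change"] = frame["bmi2"] - frame["bmi1"]
        covariates = tuple(covariates) + ("bmi_change",)
    alt_spec = ModelSpec(outcome=spec.outcome, exposures=spec.exposures,
                         covariates=covariates, alpha=spec.alpha)
    fit = fit_outcome_model(work, alt_spec)
    return SensitivityResult(
        mode=mode, fit=fit,
        delta_beta=fit.betas - main.betas,
        delta_p=fit.pvalues - main.pvalues,
    )


def benjamini_hochberg(pvalues: pd.Series) -> pd.Series:
    """Optional multiplicity correction over a family of exposure p-values."""
    from statsmodels.stats.multitest import multipletests
    adj = multipletests(pvalues.to_numpy(), method="fdr_bh")[1]
    return pd.Series(adj, index=pvalues.index)
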