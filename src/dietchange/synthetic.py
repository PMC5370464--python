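"""Synthetic paired-visit cohorts with known ground truth.

The generator emulates the structure the longitudinal analysis assumes: two
visits about ten years apart for each subject, FFQ frequency codes on the
9-level scale with within-subject correlation across visits (latent Gaussian
copula), portion-photograph selections, anthropometry, serum lipids recorded
on the measurement device of the exam date's era (Reflotron before
2009-09-09, enzymatic after), and categorical covariates drawn from realistic
marginal frequencies.  Visit-2 cardio-metabolic outcomes are built from an
explicit linear model — tracking of the baseline value, covariate effects,
injected true effects of the percent-change diet exposures, Gaussian noise —
so parameter recovery can be tested exactly.

Dietary exposures are not drawn directly: FFQ codes are generated and then
pushed through the package's own FFQ engine and scoring code, so the whole
downstream pipeline is exercised end to end.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import calibration, ffq
from . import instrument as ins
from . import scores

EXPOSURES = ("wholegrain_per2000", "pufa_epct", "chol_epct", "tfa_epct",
             "sucrose_epct", "hds", "dii")
OUTCOMES = ("bmi", "chol", "trig", "sbp")


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n_subjects: int = 1000
    sex_ratio_f: float = 0.52
    age_group_probs: dict = field(
        default_factory=lambda: {30: 0.04, 40: 0.47, 50: 0.485, 60: 0.005})
    baseline_year_range: tuple[int, int] = (1996, 2004)
    # visit interval drawn uniform inside the QC window, slightly away from
    # the closed [9, 11] y boundaries so day-rounding cannot cross them
    interval_low_y: float = 9.05
    interval_high_y: float = 10.95
    copula_rho: float = 0.5          # between-visit latent correlation
    freq_sd: float = 1.3             # spread of the discretised code marginals
    freq_mu_offset: float = -1.0     # shifts every item's typical level; the
    # default places enough mass on "never"/rare codes to keep reported
    # energy near observed FFQ means
    visit2_freq_shift: float = -0.15  # group-level frequency drift at visit 2
    qc_violation_rates: dict = field(default_factory=dict)
    seed: int = 0
    fct_seed: int = 0                # food composition table seed
    dii_seed: int = 0                # DII reference table seed

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not 0 <= self.sex_ratio_f <= 1:
            raise ConfigurationError("sex_ratio_f must be in [0, 1]")
        probs = np.array(list(self.age_group_probs.values()), dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ConfigurationError("age-group probabilities must be >= 0 and sum to 1")
        for rule, rate in self.qc_violation_rates.items():
            if rule not in VIOLATION_RULES:
                raise ConfigurationError(f"unknown QC violation rule {rule!r}")
            if not 0 <= rate <= 1:
                raise ConfigurationError(f"violation rate for {rule} must be in [0, 1]")
        if not -1 < self.copula_rho < 1:
            raise ConfigurationError("copula_rho must be in (-1, 1)")


#: default tracking of the baseline outcome in the visit-2 linear predictor
DEFAULT_TRACKING = {"bmi": 0.92, "chol": 0.55, "trig": 0.60, "sbp": 0.55}
#: default residual SD of the visit-2 outcome (outcome units)
DEFAULT_RESIDUAL_SD = {"bmi": 1.8, "chol": 0.84, "trig": 0.35, "sbp": 13.0}
#: intercepts per sex, chosen so marginal visit-2 means sit near the cohort's
#: reported characteristics under zero diet effects
DEFAULT_INTERCEPT = {
    ("bmi", "F"): 3.01, ("bmi", "M"): 3.09,
    ("chol", "F"): 2.78, ("chol", "M"): 2.57,
    ("trig", "F"): 0.56, ("trig", "M"): 0.66,
    ("sbp", "F"): 59.4, ("sbp", "M"): 61.3,
}
#: fixed covariate effects on visit-2 outcomes (per level / per unit)
DEFAULT_COVARIATE_EFFECTS = {
    "bmi":  {"academic": -0.30, "smoker": -0.30, "ex_smoker": -0.15,
             "activity": -0.20, "exam_year": 0.02, "age": 0.01},
    "chol": {"academic": -0.05, "smoker": 0.10, "ex_smoker": 0.05,
             "activity": -0.02, "exam_year": 0.00, "age": 0.012},
    "trig": {"academic": -0.02, "smoker": 0.05, "ex_smoker": 0.02,
             "activity": -0.02, "exam_year": 0.00, "age": 0.003},
    "sbp":  {"academic": -1.00, "smoker": 2.00, "ex_smoker": 1.00,
             "activity": -0.50, "exam_year": 0.05, "age": 0.30},
}


@dataclass
class TrueEffects:
    """Ground-truth generative parameters for the visit-2 outcome models.

    ``betas`` maps (exposure, outcome) to the outcome-unit change per one
    percent change in the exposure; unlisted pairs are zero.
    """

    betas: dict = field(default_factory=dict)
    tracking: dict = field(default_factory=lambda: dict(DEFAULT_TRACKING))
    residual_sd: dict = field(default_factory=lambda: dict(DEFAULT_RESIDUAL_SD))
    covariate_effects: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_EFFECTS.items()})

    def __post_init__(self):
        if any(sd <= 0 for sd in self.residual_sd.values()):
            raise ConfigurationError("residual SDs must be positive")
        for exp_out in self.betas:
            e, o = exp_out
            if e not in EXPOSURES or o not in OUTCOMES:
                raise ConfigurationError(f"unknown exposure/outcome pair {exp_out}")

    def beta(self, exposure: str, outcome: str) -> float:
        return float(self.betas.get((exposure, outcome), 0.0))


# --- synthetic food composition table ---------------------------------------
# per-100 g density ranges by item category:
# protein, carb, sucrose fraction of carb, fat, (sfa, pufa, tfa) fractions of
# fat, cholesterol (g), whole grain (g)
_CATEGORY_DENSITY = {
    "fish":            ((15, 22), (0, 2),   (0.0, 0.0),  (3, 14),  (0.25, 0.35, 0.00), (0.05, 0.09), (0, 0)),
    "fruit":           ((0.3, 1), (8, 15),  (0.4, 0.6),  (0, 0.5), (0.2, 0.2, 0.0),    (0, 0),       (0, 0)),
    "juice":           ((0.2, 0.6), (9, 12), (0.5, 0.7), (0, 0.2), (0.0, 0.0, 0.0),    (0, 0),       (0, 0)),
    "vegetable":       ((1, 3),   (3, 8),   (0.1, 0.3),  (0, 0.5), (0.2, 0.3, 0.0),    (0, 0),       (0, 0)),
    "potato":          ((1.5, 2.5), (15, 20), (0.0, 0.05), (0, 0.3), (0.2, 0.2, 0.0),  (0, 0),       (0, 0)),
    "grain_whole":     ((8, 13),  (45, 65), (0.02, 0.08), (2, 6),  (0.20, 0.30, 0.00), (0, 0),       (30, 70)),
    "grain_refined":   ((6, 11),  (30, 60), (0.05, 0.15), (1, 8),  (0.30, 0.20, 0.01), (0, 0.02),    (0, 5)),
    "meat_red":        ((13, 19), (0, 5),   (0.0, 0.1),  (10, 22), (0.40, 0.08, 0.02), (0.06, 0.09), (0, 0)),
    "meat_processed":  ((11, 15), (2, 6),   (0.0, 0.1),  (18, 28), (0.38, 0.10, 0.025), (0.05, 0.08), (0, 0)),
    "poultry":         ((18, 22), (0, 1),   (0.0, 0.0),  (4, 9),   (0.30, 0.20, 0.00), (0.06, 0.08), (0, 0)),
    "egg":             ((12, 13), (0, 1),   (0.0, 0.0),  (9, 11),  (0.30, 0.12, 0.00), (0.35, 0.42), (0, 0)),
    "dessert":         ((3, 6),   (45, 65), (0.5, 0.7),  (12, 25), (0.45, 0.08, 0.04), (0.01, 0.06), (0, 3)),
    "ssb":             ((0, 0.1), (9, 11),  (0.85, 0.95), (0, 0.1), (0.0, 0.0, 0.0),   (0, 0),       (0, 0)),
    "fried_potato":    ((2, 3.5), (25, 35), (0.0, 0.02), (8, 15),  (0.35, 0.15, 0.03), (0, 0.01),    (0, 0)),
    "snack":           ((5, 7),   (45, 55), (0.02, 0.06), (25, 35), (0.35, 0.15, 0.02), (0, 0),      (0, 0)),
    "nut":             ((18, 25), (8, 15),  (0.1, 0.2),  (45, 55), (0.12, 0.35, 0.00), (0, 0),       (0, 0)),
    "dairy_milk":      ((3, 4),   (4, 5.5), (0.0, 0.0),  (0.5, 3.5), (0.60, 0.04, 0.02), (0.005, 0.015), (0, 0)),
    "dairy_cheese":    ((24, 28), (0, 2),   (0.0, 0.0),  (25, 33), (0.60, 0.04, 0.02), (0.07, 0.10), (0, 0)),
    "dairy_cream":     ((2, 3),   (3, 4),   (0.1, 0.2),  (25, 38), (0.60, 0.04, 0.02), (0.08, 0.12), (0, 0)),
    "fat_butter":      ((0.5, 1), (0, 1),   (0.0, 0.0),  (78, 82), (0.60, 0.04, 0.02), (0.20, 0.25), (0, 0)),
    "fat_margarine":   ((0, 0.5), (0, 1),   (0.0, 0.0),  (60, 80), (0.28, 0.25, 0.08), (0, 0),       (0, 0)),
    "fat_oil":         ((0, 1),   (0, 3),   (0.0, 0.0),  (60, 90), (0.12, 0.50, 0.00), (0, 0.02),    (0, 0)),
    "beverage":        ((0, 0.3), (0, 0.5), (0.0, 0.0),  (0, 0.1), (0.0, 0.0, 0.0),    (0, 0),       (0, 0)),
    "beverage_energy": ((0.3, 0.5), (2, 4), (0.0, 0.1),  (0, 0.1), (0.0, 0.0, 0.0),    (0, 0),       (0, 0)),
    "sugar":           ((0, 0.3), (60, 99), (0.7, 0.95), (0, 0.2), (0.0, 0.0, 0.0),    (0, 0),       (0, 0)),
    "mixed":           ((6, 10),  (10, 20), (0.02, 0.08), (6, 12), (0.35, 0.12, 0.01), (0.02, 0.04), (0, 4)),
}


def generate_food_composition_table(seed: int = 0) -> ffq.FoodCompositionTable:
    """Draw a 64-item nutrient-density table consistent by construction.

    Densities are drawn per item within plausible category-specific ranges;
    item energy is defined as the Atwater combination 4*protein +
    4*carbohydrate + 9*fat, sucrose as a fraction of carbohydrate, and the
    fat subclasses as fractions of total fat, so the table's internal
    hierarchies hold exactly.
    """
    rng = np.random.default_rng([int(seed), 101])
    rows = []
    for it in ins.ITEMS:
        (p_r, c_r, sf_r, f_r, fracs, ch_r, wg_r) = _CATEGORY_DENSITY[it.category]
        protein = rng.uniform(*p_r)
        carb = rng.uniform(*c_r)
        suc = carb * rng.uniform(*sf_r)
        fat = rng.uniform(*f_r)
        sfa_f, pufa_f, tfa_f = fracs
        rows.append({
            "protein_g": protein, "carb_g": carb, "sucrose_g": suc,
            "fat_g": fat, "sfa_g": fat * sfa_f, "pufa_g": fat * pufa_f,
            "tfa_g": fat * tfa_f, "chol_g": rng.uniform(*ch_r),
            "wholegrain_g": rng.uniform(*wg_r),
            "energy_kcal": 4 * protein + 4 * carb + 9 * fat,
        })
    df = pd.DataFrame(rows, index=list(ins.ITEM_NAMES))
    return ffq.FoodCompositionTable(df)


def generate_dii_reference(seed: int = 0) -> scores.DiiConfig:
    """Draw a 30-parameter DII reference (global mean, SD, effect weight).

    Global means are centred on the typical intake implied by each item's
    standard portion and typical frequency so that synthetic z-scores are
    well scaled; effect weight signs follow the instrument's category
    convention (anti-inflammatory negative).
    """
    rng = np.random.default_rng([int(seed), 202])
    rates = np.asarray(ins.DEFAULT_RATES_PER_DAY)
    levels = np.arange(ins.N_FREQ_LEVELS)

    def typical_grams(item: ins.ItemDef) -> float:
        rate = float(np.interp(item.freq_mu, levels, rates))
        if item.photo_class is not None:
            portion = float(np.mean(ins.DEFAULT_PHOTO_GRAMS[item.photo_class]))
        else:
            portion = item.portion_g
        return rate * portion

    by_name = {it.name: it for it in ins.ITEMS}
    rows = []
    for param in ins.DII_PARAMS:
        if param == "caffeine":
            typ = sum(typical_grams(by_name[bev]) * mg
                      for bev, mg in ins.CAFFEINE_MG_PER_G.items())
        else:
            typ = typical_grams(by_name[param])
        mean = max(typ, 1e-3) * rng.uniform(0.8, 1.2)
        rows.append({
            "global_mean": mean,
            "global_sd": mean * rng.uniform(0.4, 0.7),
            "effect_weight": ins.dii_effect_sign(param) * rng.uniform(0.05, 0.45),
        })
    table = pd.DataFrame(rows, index=list(ins.DII_PARAMS))
    return scores.DiiConfig(table)


# --- cohort generation -------------------------------------------------------

_HEIGHT = {"F": (165.6, 5.9), "M": (179.1, 6.4)}
_BMI1 = {"F": (25.1, 4.3), "M": (26.1, 3.3)}
_CHOL1 = {"F": (5.5, 0.9), "M": (5.7, 1.0)}          # enzymatic scale
_SBP1 = {"F": (121.1, 15.9), "M": (125.6, 14.2)}
_EDU_P = {"F": 0.352, "M": 0.234}                     # P(academic)
_SMOKE_P = {"F": (0.215, 0.320, 0.465), "M": (0.181, 0.319, 0.500)}
_ACT_P = {"F": (0.172, 0.343, 0.278, 0.207), "M": (0.186, 0.329, 0.287, 0.198)}
_PHOTO_P = {"F": (0.30, 0.40, 0.25, 0.05), "M": (0.10, 0.30, 0.40, 0.20)}

VIOLATION_RULES = ("ffq_missing", "portion_missing", "fil_missing",
                   "anthropometry", "interval")


def generate_cohort(config: SimulationConfig,
                    effects: TrueEffects | None = None,
                    return_truth: bool = False):
    """Generate a paired-visit cohort table (one row per subject-visit).

    Visit-2 outcomes satisfy the linear ground-truth model exactly up to
    Gaussian noise; lipids are recorded on the device scale of the exam
    date's era.  With ``return_truth=True`` also returns the realised percent
    changes per exposure and the noiseless linear predictors, for parameter
    recovery tests.
    """
    effects = effects or TrueEffects()
    rng = np.random.default_rng([int(config.seed), 1])
    n = config.n_subjects

    sex = np.where(rng.random(n) < config.sex_ratio_f, "F", "M")
    groups = np.array(list(config.age_group_probs))
    gprobs = np.array(list(config.age_group_probs.values()), dtype=float)
    age_group = rng.choice(groups, size=n, p=gprobs / gprobs.sum())

    y0, y1 = config.baseline_year_range
    base_year = rng.integers(y0, y1 + 1, size=n)
    day = rng.integers(0, 365, size=n)
    date1 = (pd.to_datetime(base_year.astype(str) + "-01-01")
             + pd.to_timedelta(day, unit="D"))
    interval = rng.uniform(config.interval_low_y, config.interval_high_y, size=n)
    date2 = date1 + pd.to_timedelta(np.round(interval * 365.25).astype(int), unit="D")

    height1 = np.empty(n)
    bmi1 = np.empty(n)
    chol1 = np.empty(n)
    sbp1 = np.empty(n)
    edu = np.empty(n, dtype=object)
    smoke = np.empty(n, dtype=object)
    act = np.empty(n, dtype=object)
    photo1 = {c: np.empty(n, dtype=int) for c in ins.PHOTO_CLASSES}
    photo2 = {c: np.empty(n, dtype=int) for c in ins.PHOTO_CLASSES}
    smoke_levels = np.array(["smoker", "ex_smoker", "never"])
    act_levels = np.array(["inactive", "mod_inactive", "mod_active", "active"])
    for s in ("F", "M"):
        m = sex == s
        k = int(m.sum())
        height1[m] = np.clip(rng.normal(*_HEIGHT[s], size=k), 150, 205)
        bmi1[m] = np.clip(rng.normal(*_BMI1[s], size=k), 17, 55)
        chol1[m] = np.clip(rng.normal(*_CHOL1[s], size=k), 2.5, 12)
        sbp1[m] = np.clip(rng.normal(*_SBP1[s], size=k), 85, 220)
        edu[m] = np.where(rng.random(k) < _EDU_P[s], "academic", "basic")
        smoke[m] = rng.choice(smoke_levels, size=k, p=_SMOKE_P[s])
        act[m] = rng.choice(act_levels, size=k, p=_ACT_P[s])
        for c in ins.PHOTO_CLASSES:
            photo1[c][m] = rng.choice([1, 2, 3, 4], size=k, p=_PHOTO_P[s])
            photo2[c][m] = rng.choice([1, 2, 3, 4], size=k, p=_PHOTO_P[s])
    weight1 = bmi1 * (height1 / 100.0) ** 2
    height2 = height1 - 0.5
    # visit-1 triglycerides: Reflotron raw readings drawn lognormal, so the
    # calibrated scale inherits the published map's compression
    trig_raw1 = rng.lognormal(mean=np.log(1.15), sigma=0.5, size=n)
    trig1 = calibration.CALIBRATION["triglycerides"][0] \
        + calibration.CALIBRATION["triglycerides"][1] * trig_raw1

    # frequency-code marginals: per-item typical level plus subject-level
    # appetite heterogeneity, drifted at visit 2
    item_mu = np.array([it.freq_mu for it in ins.ITEMS]) + config.freq_mu_offset
    appetite = rng.normal(0, 0.35, size=n)
    mu1 = item_mu[None, :] + appetite[:, None]
    mu2 = mu1 + config.visit2_freq_shift
    # latent Gaussian copula: correlated normals across visits, mapped through
    # each subject-item's discretised-normal marginal over the 9 levels
    k = np.arange(ins.N_FREQ_LEVELS)
    z1 = rng.standard_normal((n, ins.N_ITEMS))
    z2 = (config.copula_rho * z1
          + np.sqrt(1 - config.copula_rho ** 2) * rng.standard_normal((n, ins.N_ITEMS)))
    codes = []
    for z, mu in ((z1, mu1), (z2, mu2)):
        logits = -((k[None, None, :] - mu[:, :, None]) ** 2) / (2 * config.freq_sd ** 2)
        probs = np.exp(logits)
        probs /= probs.sum(axis=2, keepdims=True)
        cum = np.cumsum(probs, axis=2)
        u = stats.norm.cdf(z)
        c = (u[:, :, None] > cum[:, :, :-1]).sum(axis=2)
        codes.append(np.clip(c, 0, 8))
    codes1, codes2 = codes

    subject_id = np.arange(1, n + 1)

    def visit_frame(visit, codes_v, photo_v, date_v, height, weight):
        df = pd.DataFrame({
            "subject_id": subject_id, "visit": visit, "sex": sex,
            "age_group": age_group.astype(int),
        })
        age = age_group.astype(float) if visit == 1 else age_group + interval
        df["age"] = age
        df["exam_date"] = pd.Series(date_v).dt.strftime("%Y-%m-%d")
        df["exam_year"] = pd.Series(date_v).dt.year
        df["education"] = edu
        df["smoking"] = smoke
        df["activity"] = act
        df["height_cm"] = height
        df["weight_kg"] = weight
        for c in ins.PHOTO_CLASSES:
            df[f"photo_{c}"] = photo_v[c].astype(float)
        for j, col in enumerate(ins.FFQ_COLUMNS):
            df[col] = codes_v[:, j].astype(float)
        return df

    long1 = visit_frame(1, codes1, photo1, date1, height1, weight1)
    long2 = visit_frame(2, codes2, photo2, date2, height2, np.nan)
    both = pd.concat([long1, long2], ignore_index=True)

    # run the package's own derivation to obtain realised exposures
    fct = generate_food_composition_table(config.fct_seed)
    dii_ref = generate_dii_reference(config.dii_seed)
    processed = ffq.process_records(both, fct)
    scored = scores.score_cohort(processed, dii_ref)
    v1 = scored[scored["visit"] == 1].set_index("subject_id")
    v2 = scored[scored["visit"] == 2].set_index("subject_id")

    pct = {}
    for exp in EXPOSURES:
        x1 = v1.loc[subject_id, exp].to_numpy(dtype=float)
        x2 = v2.loc[subject_id, exp].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = 100.0 * (x2 - x1) / x1
        pct[exp] = np.where(np.isclose(x1, 0) | ~np.isfinite(p), np.nan, p)

    baseline = {"bmi": bmi1, "chol": chol1, "trig": trig1, "sbp": sbp1}
    cov = effects.covariate_effects
    exam_year_c = base_year - 2000.0
    age_c = age_group.astype(float) - 45.0
    act_score = pd.Categorical(act, categories=act_levels).codes.astype(float)
    linpred = {}
    outcome2 = {}
    for out in OUTCOMES:
        intercept = np.array([DEFAULT_INTERCEPT[(out, s)] for s in sex])
        lp = intercept + effects.tracking[out] * baseline[out]
        ce = cov.get(out, {})
        lp = lp + ce.get("academic", 0.0) * (edu == "academic")
        lp = lp + ce.get("smoker", 0.0) * (smoke == "smoker")
        lp = lp + ce.get("ex_smoker", 0.0) * (smoke == "ex_smoker")
        lp = lp + ce.get("activity", 0.0) * act_score
        lp = lp + ce.get("exam_year", 0.0) * exam_year_c
        lp = lp + ce.get("age", 0.0) * age_c
        for exp in EXPOSURES:
            b = effects.beta(exp, out)
            if b:
                lp = lp + b * np.nan_to_num(pct[exp], nan=0.0)
        linpred[out] = lp
        outcome2[out] = lp + rng.normal(0, effects.residual_sd[out], size=n)

    # record measured values, on the device scale where applicable
    # clip recorded visit-2 BMI away from the QC bounds so natural
    # anthropometry violations cannot occur unless injected
    weight2 = np.clip(outcome2["bmi"], 16, 60) * (height2 / 100.0) ** 2
    device1 = calibration.infer_device(date1)
    device2 = calibration.infer_device(date2)

    def to_device(true_vals, analyte, device):
        intercept, slope = calibration.CALIBRATION[analyte]
        raw = (true_vals - intercept) / slope
        raw = np.maximum(raw, 0.05)
        return np.where(device == "Reflotron", raw, np.maximum(true_vals, 0.05))

    mask1 = both["visit"] == 1
    mask2 = both["visit"] == 2
    both.loc[mask1, "chol_mmol_l"] = to_device(chol1, "cholesterol", device1)
    both.loc[mask1, "trig_mmol_l"] = np.where(
        device1 == "Reflotron", trig_raw1, trig1)
    both.loc[mask1, "sbp_mmhg"] = sbp1
    both.loc[mask1, "device"] = device1
    both.loc[mask2, "weight_kg"] = weight2
    both.loc[mask2, "chol_mmol_l"] = to_device(
        np.maximum(outcome2["chol"], 1.0), "cholesterol", device2)
    both.loc[mask2, "trig_mmol_l"] = to_device(
        np.maximum(outcome2["trig"], 0.2), "triglycerides", device2)
    both.loc[mask2, "sbp_mmhg"] = np.clip(outcome2["sbp"], 70, 260)
    both.loc[mask2, "device"] = device2

    if return_truth:
        truth = pd.DataFrame({"subject_id": subject_id, "sex": sex})
        for exp in EXPOSURES:
            truth[f"pct_{exp}"] = pct[exp]
        for out in OUTCOMES:
            truth[f"linpred_{out}"] = linpred[out]
            truth[f"outcome2_{out}"] = outcome2[out]
        return both, truth
    return both


def inject_qc_violations(cohort: pd.DataFrame, config: SimulationConfig):
    """Corrupt records so each exclusion rule fires at its configured rate.

    Subjects are drawn without replacement and disjointly across rules so the
    returned ledger (rule -> sorted subject ids) matches the cascade's
    per-rule flags count for count.  Rates of zero (the default) leave the
    cohort untouched.
    """
    rates = {r: float(config.qc_violation_rates.get(r, 0.0)) for r in VIOLATION_RULES}
    out = cohort.copy()
    rng = np.random.default_rng([int(config.seed), 2])
    subjects = out["subject_id"].unique()
    available = list(rng.permutation(subjects))
    ledger: dict[str, list] = {}
    for rule in VIOLATION_RULES:
        n_hit = rng.binomial(len(subjects), rates[rule])
        n_hit = min(n_hit, len(available))
        hit = [available.pop() for _ in range(n_hit)]
        ledger[rule] = sorted(int(s) for s in hit)
        for sid in hit:
            visit = int(rng.integers(1, 3))
            row = (out["subject_id"] == sid) & (out["visit"] == visit)
            if rule == "ffq_missing":
                # blank 8/64 items: 12.5% > the 10% threshold
                items = rng.choice(ins.FFQ_COLUMNS, size=8, replace=False)
                out.loc[row, list(items)] = np.nan
            elif rule == "portion_missing":
                col = rng.choice(ins.PHOTO_COLUMNS)
                out.loc[row, col] = np.nan
            elif rule == "fil_missing":
                out.loc[row, "weight_kg"] = np.nan
            elif rule == "anthropometry":
                out.loc[row, "weight_kg"] = 30.0
            elif rule == "interval":
                row2 = (out["subject_id"] == sid) & (out["visit"] == 2)
                row1 = (out["subject_id"] == sid) & (out["visit"] == 1)
                # place visit 2 firmly outside the closed [9, 11] y window
                target_y = float(rng.choice([8.3, 11.7]))
                d1 = pd.to_datetime(out.loc[row1, "exam_date"].iloc[0])
                d = pd.Series(d1 + pd.Timedelta(days=round(target_y * 365.25)),
                              index=out.index[row2])
                out.loc[row2, "exam_date"] = d.dt.strftime("%Y-%m-%d")
                out.loc[row2, "exam_year"] = d.dt.year.astype(float)
                out.loc[row2, "device"] = calibration.infer_device(d)
    return out, ledger


def config_hash(config: SimulationConfig) -> str:
    payload = json.dumps(
        {k: (list(v) if isinstance(v, tuple) else v)
         for k, v in vars(config).items()}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_cohort(cohort: pd.DataFrame, path, config: SimulationConfig) -> None:
    """Write the cohort as TSV plus a JSON run-metadata sidecar."""
    cohort.to_csv(path, sep="\t", index=False)
    meta = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "n_subjects": int(cohort["subject_id"].nunique()),
        "n_rows": int(len(cohort)),
    }
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sex": str, "device": str})
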