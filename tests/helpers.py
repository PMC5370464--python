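"""Direct simulators for the regression-engine tests.

These build per-subject change frames without going through the FFQ pipeline,
so the regression machinery can be exercised against exactly known designs.
"""

import numpy as np
import pandas as pd

from dietchange.analysis import JOINT_EXPOSURES

EDU = np.array(["basic", "academic"])
SMOKE = np.array(["never", "ex_smoker", "smoker"])
ACT = np.array(["inactive", "mod_inactive", "mod_active", "active"])


def simulate_change_frame(rng, n, betas=None, tracking=0.92, resid_sd=1.8,
                          outcome="bmi", exposure_sd=20.0):
    """One-sex change frame with known exposure effects on the outcome.

    ``betas`` maps exposure name -> outcome-units per percent change.
    Covariates carry real effects so that adjustment matters.
    """
    betas = betas or {}
    frame = pd.DataFrame({
        "sex": "F",
        "age1": rng.choice([30.0, 40.0, 50.0, 60.0], size=n),
        "exam_year1": rng.integers(1996, 2005, size=n).astype(float),
        "education": rng.choice(EDU, size=n),
        "smoking": rng.choice(SMOKE, size=n),
        "activity": rng.choice(ACT, size=n),
    })
    for exp in JOINT_EXPOSURES:
        frame[f"pct_{exp}"] = rng.normal(0, exposure_sd, size=n)
    base = rng.normal(25.1, 4.3, size=n)
    y = tracking * base + 3.0
    y = y + 0.4 * (frame["education"] == "academic").to_numpy()
    y = y - 0.5 * (frame["smoking"] == "smoker").to_numpy()
    y = y + 0.3 * (frame["activity"] == "active").to_numpy()
    y = y + 0.02 * (frame["exam_year1"].to_numpy() - 2000)
    y = y + 0.01 * (frame["age1"].to_numpy() - 45)
    for exp, b in betas.items():
        y = y + b * frame[f"pct_{exp}"].to_numpy()
    y = y + rng.normal(0, resid_sd, size=n)
    from dietchange.analysis import OUTCOME_COLUMNS
    ocol = OUTCOME_COLUMNS[outcome]
    frame[f"{ocol}1"] = base
    frame[f"{ocol}2"] = y
    return frame


def normal_equations(X, y):
    """Closed-form OLS oracle: betas and classical SEs from (X'X)^-1."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(y) - X.shape[1])
    se = np.sqrt(np.diag(sigma2 * xtx_inv))
    return beta, se


def build_design_like_package(frame, numeric, categorical):
    """Reference-coded design rebuilt independently of the package helper."""
    X = pd.DataFrame({"const": np.ones(len(frame))}, index=frame.index)
    for col in numeric:
        X[col] = frame[col].astype(float)
    for col in categorical:
        ref = frame[col].value_counts().index[0]
        for lv in sorted(frame[col].unique()):
            if lv != ref:
                X[f"{col}[{lv}]"] = (frame[col] == lv).astype(float)
    return X
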