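"""Harmonisation of Reflotron bench-top lipid readings to the enzymatic method.

Serum cholesterol and triglycerides were measured on a Reflotron dry-chemistry
analyzer until 2009-09-09 and with an enzymatic routine method thereafter.
Reflotron readings are mapped onto the enzymatic scale with the published
affine calibrations:

    cholesterol_corrected   = 0.738 + 0.901 * cholesterol_Reflotron
    triglycerides_corrected = 0.888 + 0.139 * triglycerides_Reflotron

Enzymatic values pass through unchanged.  The triglyceride slope (0.139) is
implemented exactly as published; note it compresses the Reflotron-era
triglyceride scale considerably.
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REFLOTRON_CUTOFF = dt.date(2009, 9, 9)

CALIBRATION = {
    "cholesterol": (0.738, 0.901),
    "triglycerides": (0.888, 0.139),
}
DEVICES = ("Reflotron", "enzymatic")


class CalibrationError(ValueError):
    pass


def infer_device(exam_date) -> np.ndarray:
    """Device from exam date: Reflotron strictly before 2009-09-09."""
    dates = pd.to_datetime(pd.Series(np.atleast_1d(exam_date)))
    return np.where(dates.dt.date < REFLOTRON_CUTOFF, "Reflotron", "enzymatic")


def calibrate(value, analyte: str, device) -> np.ndarray | float:
    """Map lipid readings onto the enzymatic scale.

    ``value`` in mmol/l (> 0); ``device`` per element, "Reflotron" readings
    are transformed, "enzymatic" pass through unchanged.
    """
    if analyte not in CALIBRATION:
        raise CalibrationError(f"unknown analyte: {analyte!r}")
    intercept, slope = CALIBRATION[analyte]
    vals = np.asarray(value, dtype=float)
    dev = np.asarray(device)
    known = np.isin(dev, DEVICES)
    if not known.all():
        raise CalibrationError(f"unknown device(s): {np.unique(dev[~known])}")
    with np.errstate(invalid="ignore"):
        if (np.nan_to_num(vals, nan=1.0) <= 0).any():
            raise CalibrationError("lipid values must be positive")
    out = np.where(dev == "Reflotron", intercept + slope * vals, vals)
    if np.isscalar(value):
        return float(out)
    return out


def calibrate_cohort(df: pd.DataFrame,
                     chol_col: str = "chol_mmol_l",
                     trig_col: str = "trig_mmol_l",
                     device_col: str = "device",
                     date_col: str = "exam_date") -> pd.DataFrame:
    """Calibrate a cohort table's lipid columns in place (on a copy).

    The explicit device column is used when present; otherwise the device is
    inferred from the exam date.
    """
    out = df.copy()
    if device_col in out.columns:
        device = out[device_col].to_numpy()
    else:
        device = infer_device(out[date_col])
    n_reflo = int((device == "Reflotron").sum())
    out[chol_col] = calibrate(out[chol_col].to_numpy(), "cholesterol", device)
    out[trig_col] = calibrate(out[trig_col].to_numpy(), "triglycerides", device)
    logger.info("calibrated %d Reflotron-era lipid records", n_reflo)
    return out
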