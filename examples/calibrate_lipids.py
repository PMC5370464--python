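"""Harmonise Reflotron-era lipid readings to the enzymatic method.

Reflotron bench-top readings (used before 2009-09-09) are mapped onto the
enzymatic scale with published affine calibrations; enzymatic-era values pass
through unchanged.
"""

import pandas as pd

import dietchange as dc

measurements = pd.DataFrame({
    "exam_date": ["1999-05-02", "2003-11-20", "2012-03-14"],
    "chol_mmol_l": [5.0, 6.2, 5.0],
    "trig_mmol_l": [1.0, 2.4, 1.0],
})
measurements["device"] = dc.infer_device(measurements["exam_date"])
calibrated = dc.calibrate_cohort(measurements)

print(pd.concat([measurements[["exam_date", "device"]],
                 calibrated[["chol_mmol_l", "trig_mmol_l"]]], axis=1))
# Reflotron cholesterol 5.0 -> 0.738 + 0.901*5.0 = 5.243 mmol/l, while the
# 2012 enzymatic reading is already on the reference scale and is unchanged.
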