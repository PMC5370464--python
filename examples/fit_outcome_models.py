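"""Fit percent-change diet exposure models with a known injected effect.

Injects a true effect of 0.02 mmol/l serum cholesterol per 1% change in
trans-fat E% (i.e. 0.2 per 10% change), runs the full pipeline on 5,000
subjects, and fits the joint outcome model per sex.  The fitted trans-fat
beta should sit within a few SE of 0.02.
"""

import dietchange as dc
from dietchange.analysis import JOINT_EXPOSURES_TFA

effects = dc.TrueEffects(betas={("tfa_epct", "chol"): 0.02})
cfg = dc.SimulationConfig(n_subjects=5000, seed=1)
cohort = dc.generate_cohort(cfg, effects)

fct = dc.generate_food_composition_table(0)
dii_ref = dc.generate_dii_reference(0)
frame = dc.build_change_frame(dc.calibrate_cohort(
    dc.score_cohort(dc.process_records(cohort, fct), dii_ref)))

spec = dc.ModelSpec("chol", exposures=JOINT_EXPOSURES_TFA)
for sex in ("F", "M"):
    fit = dc.fit_outcome_model(frame[frame["sex"] == sex], spec)
    print(f"\n{sex}: serum cholesterol at visit 2 ~ percent diet changes "
          f"(n={fit.n_used})")
    print(fit.table().round(4))
    print(f"R2 full = {fit.r2_full:.1f}%, diet-only = {fit.r2_diet_only:.2f}%")
# tfa_epct's beta estimates the injected 0.02; the other exposures carry no
# true effect, so their betas hover near zero.  The diet-only R2 shows how
# little outcome variance the diet changes explain next to baseline tracking.
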