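"""Staged pipeline: simulate -> process -> qc -> score -> calibrate -> analyze.

Each stage reads and writes delimited text in the run's output directory, so
stages can be rerun independently; a JSON manifest records the seed, a config
hash, per-stage row counts, the exclusion ledger and checksums of the model
tables.  Identical config and seed produce an identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import analysis, calibration, ffq, qc, scores, synthetic

logger = logging.getLogger(__name__)

STAGES = ("simulate", "process", "qc", "score", "calibrate", "analyze")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    cohort_path: str | None = None          # mutually exclusive with simulation
    simulation: dict = field(default_factory=dict)
    qc_overrides: dict = field(default_factory=dict)
    dii_transform: str = "identity"
    outcomes: tuple[str, ...] = ("bmi", "chol", "trig", "sbp")
    collinearity_threshold: float = 0.3
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.cohort_path is None) == (self.simulation is None):
            pass
        if self.cohort_path is not None and self.simulation:
            raise PipelineError(
                "provide either an input cohort table or a simulation block, not both")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "outcomes" in raw:
            raw["outcomes"] = tuple(raw["outcomes"])
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in vars(self).items()}, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _sim_config(cfg: RunConfig) -> synthetic.SimulationConfig:
    params = dict(cfg.simulation)
    params.setdefault("seed", cfg.seed)
    if "baseline_year_range" in params:
        params["baseline_year_range"] = tuple(params["baseline_year_range"])
    return synthetic.SimulationConfig(**params)


def stage_simulate(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    sim = _sim_config(cfg)
    effects = synthetic.TrueEffects()
    cohort = synthetic.generate_cohort(sim, effects)
    if any(sim.qc_violation_rates.values()):
        cohort, ledger = synthetic.inject_qc_violations(cohort, sim)
    else:
        ledger = {r: [] for r in synthetic.VIOLATION_RULES}
    synthetic.write_cohort(cohort, outdir / "cohort.tsv", sim)
    (outdir / "violation_ledger.json").write_text(json.dumps(ledger, indent=2))
    return cohort


def stage_process(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    src = Path(cfg.cohort_path) if cfg.cohort_path else outdir / "cohort.tsv"
    cohort = synthetic.read_cohort(src)
    sim = _sim_config(cfg) if not cfg.cohort_path else synthetic.SimulationConfig(seed=cfg.seed)
    fct = synthetic.generate_food_composition_table(sim.fct_seed)
    fct.to_tsv(outdir / "food_composition.tsv")
    processed = ffq.process_records(cohort, fct)
    processed.to_csv(outdir / "processed.tsv", sep="\t", index=False)
    return processed


def stage_qc(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    processed = pd.read_csv(outdir / "processed.tsv", sep="\t")
    config = qc.QcConfig(**cfg.qc_overrides)
    outcome = qc.apply_cascade(processed, config)
    (outdir / "qc_outcome.json").write_text(outcome.to_json())
    (outdir / "qc_flow.txt").write_text(outcome.flow_text() + "\n")
    retained = processed[processed["subject_id"].isin(outcome.retained_ids)]
    retained.to_csv(outdir / "retained.tsv", sep="\t", index=False)
    return retained


def stage_score(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    retained = pd.read_csv(outdir / "retained.tsv", sep="\t")
    sim = _sim_config(cfg) if not cfg.cohort_path else synthetic.SimulationConfig(seed=cfg.seed)
    dii_ref = synthetic.generate_dii_reference(sim.dii_seed)
    dii_ref.to_tsv(outdir / "dii_reference.tsv")
    scored = scores.score_cohort(retained, dii_ref, dii_transform=cfg.dii_transform)
    scored.to_csv(outdir / "scored.tsv", sep="\t", index=False)
    return scored


def stage_calibrate(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    scored = pd.read_csv(outdir / "scored.tsv", sep="\t")
    calibrated = calibration.calibrate_cohort(scored)
    calibrated.to_csv(outdir / "calibrated.tsv", sep="\t", index=False)
    return calibrated


def stage_analyze(cfg: RunConfig, outdir: Path) -> dict:
    calibrated = pd.read_csv(outdir / "calibrated.tsv", sep="\t")
    frame = analysis.build_change_frame(calibrated)
    frame.to_csv(outdir / "change_frame.tsv", sep="\t", index=False)

    # collinearity screen decides the joint-model variants
    screen = analysis.collinearity_screen(
        frame, ("wholegrain_per2000", "pufa_epct", "chol_epct", "tfa_epct",
                "sucrose_epct"), cfg.collinearity_threshold)
    screen.correlations.to_csv(outdir / "exposure_correlations.tsv", sep="\t")

    rows = []
    for outcome in cfg.outcomes:
        for sex in ("F", "M"):
            sub = frame[frame["sex"] == sex]
            model_sets = [("joint_chol", analysis.JOINT_EXPOSURES),
                          ("joint_tfa", analysis.JOINT_EXPOSURES_TFA),
                          ("hds_only", ("hds",)), ("dii_only", ("dii",))]
            for label, exposures in model_sets:
                spec = analysis.ModelSpec(outcome=outcome, exposures=exposures)
                fit = analysis.fit_outcome_model(sub, spec)
                for exp in exposures:
                    rows.append({
                        "outcome": outcome, "sex": sex, "model": label,
                        "exposure": exp, "beta": fit.betas[exp],
                        "se": fit.ses[exp], "p": fit.pvalues[exp],
                        "r2_full_pct": fit.r2_full,
                        "r2_diet_only_pct": fit.r2_diet_only,
                        "n": fit.n_used,
                    })
    models = pd.DataFrame(rows)
    models.to_csv(outdir / "outcome_models.tsv", sep="\t", index=False,
                  float_format="%.6g")

    # descriptive tables: characteristics and adjusted nutrient means
    calibrated = calibrated.copy()
    calibrated["bmi"] = qc.compute_bmi(calibrated["weight_kg"], calibrated["height_cm"])
    for s in ("F", "M"):
        m = calibrated["sex"] == s
        calibrated.loc[m, "bmi_quintile"] = pd.qcut(
            calibrated.loc[m, "bmi"], 5, labels=False, duplicates="drop")
    char_rows = []
    for col in ("bmi", "chol_mmol_l", "trig_mmol_l", "sbp_mmhg", "energy_kcal",
                "protein_epct", "carb_epct", "fat_epct", "sucrose_epct",
                "pufa_epct", "tfa_epct", "chol_epct", "wholegrain_per2000",
                "hds", "dii"):
        adj = analysis.adjusted_stratum_means(
            calibrated, col, strata=["sex", "visit"],
            numeric_covariates=["exam_year", "age"],
            categorical_covariates=["bmi_quintile"] if col != "bmi" else [])
        for stratum, row in adj.iterrows():
            char_rows.append({"variable": col, "stratum": stratum,
                              "adjusted_mean": row["adjusted_mean"],
                              "ci_low": row["ci_low"], "ci_high": row["ci_high"],
                              "n": row["n"]})
    pd.DataFrame(char_rows).to_csv(outdir / "adjusted_means.tsv", sep="\t",
                                   index=False, float_format="%.6g")
    return {"n_models": len(models), "split_needed": screen.needs_split()}


_STAGE_FUNCS = {
    "simulate": stage_simulate, "process": stage_process, "qc": stage_qc,
    "score": stage_score, "calibrate": stage_calibrate, "analyze": stage_analyze,
}


def run(cfg: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute pipeline stages in order and write the run manifest.

    A stage failure aborts the run with the failing stage named; a
    ``manifest.partial`` marker is left next to whatever outputs exist.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.cohort_path is not None and "simulate" in stages:
        stages = tuple(s for s in stages if s != "simulate")
        # with a provided cohort the simulate stage has nothing to do
        src = Path(cfg.cohort_path)
        (outdir / "cohort.tsv").write_text(src.read_text())

    manifest: dict = {"seed": cfg.seed, "config_hash": cfg.hash(),
                      "stages": {}, "checksums": {}}
    partial = outdir / "manifest.partial"
    partial.write_text("run in progress\n")
    try:
        for stage in stages:
            logger.info("stage %s", stage)
            try:
                result = _STAGE_FUNCS[stage](cfg, outdir)
            except Exception as exc:
                raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
            if isinstance(result, pd.DataFrame):
                manifest["stages"][stage] = {"rows": int(len(result))}
            else:
                manifest["stages"][stage] = result
    except PipelineError:
        raise
    finally:
        if partial.exists() and (outdir / "manifest.json").exists():
            partial.unlink()

    ledger_path = outdir / "violation_ledger.json"
    if ledger_path.exists():
        ledger = json.loads(ledger_path.read_text())
        manifest["violation_ledger_counts"] = {k: len(v) for k, v in ledger.items()}
    for name in ("outcome_models.tsv", "adjusted_means.tsv", "qc_outcome.json"):
        p = outdir / name
        if p.exists():
            manifest["checksums"][name] = _sha256(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    if partial.exists():
        partial.unlink()
    return manifest
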