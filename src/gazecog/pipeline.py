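"""End-to-end orchestration: simulate -> score -> exposure -> associate -> report.

Each stage reads and writes plain CSV/JSON artifacts in a run directory,
never mutating another stage's outputs, and every run records provenance
(config hash, seed, package version).  Warnings are emitted both to the
log and as machine-parseable JSON lines in ``warnings.jsonl``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from . import airquality, assoc, gaze_io, looking, synth

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class ExposureStageConfig:
    k_hour: int = 11
    k_date: int = 11
    rho: float = 0.6
    min_round_hours: float = 5.0
    qc_bounds: tuple[float, float] = (1.0, 750.0)
    max_flag_fraction: float = 0.10


@dataclass
class ModelsConfig:
    alpha: float = 0.05
    candidates_cp: list[str] = field(default_factory=lambda: [
        "Year:SES", "Year:LookingWindow1", "SES:LookingWindow1",
        "Year:SES:LookingWindow1",
    ])
    candidates_shift: list[str] = field(default_factory=lambda: ["Year:SES"])
    analysis_unit: str = "cells"  # or "trials"

    def __post_init__(self):
        if self.analysis_unit not in ("cells", "trials"):
            raise ValueError("analysis_unit must be 'cells' or 'trials'")


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict | None = None      # GenConfig overrides; None = inputs exist
    task: dict = {}                   # TaskConfig overrides
    exposure: dict = {}               # ExposureStageConfig overrides
    models: dict = {}                 # ModelsConfig overrides

    def task_config(self) -> gaze_io.TaskConfig:
        try:
            return gaze_io.TaskConfig(**self.task)
        except TypeError as exc:
            raise ConfigError(f"bad task config: {exc}") from exc

    def gen_config(self) -> synth.GenConfig:
        try:
            return synth.GenConfig(**(self.simulate or {}))
        except TypeError as exc:
            raise ConfigError(f"bad simulate config: {exc}") from exc

    def exposure_config(self) -> ExposureStageConfig:
        try:
            cfg = ExposureStageConfig(**self.exposure)
            cfg.qc_bounds = tuple(cfg.qc_bounds)  # yaml lists -> tuple
            return cfg
        except TypeError as exc:
            raise ConfigError(f"bad exposure config: {exc}") from exc

    def models_config(self) -> ModelsConfig:
        try:
            return ModelsConfig(**self.models)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad models config: {exc}") from exc


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        cfg = PipelineConfig(**raw)
    except Exception as exc:
        raise ConfigError(str(exc)) from exc
    # validate nested sections eagerly, before any computation
    cfg.task_config(), cfg.exposure_config(), cfg.models_config()
    if cfg.simulate is not None:
        cfg.gen_config()
    return cfg


def _emit_warning(out: Path, stage: str, message: str, **extra) -> None:
    logger.warning("[%s] %s", stage, message)
    rec = {"stage": stage, "message": message, **extra}
    with open(out / "warnings.jsonl", "a") as fh:
        fh.write(json.dumps(rec) + "\n")


def _provenance(cfg: PipelineConfig, out: Path, stage: str) -> None:
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    rec = {
        "stage": stage,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": cfg.seed,
        "gazecog_version": __version__,
    }
    path = out / "provenance.json"
    records = json.loads(path.read_text()) if path.exists() else []
    records.append(rec)
    path.write_text(json.dumps(records, indent=1))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = cfg.gen_config()
    hh = synth.generate_households(gen.n_households, cfg.seed)
    truth = synth.make_truth(hh, gen, cfg.seed)
    aqi = synth.generate_aqi_logs(hh, gen, truth, cfg.seed)
    gaze = synth.generate_gaze_trials(hh, truth, gen, cfg.seed)
    assessments = synth.generate_assessments(hh, truth, cfg.seed)
    synth.write_dataset(out, hh, truth, aqi=aqi, gaze=gaze, assessments=assessments)
    _provenance(cfg, out, "simulate")
    return out


def stage_score(cfg: PipelineConfig) -> Path:
    out = Path(cfg.out_dir)
    task = cfg.task_config()
    samples = gaze_io.read_gaze_csv(out / "gaze_samples.csv")
    trial_table = gaze_io.read_trials_csv(out / "trials.csv")
    et = samples[samples["source"] == "eyetracker"]
    vid = samples[samples["source"] == "video"]
    trials = gaze_io.merge_sources(et, vid, expected_trials=trial_table)
    trials = gaze_io.attach_metadata(trials, trial_table)
    scores, agg, exclusions = looking.score_dataset(trials, task)
    scores.to_csv(out / "trial_scores.csv", index=False)
    agg.to_csv(out / "score_aggregates.csv", index=False)
    for name, count in exclusions.items():
        if name != "n_trials" and count:
            _emit_warning(out, "score", f"{name}: {count} trials", count=count)
    (out / "score_exclusions.json").write_text(json.dumps(exclusions, indent=1))
    _provenance(cfg, out, "score")
    return out


def stage_exposure(cfg: PipelineConfig) -> Path:
    out = Path(cfg.out_dir)
    ecfg = cfg.exposure_config()
    records = pd.read_csv(out / "aqi_log.csv")
    records["timestamp"] = pd.to_datetime(records["timestamp"], utc=True,
                                          format="ISO8601").dt.tz_convert(synth.TZ)
    records, qc_report = airquality.qc_rounds(records, ecfg.min_round_hours)
    dropped = qc_report[~qc_report["retained"]]
    if len(dropped):
        _emit_warning(out, "exposure",
                      f"dropped {len(dropped)} household-rounds below "
                      f"{ecfg.min_round_hours} h coverage", count=len(dropped))
    records, dev_report = airquality.device_plausibility_filter(
        records, ecfg.qc_bounds, ecfg.max_flag_fraction)
    excluded = dev_report[dev_report["excluded"]]
    if len(excluded):
        _emit_warning(out, "exposure",
                      f"retired {excluded['device_id'].nunique()} devices",
                      count=int(len(excluded)))
    hourly = airquality.downsample_hourly(records)
    model = airquality.fit_exposure_model(
        hourly, airquality.ExposureSpec(k_hour=ecfg.k_hour, k_date=ecfg.k_date,
                                        rho=ecfg.rho))
    airquality.extract_exposure(model).to_csv(out / "household_exposure.csv",
                                              index=False)
    qc_report.to_csv(out / "exposure_qc_report.csv", index=False)
    prof = model.diurnal_profile()
    prof.rename_axis("hour").to_csv(out / "diurnal_profile.csv")
    _provenance(cfg, out, "exposure")
    return out


def _analysis_tables(out: Path, unit: str) -> dict[str, pd.DataFrame]:
    scores = pd.read_csv(out / "trial_scores.csv",
                         dtype={"participant_id": str})
    households = pd.read_csv(out / "households.csv", dtype={"household_id": str})
    exposure = pd.read_csv(out / "household_exposure.csv",
                           dtype={"household_id": str})
    lw1 = (scores.dropna(subset=["looking_window1"])
           .groupby(["participant_id", "year"])["looking_window1"]
           .mean().reset_index())

    def enrich(df: pd.DataFrame) -> pd.DataFrame:
        df = df.merge(lw1, on=["participant_id", "year"], how="left")
        df = df.merge(households[["household_id", "ses_score", "cohort"]],
                      left_on="participant_id", right_on="household_id", how="left")
        df = df.merge(exposure[["household_id", "exposure_score"]],
                      on="household_id", how="left")
        return df.rename(columns={"exposure_score": "exposure"})

    if unit == "trials":
        cp_nc = scores[scores["cp_valid"] & (scores["first_look"] == "no_change")]
        cp_nc = cp_nc.rename(columns={"change_preference": "cp"})
        cp_ch = scores[scores["cp_valid"] & (scores["first_look"] == "change")]
        cp_ch = cp_ch.rename(columns={"change_preference": "cp"})
        sr = scores.dropna(subset=["shift_rate"])
    else:
        valid = scores[scores["cp_valid"]]
        key = ["participant_id", "year", "load_level"]
        cp_nc = (valid[valid["first_look"] == "no_change"]
                 .groupby(key)["change_preference"].mean().rename("cp").reset_index())
        cp_ch = (valid[valid["first_look"] == "change"]
                 .groupby(key)["change_preference"].mean().rename("cp").reset_index())
        sr = (scores.dropna(subset=["shift_rate"])
              .groupby(key)["shift_rate"].mean().reset_index())
    return {"cp_no_change": enrich(cp_nc), "cp_change": enrich(cp_ch),
            "shift_rate": enrich(sr)}


def stage_associate(cfg: PipelineConfig) -> Path:
    out = Path(cfg.out_dir)
    mcfg = cfg.models_config()
    tables = _analysis_tables(out, mcfg.analysis_unit)
    exposure = pd.read_csv(out / "household_exposure.csv",
                           dtype={"household_id": str})
    summary: dict[str, dict] = {}
    specs: dict[str, assoc.ModelSpec] = {}
    for outcome in ("cp_no_change", "cp_change", "shift_rate"):
        data, _ = assoc.code_predictors(tables[outcome])
        cands = (mcfg.candidates_shift if outcome == "shift_rate"
                 else mcfg.candidates_cp)
        col = "cp" if outcome.startswith("cp") else "shift_rate"
        spec, base_fit, sel_log = assoc.build_baseline(
            outcome, cands, data, mcfg.alpha)
        aug_fit, comparison = assoc.add_air_quality(spec, exposure, data, mcfg.alpha)
        specs[outcome] = spec
        summary[outcome] = {
            "baseline": base_fit.to_dict(),
            "augmented": aug_fit.to_dict(),
            "selection_log": sel_log,
            "comparison": comparison,
        }
    # robustness analyses on the merged cp/shift cell table
    cp_tab, _ = assoc.code_predictors(tables["cp_no_change"])
    sr_tab, _ = assoc.code_predictors(tables["shift_rate"])
    key = ["participant_id", "year", "load_level"]
    merged = cp_tab.merge(sr_tab[key + ["shift_rate"]], on=key, how="inner")
    merged = merged.merge(
        exposure.rename(columns={"household_id": "participant_id"})
        [["participant_id", "exposure_score"]], on="participant_id", how="inner")
    merged["AQI"] = merged["exposure_score"]
    cp_aug_terms = [t for t in summary["cp_no_change"]["augmented"]["terms"]]
    sr_aug_terms = [t for t in summary["shift_rate"]["augmented"]["terms"]]
    try:
        cp_rob, sr_rob = assoc.robustness_cross_covariate(
            merged,
            assoc.ModelSpec("cp_no_change", cp_aug_terms, True),
            assoc.ModelSpec("shift_rate", sr_aug_terms, True),
        )
        summary["robustness"] = {"cp_with_shift_covariate": cp_rob.to_dict(),
                                 "shift_with_cp_covariate": sr_rob.to_dict()}
    except Exception as exc:  # robustness is reported, never fatal
        _emit_warning(out, "associate", f"cross-covariate robustness failed: {exc}")
    try:
        lm = assoc.load_matched_analysis(merged, mcfg.alpha)
        summary["load_matched"] = lm.to_dict() | {"comparison": lm.comparison}
    except ValueError as exc:
        _emit_warning(out, "associate", f"load-matched analysis skipped: {exc}")
    # assessments
    apath = out / "assessments.csv"
    if apath.exists():
        assessments = pd.read_csv(apath, dtype={"participant_id": str})
        households = pd.read_csv(out / "households.csv",
                                 dtype={"household_id": str})
        adf = assessments.merge(households[["household_id", "ses_score", "cohort"]],
                                left_on="participant_id", right_on="household_id")
        adf = adf.merge(exposure[["household_id", "exposure_score"]],
                        on="household_id")
        adf = adf.rename(columns={"exposure_score": "exposure"})
        adf, _ = assoc.code_predictors(adf)
        fits = assoc.fit_assessment_models(adf, mcfg.alpha)
        summary["assessments"] = {
            m: {k: f.to_dict() for k, f in d.items()} for m, d in fits.items()
        }
    (out / "model_summary.json").write_text(json.dumps(summary, indent=1))
    _provenance(cfg, out, "associate")
    return out


def _fmt_model_table(coef_records: list[dict]) -> list[str]:
    header = ["Variable", "Estimate", "Std. Error", "DF", "t value", "Pr(>|t|)"]
    lines = ["| " + " | ".join(header) + " |",
             "|" + "---|" * len(header)]
    for r in coef_records:
        df = r.get("DF")
        lines.append(
            "| {term} | {est:.3f} | {se} | {df} | {t} | {p} |".format(
                term=r["term"],
                est=r["Estimate"],
                se="" if pd.isna(r.get("Std. Error", np.nan)) else f"{r['Std. Error']:.3f}",
                df="" if df is None or pd.isna(df) else f"{df:.1f}",
                t="" if pd.isna(r.get("t value", np.nan)) else f"{r['t value']:.3f}",
                p="" if pd.isna(r.get("Pr(>|t|)", np.nan)) else f"{r['Pr(>|t|)']:.3g}",
            )
        )
    return lines


def render_report(artifact_dir: str | Path) -> str:
    """Human-readable markdown report over existing pipeline outputs.

    Numbers are read from the output files, never recomputed; absent
    outputs become flagged absent sections rather than errors.
    """
    out = Path(artifact_dir)
    lines = ["# gazecog pipeline report", ""]

    scores_path = out / "trial_scores.csv"
    if scores_path.exists():
        scores = pd.read_csv(scores_path)
        lines += ["## Looking measures", ""]
        cp = (scores[scores["cp_valid"]]
              .groupby("load_level")["change_preference"].mean()
              .reindex(["low", "medium", "high"]))
        lines += ["Change preference by memory load:", "",
                  "| Load | Mean CP |", "|---|---|"]
        lines += [f"| {k} | {v:.3f} |" for k, v in cp.items()]
        sr = (scores.dropna(subset=["shift_rate"])
              .groupby("load_level")["shift_rate"].mean()
              .reindex(["low", "medium", "high"]))
        lines += ["", "Shift rate (shifts/s) by memory load:", "",
                  "| Load | Mean shift rate |", "|---|---|"]
        lines += [f"| {k} | {v:.3f} |" for k, v in sr.items()]
        lines.append("")
    else:
        lines += ["## Looking measures", "", "_Section missing: trial_scores.csv not found._", ""]

    expo_path = out / "household_exposure.csv"
    hh_path = out / "households.csv"
    if expo_path.exists() and hh_path.exists():
        expo = pd.read_csv(expo_path, dtype={"household_id": str})
        hh = pd.read_csv(hh_path, dtype={"household_id": str})
        m = expo.merge(hh[["household_id", "cooking_fuel"]], on="household_id")
        m["aqi_visual"] = m["exposure_score"] + m["grand_mean"]
        lines += ["## Household exposure", "",
                  f"Grand mean AQI: {expo['grand_mean'].iloc[0]:.1f}", "",
                  "Mean AQI (grand-mean scale) by cooking fuel:", "",
                  "| Fuel | Mean AQI | n |", "|---|---|---|"]
        for fuel, g in m.groupby("cooking_fuel"):
            lines.append(f"| {fuel} | {g['aqi_visual'].mean():.1f} | {len(g)} |")
        lines.append("")
    else:
        lines += ["## Household exposure", "",
                  "_Section missing: household_exposure.csv not found._", ""]

    ms_path = out / "model_summary.json"
    if ms_path.exists():
        summary = json.loads(ms_path.read_text())
        lines += ["## Association models", ""]
        for outcome in ("cp_no_change", "cp_change", "shift_rate"):
            if outcome not in summary:
                continue
            for which in ("baseline", "augmented"):
                fit = summary[outcome][which]
                lines += [f"### {outcome} — {which}", ""]
                lines += _fmt_model_table(fit["coefficients"])
                lines.append("")
    else:
        lines += ["## Association models", "",
                  "_Section missing: model_summary.json not found._", ""]
    text = "\n".join(lines)
    (out / "report.md").write_text(text)
    return text


STAGES = {
    "simulate": stage_simulate,
    "score": stage_score,
    "exposure": stage_exposure,
    "associate": stage_associate,
    "report": lambda cfg: render_report(cfg.out_dir),
}


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all stages in order (simulate only when configured)."""
    order = ["score", "exposure", "associate", "report"]
    if cfg.simulate is not None:
        order.insert(0, "simulate")
    for name in order:
        logger.info("running stage %s", name)
        STAGES[name](cfg)
    return Path(cfg.out_dir)
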