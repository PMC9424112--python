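"""End-to-end orchestration: simulate/read -> consensus -> agreement ->
scoring -> survival -> evaluation, assembled into one report bundle.

The bundle (a JSON-serialisable dict) is the single source of truth; every
CSV artefact is regenerated from it, so a report can be rebuilt from the
bundle alone. Configuration is one YAML file; unknown keys are rejected and
every default in force is echoed into the bundle's log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .agreement import agreement_table, report_round
from .cohort import (
    ValidationError,
    cohort_to_frame,
    read_cohort,
    read_ratings,
    write_cohort,
    write_ratings,
)
from .consensus import consensus_profiles
from .evaluation import (
    WHO_ORDINAL,
    augmented_model_auroc,
    auroc,
    compare_auroc,
    event_indicator,
    incidence_table,
    per_rater_evaluation,
)
from .scoring import MODELS, score_cohort
from .simulate import GeneratorConfig, calibration_report, default_config, generate
from .survival import EVENTS, km_fit, univariate_feature_cox

logger = logging.getLogger(__name__)

RISK_HORIZONS = (24.0, 60.0)

_CONFIG_KEYS = {"seed", "generator", "inputs", "min_agree", "strict_followup"}


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage."""


def _load_config(config: str | Path | Mapping[str, Any]) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(config)
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "generator" not in cfg and "inputs" not in cfg:
        raise ValidationError("config needs either 'generator' or 'inputs'")
    return cfg


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _records(frame: pd.DataFrame) -> list[dict]:
    out = frame.replace({np.nan: None}).to_dict(orient="records")
    return out


def run_pipeline(config: str | Path | Mapping[str, Any]) -> dict:
    """Run the whole analysis and return the JSON-serialisable report bundle."""
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    logger.info("pipeline start; seed=%d", seed)

    bundle: dict[str, Any] = {"meta": {"seed": seed, "assumptions": []}}
    note = bundle["meta"]["assumptions"].append

    if "generator" in cfg:
        gen_overrides = dict(cfg.get("generator") or {})
        gen_cfg: GeneratorConfig = default_config(seed, **gen_overrides)
        study = _stage("simulate")(generate)(gen_cfg)
        panel, records = study.panel, study.records
        bundle["calibration"] = _stage("calibration")(calibration_report)(study)
        bundle["meta"]["generator"] = {
            k: v for k, v in dataclasses.asdict(gen_cfg).items() if not isinstance(v, dict)
        }
        note("synthetic study generated; baseline hazards calibrated to target event rates")
    else:
        inputs = cfg["inputs"]
        strict = bool(cfg.get("strict_followup", True))
        panel = _stage("read_ratings")(read_ratings)(inputs["ratings"])
        records = _stage("read_cohort")(read_cohort)(inputs["cohort"], strict_followup=strict)
        note(f"inputs read from files; strict 60-month follow-up rule={'on' if strict else 'off'}")

    frame = cohort_to_frame(records)
    min_agree = cfg.get("min_agree")
    profiles = _stage("consensus")(consensus_profiles)(panel, min_agree)
    note(f"consensus threshold: {'strict majority (default)' if min_agree is None else min_agree}")

    summaries = _stage("agreement")(agreement_table)(panel)
    bundle["agreement"] = [
        {**s.as_dict(), "kappa_2dp": report_round(s.kappa), "ac1_2dp": report_round(s.ac1)}
        for s in summaries
    ]

    bundle["incidence"] = _records(_stage("incidence")(incidence_table)(frame, profiles))

    scores: dict[str, pd.Series] = {}
    bundle["scores"] = {}
    for model in MODELS:
        results, counts = _stage(f"score:{model}")(score_cohort)(profiles, model)
        scores[model] = pd.Series({r.case_id: r.score for r in results}).reindex(frame.index)
        bundle["scores"][model] = {
            "stratum_counts": counts,
            "per_case": [dataclasses.asdict(r) for r in results],
        }

    bundle["cox_univariate"] = _records(
        _stage("cox")(univariate_feature_cox)(frame, profiles)
    )

    bundle["km"] = _stage("km")(_km_section)(frame, profiles)

    bundle["auroc"] = _stage("evaluate")(_auroc_section)(frame, scores)
    bundle["per_rater_auroc"] = _records(
        _stage("per_rater")(per_rater_evaluation)(panel, frame)
    )
    logger.info("pipeline done")
    return bundle


def _km_section(frame: pd.DataFrame, profiles) -> dict:
    """Stratified KM risks at 2 and 5 years plus full curve point sets."""
    section: dict[str, Any] = {"risks": [], "curves": []}
    for model in MODELS:
        results, _ = score_cohort(profiles, model)
        strata = {r.case_id: r.stratum for r in results}
        for event in EVENTS:
            for curve in km_fit(frame, event, strata):
                for horizon in RISK_HORIZONS:
                    section["risks"].append(
                        {
                            "model": model,
                            "event": event,
                            "stratum": curve.stratum,
                            "horizon_months": horizon,
                            "risk": curve.risk_at(horizon),
                            "n": curve.n_subjects,
                            "n_events": curve.n_events,
                            "flagged_no_events": curve.flagged_no_events,
                        }
                    )
                section["curves"].append(
                    {
                        "model": model,
                        "event": event,
                        "stratum": curve.stratum,
                        "points": [
                            {"t": float(t), "s": float(s), "lo": float(lo), "hi": float(hi)}
                            for t, s, lo, hi in zip(
                                curve.times, curve.survival, curve.ci_lower, curve.ci_upper
                            )
                        ],
                    }
                )
    return section


def _auroc_section(frame: pd.DataFrame, scores: Mapping[str, pd.Series]) -> dict:
    """Score, grade, covariate-augmented and comparison AUROCs."""
    grade_predictors = {
        "who_grade": frame["who_grade"].map(WHO_ORDINAL).astype(float),
        "binary_grade": (frame["binary_grade"] == "high").astype(float),
    }
    section: dict[str, Any] = {"models": [], "augmented": [], "comparisons": []}
    for event in EVENTS:
        y = event_indicator(frame, event)
        rocs = {}
        for name, pred in {**scores, **grade_predictors}.items():
            rocs[name] = auroc(pred, y, name, event, frame.index)
            section["models"].append({"predictor": name, "event": event, "auroc": rocs[name].auc})
        for model in scores:
            for covs in (("age", "gender"), ("who_grade",), ("binary_grade",)):
                res = augmented_model_auroc(scores[model], frame, covs, event, predictor=f"{model}+{'+'.join(covs)}")
                section["augmented"].append(
                    {
                        "model": model,
                        "covariates": "+".join(covs),
                        "event": event,
                        "auroc": res.auc,
                        "notes": list(res.notes),
                    }
                )
            for grade in grade_predictors:
                cmp = compare_auroc(rocs[model], rocs[grade])
                section["comparisons"].append(
                    {
                        "model": model,
                        "versus": grade,
                        "event": event,
                        "auc_model": cmp["auc_a"],
                        "auc_versus": cmp["auc_b"],
                        "difference": cmp["difference"],
                        "p": cmp["p"],
                    }
                )
    return section


# ---------------------------------------------------------------------------
# bundle -> artefact files


def bundle_to_tables(bundle: Mapping[str, Any]) -> dict[str, pd.DataFrame]:
    """Regenerate every tabular artefact from the bundle alone."""
    tables = {
        "agreement": pd.DataFrame(bundle["agreement"]),
        "incidence": pd.DataFrame(bundle["incidence"]),
        "cox_univariate": pd.DataFrame(bundle["cox_univariate"]),
        "km_risks": pd.DataFrame(bundle["km"]["risks"]),
        "auroc_models": pd.DataFrame(bundle["auroc"]["models"]),
        "auroc_augmented": pd.DataFrame(bundle["auroc"]["augmented"]),
        "auroc_comparisons": pd.DataFrame(bundle["auroc"]["comparisons"]),
        "per_rater_auroc": pd.DataFrame(bundle["per_rater_auroc"]),
    }
    for model in MODELS:
        tables[f"scores_{model}"] = pd.DataFrame(bundle["scores"][model]["per_case"])
    return tables


def write_report(bundle: Mapping[str, Any], out_dir: str | Path) -> list[Path]:
    """Write bundle.json plus one CSV per table; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = [out / "bundle.json"]
    with open(paths[0], "w") as fh:
        json.dump(bundle, fh, indent=1, default=_jsonify)
    for name, table in bundle_to_tables(bundle).items():
        path = out / f"{name}.csv"
        table.to_csv(path, index=False, na_rep="—")
        paths.append(path)
    return paths


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def write_study(study, out_dir: str | Path) -> dict[str, Path]:
    """Write a synthetic study's ratings.csv, cohort.csv and truth.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ratings": out / "ratings.csv",
        "cohort": out / "cohort.csv",
        "truth": out / "truth.csv",
    }
    write_ratings(study.panel, paths["ratings"])
    write_cohort(study.records, paths["cohort"])
    study.truth.reset_index().to_csv(paths["truth"], index=False)
    return paths
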