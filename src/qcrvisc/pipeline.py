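"""End-to-end orchestration: simulate -> extract -> summarise -> classify -> report.

A run is driven by a plain configuration mapping (usually loaded from YAML)
with three mandatory sections -- ``cohort``, ``stats`` and ``classify`` -- plus
a global ``seed``.  Every stage derives its own seed from the global one via
:func:`qcrvisc.seeding.stage_seed`, so adding a stage never perturbs the
random streams of earlier stages.  All outputs are CSV/JSON files under the
run's output directory, and ``report.json`` collects the run summary; the
same configuration and seed reproduce it byte for byte.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import _version
from .classify import MlpSpec, SplitSpec, run_experiment
from .cohort import default_config, generate_clinical_covariates, generate_cohort, write_manifest
from .reference import verify_reported_accuracies
from .seeding import stage_seed
from .stats import summary_table
from .sweeps import write_feature_table

__all__ = [
    "PipelineConfigError",
    "default_pipeline_config",
    "load_pipeline_config",
    "validate_pipeline_config",
    "run_pipeline",
]

log = logging.getLogger("qcrvisc.pipeline")

REQUIRED_SECTIONS = ("cohort", "stats", "classify")


class PipelineConfigError(ValueError):
    """The pipeline configuration is structurally invalid."""


def default_pipeline_config() -> dict:
    """The full default configuration: both tubes, all scenarios."""
    return {
        "seed": 0,
        "cohort": {
            "tubes": ["edta", "heparin"],
            "overrides": {},
        },
        "stats": {"mode": "per_sample"},
        "classify": {
            "split_mode": "point",
            "balances": ["unbalanced", "balanced"],
            "models": ["mlp", "svm", "rf"],
            "mlp": [
                {"hidden_layers": hl, "epochs": ep}
                for hl in (1, 2)
                for ep in (100, 200, 300)
            ],
        },
    }


def load_pipeline_config(path: str | Path) -> dict:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    validate_pipeline_config(config)
    return config


def validate_pipeline_config(config: dict) -> None:
    """Check the configuration shape before any computation is started."""
    if not isinstance(config, dict):
        raise PipelineConfigError("pipeline configuration must be a mapping")
    missing = [s for s in REQUIRED_SECTIONS if s not in config]
    if missing:
        raise PipelineConfigError(f"missing configuration section(s): {', '.join(missing)}")
    if "seed" not in config or not isinstance(config["seed"], int):
        raise PipelineConfigError("configuration needs an integer 'seed'")
    tubes = config["cohort"].get("tubes", [])
    bad = [t for t in tubes if t not in ("edta", "heparin")]
    if not tubes or bad:
        raise PipelineConfigError(f"cohort.tubes must name edta/heparin tubes, got {tubes!r}")
    if config["stats"].get("mode", "per_sample") not in ("per_sample", "per_point"):
        raise PipelineConfigError("stats.mode must be 'per_sample' or 'per_point'")
    cls = config["classify"]
    for model in cls.get("models", []):
        if model not in ("mlp", "svm", "rf"):
            raise PipelineConfigError(f"unknown model {model!r} in classify.models")
    if cls.get("split_mode", "point") not in ("point", "grouped"):
        raise PipelineConfigError("classify.split_mode must be 'point' or 'grouped'")


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute all stages and return the run report (also written as JSON)."""
    validate_pipeline_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config["seed"]
    report: dict = {
        "software": {"name": "qcrvisc", "version": _version.__version__},
        "config": copy.deepcopy(config),
        "stages": {},
    }

    # -- stage 1: cohort simulation -------------------------------------
    cohorts: dict[str, pd.DataFrame] = {}
    counts = {}
    for tube in config["cohort"]["tubes"]:
        cfg = default_config(
            tube,
            seed=stage_seed(seed, f"cohort:{tube}"),
            **config["cohort"].get("overrides", {}).get(tube, {}),
        )
        rows = generate_clinical_covariates(cfg, generate_cohort(cfg))
        cohorts[tube] = rows
        write_feature_table(out / f"features_{tube}.csv", rows)
        write_manifest(cfg, rows, out / f"manifest_{tube}.json")
        counts[tube] = {
            "rows": int(len(rows)),
            "samples": int(rows["sample_id"].nunique()),
            "rows_per_class": {k: int(v) for k, v in rows["label"].value_counts().items()},
        }
        log.info("simulated %s cohort: %d rows, %d samples", tube, len(rows), counts[tube]["samples"])
    report["stages"]["cohort"] = counts

    # -- stage 2: group statistics --------------------------------------
    stats_mode = config["stats"].get("mode", "per_sample")
    stats_report = {}
    for tube, rows in cohorts.items():
        table = summary_table(rows, mode=stats_mode)
        table.to_csv(out / f"summary_{tube}.csv", index=False)
        stats_report[tube] = {
            r["feature"]: {"auc": round(r["auc"], 4), "p_value": round(r["p_value"], 4)}
            for _, r in table.iterrows()
        }
        log.info("summarised %s cohort (%s mode)", tube, stats_mode)
    report["stages"]["stats"] = stats_report

    # -- stage 3: classification ----------------------------------------
    cls = config["classify"]
    split_mode = cls.get("split_mode", "point")
    grid_records = []
    for tube, rows in cohorts.items():
        for balance_name in cls.get("balances", ["unbalanced"]):
            balance = "none" if balance_name == "unbalanced" else "before_split"
            for model in cls.get("models", ["mlp"]):
                scenarios = cls["mlp"] if model == "mlp" else [None]
                for scen in scenarios:
                    run_seed = stage_seed(
                        seed, f"classify:{tube}:{balance_name}:{model}:{scen}"
                    )
                    mlp_spec = None
                    name = model
                    if model == "mlp":
                        mlp_spec = MlpSpec(
                            hidden_layers=scen["hidden_layers"],
                            epochs=scen["epochs"],
                            seed=run_seed,
                        )
                        name = f"mlp_hl{scen['hidden_layers']}_e{scen['epochs']}"
                    fractions = (0.70, 0.15, 0.15) if model == "mlp" else (0.85, 0.0, 0.15)
                    result = run_experiment(
                        rows,
                        model,
                        mlp_spec=mlp_spec,
                        split=SplitSpec(fractions=fractions, mode=split_mode, seed=run_seed),
                        balance=balance,
                        seed=run_seed,
                    )
                    tag = f"{name}_{tube}_{balance_name}"
                    payload = {
                        "condition": f"{tube}/{balance_name}/{name}",
                        **result["confusion"].as_dict(),
                        "accuracy": result["accuracy"],
                        "accuracy_reported": result["accuracy_reported"],
                        "n_test": result["n_test"],
                    }
                    (out / f"confusion_{tag}.json").write_text(
                        json.dumps(payload, indent=2, sort_keys=True)
                    )
                    if result["history"] is not None:
                        result["history"].to_frame().to_csv(
                            out / f"history_{tag}.csv", index=False
                        )
                    grid_records.append(
                        {
                            "tube": tube,
                            "balance": balance_name,
                            "model": name,
                            "accuracy": result["accuracy"],
                            "accuracy_reported": result["accuracy_reported"],
                        }
                    )
                    log.info("%s: accuracy %.4f", tag, result["accuracy"])
    grid = pd.DataFrame.from_records(grid_records)
    grid.to_csv(out / "accuracy_table.csv", index=False)
    report["stages"]["classify"] = grid_records

    # -- stage 4: reference verification --------------------------------
    verification = verify_reported_accuracies()
    verification.to_csv(out / "verification.csv", index=False)
    report["stages"]["verification"] = {
        "n_scenarios": int(len(verification)),
        "n_matching": int(verification["match"].sum()),
        "inconsistent_totals": verification.loc[
            ~verification["total_consistent"], "condition"
        ].tolist(),
    }

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "config_resolved.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    return report
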