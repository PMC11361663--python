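"""End-to-end orchestration: simulate/load -> weight -> fit -> MC -> evaluate -> requirements.

A `RunConfig` names either an input CSV or simulation parameters, plus the
analysis options; `run_pipeline` executes the stages per mineral, writes
every intermediate table next to the report, and aggregates the results
into a single JSON-serializable run report. Reruns with the same config and
seed are byte-identical for simulated inputs. Attrition counts (parsed ->
scaled -> post-outlier -> CV pairs) are logged at each step.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import balance_data, evaluation, metabolizable, meta_regression, synthetic_data
from .requirements import Scenario, compare_systems

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """One reproducible pipeline run (exactly one input source)."""

    input_csv: str | None = None
    simulation: synthetic_data.SimulationParams | None = None
    minerals: tuple = ("P",)
    trim_factor: float = 0.35
    sed_divisor: str = "half"
    outlier_threshold: float = 2.0
    outlier_max_iter: int = 10
    cv_folds: int = 5
    seed: int = 0
    scenarios: tuple = ()
    out_dir: str = "dairymin_run"

    def validate(self) -> None:
        if (self.input_csv is None) == (self.simulation is None):
            raise ValueError("set exactly one of input_csv / simulation")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "simulation" in raw and raw["simulation"] is not None:
            sim = dict(raw["simulation"])
            mineral = sim.pop("mineral", "P")
            for key in ("treatments_per_study", "intake_range"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            raw["simulation"] = synthetic_data.SimulationParams.for_mineral(
                mineral, **sim)
        if "scenarios" in raw:
            raw["scenarios"] = tuple(Scenario(**s) for s in raw["scenarios"])
        if "minerals" in raw:
            raw["minerals"] = tuple(raw["minerals"])
        return cls(**raw)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


class StageError(RuntimeError):
    def __init__(self, stage, original):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the aggregated report (also written to
    ``report.json`` in the output directory). Stage failures halt the run
    with the stage name; artifacts written so far are preserved."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "minerals": list(config.minerals),
                    "stages": {}, "attrition": {}}

    stage = "load"
    try:
        if config.input_csv is not None:
            records = balance_data.read_dataset(config.input_csv)
            report["input"] = str(config.input_csv)
        else:
            params = dataclasses.replace(config.simulation, seed=config.seed)
            records = synthetic_data.simulate_balance_trials(params)
            balance_data.write_dataset(records, out / "dataset.csv")
            report["input"] = "simulated"
            report["simulation"] = _jsonable(params)
        report["attrition"]["parsed"] = len(records)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, exc) from exc

    for mineral in config.minerals:
        mrep: dict = {}
        subset = records.loc[records["mineral"] == mineral]
        if subset.empty:
            logger.warning("no %s records; skipping mineral", mineral)
            continue
        tag = mineral.lower()

        stage = f"weight[{mineral}]"
        try:
            weights = balance_data.compute_weights(
                subset, trim_factor=config.trim_factor,
                sed_divisor=config.sed_divisor)
            weights.to_csv(out / f"weights_{tag}.csv", index=False)
            obs = balance_data.scale_observations(subset)
            obs = obs.merge(weights[["record_id", "weight"]], on="record_id")
            obs.to_csv(out / f"scaled_{tag}.csv", index=False)
            report["attrition"][f"scaled[{mineral}]"] = len(obs)
        except Exception as exc:
            raise StageError(stage, exc) from exc

        stage = f"fit[{mineral}]"
        try:
            fit = meta_regression.remove_outliers_and_refit(
                obs, threshold=config.outlier_threshold,
                max_iter=config.outlier_max_iter)
            used = obs.loc[~obs["record_id"].isin(fit.removed_ids)]
            het = meta_regression.heterogeneity_index(fit, used)
            mrep["fit"] = _jsonable(fit)
            mrep["heterogeneity"] = _jsonable(het)
            report["attrition"][f"post_outlier[{mineral}]"] = fit.n_used
            (out / f"fit_{tag}.json").write_text(
                json.dumps(_jsonable({"fit": fit, "heterogeneity": het}), indent=2))
        except Exception as exc:
            raise StageError(stage, exc) from exc

        stage = f"mc[{mineral}]"
        try:
            mc_obs = metabolizable.compute_mc(subset, fit)
            mc_obs.to_csv(out / f"mc_{tag}.csv", index=False)
            pvals = metabolizable.screen_all_covariates(mc_obs, weights)
            mc_res = metabolizable.overall_mc(mc_obs, weights, mineral=mineral,
                                              threshold=config.outlier_threshold,
                                              covariate_pvalues=pvals)
            mrep["mc"] = _jsonable(mc_res)
            (out / f"mc_{tag}.json").write_text(
                json.dumps(_jsonable(mc_res), indent=2))
        except Exception as exc:
            raise StageError(stage, exc) from exc

        stage = f"evaluate[{mineral}]"
        try:
            pairs = evaluation.cross_validate(
                obs, k=config.cv_folds, seed=config.seed,
                threshold=config.outlier_threshold,
                max_iter=config.outlier_max_iter)
            pairs.to_csv(out / f"cv_pairs_{tag}.csv", index=False)
            metrics = evaluation.obs_vs_pred_metrics(pairs)
            mrep["cv_metrics"] = _jsonable(metrics)
            report["attrition"][f"cv_pairs[{mineral}]"] = len(pairs)
            (out / f"metrics_{tag}.json").write_text(
                json.dumps(_jsonable(metrics), indent=2))
        except Exception as exc:
            raise StageError(stage, exc) from exc

        stage = f"milk[{mineral}]"
        try:
            milk = evaluation.compare_breed_milk_concentration(subset, mineral)
            mrep["milk_concentration"] = {
                "per_breed": _jsonable(milk["per_breed"].to_dict("records")),
                "verdict": milk["verdict"],
            }
        except Exception as exc:
            raise StageError(stage, exc) from exc

        report["stages"][mineral] = mrep

    if config.scenarios:
        stage = "requirements"
        try:
            blocks = []
            for scenario in config.scenarios:
                comp = compare_systems(scenario)
                blocks.append({
                    "scenario": _jsonable(scenario),
                    "results": {k: _jsonable(v) for k, v in comp["results"].items()},
                    "pct_difference_vs": _jsonable(comp["pct_difference_vs"]),
                })
            report["requirements"] = blocks
            (out / "requirements.json").write_text(json.dumps(blocks, indent=2))
        except Exception as exc:
            raise StageError(stage, exc) from exc

    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2,
                                                sort_keys=True))
    return report
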