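"""End-to-end orchestration of the dual modelling workflow.

Stage order: synthetic (or loaded) climate -> ecoclimatic-index map;
occurrences -> spatial thinning -> pseudo-absence sampling -> predictor
extraction -> collinearity filter -> stratified split -> out-of-bag tuning
-> fit -> held-out evaluation -> probability-map projection.  Every stage
logs its parameters and the SHA-256 of every artifact it writes, so a rerun
with the same config and seed is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import ei_engine, occurrence, rf_pipeline, synthetic
from .errors import ConfigError
from .features import correlation_filter, extract_at_points
from .io import write_ascii_grid

logger = logging.getLogger(__name__)

__all__ = ["load_config", "run_pipeline", "run_rf_workflow", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "scenario": {},            # overrides on SyntheticScenario defaults
    "ei": {"use_pdd": True, "params_file": None},
    "thin": {"radius_km": 10.0},
    "split": {"train_fraction": 0.7},
    "correlation": {"threshold": 0.8},
    "rf": {
        "ntree_grid": list(rf_pipeline.DEFAULT_NTREE_GRID),
        "mtry_grid": list(rf_pipeline.DEFAULT_MTRY_GRID),
        "n_permutations": 10,
    },
}


def load_config(path: str | Path | None) -> dict:
    """Merge a YAML config file over the documented defaults."""
    config = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        user = yaml.safe_load(path.read_text()) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config root must be a mapping, got {type(user).__name__}")
        for section, value in user.items():
            if section not in config:
                raise ConfigError(f"unknown config section {section!r}")
            if isinstance(config[section], dict):
                config[section] = {**config[section], **value}
            else:
                config[section] = value
    return config


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_rf_workflow(scenario, seed: int, thin_radius_km: float = 10.0,
                    train_fraction: float = 0.7, correlation_threshold: float = 0.8,
                    ntree_grid=None, mtry_grid=None, n_permutations: int = 10,
                    importance_on: str = "test") -> dict:
    """In-memory occurrence-to-evaluation workflow on a synthetic scenario.

    Runs generate -> thin -> pseudo-absences -> extraction -> collinearity
    filter -> stratified split -> OOB tuning -> fit -> held-out evaluation,
    without writing artifacts.  ``importance_on`` selects the table used for
    permutation importance: the held-out ``"test"`` rows or ``"all"``
    labelled rows (steadier MDA ranks on small point sets).
    """
    scenario = scenario.with_(rng_seed=seed)
    stack, _, _ = synthetic.generate_stack(scenario)
    raw = synthetic.generate_occurrences(scenario, stack)
    presence = occurrence.thin_occurrences(raw, radius_km=thin_radius_km)
    absences = occurrence.sample_pseudo_absences(raw, stack.geom,
                                                 n=len(presence), rng_seed=seed)
    data = occurrence.make_occurrence_set(
        np.concatenate([presence["lon"], absences["lon"]]),
        np.concatenate([presence["lat"], absences["lat"]]),
        label=np.concatenate([np.ones(len(presence), int),
                              np.zeros(len(absences), int)]))
    table = extract_at_points(stack, data)
    retained = correlation_filter(table.drop(columns="label"),
                                  threshold=correlation_threshold)
    table = table[["label", *retained]]
    split = occurrence.stratified_split(table, train_fraction=train_fraction,
                                        rng_seed=seed)
    config, grid_report = rf_pipeline.tune_rf(
        split.train,
        ntree_grid=ntree_grid or rf_pipeline.DEFAULT_NTREE_GRID,
        mtry_grid=mtry_grid or rf_pipeline.DEFAULT_MTRY_GRID,
        rng_seed=seed)
    model = rf_pipeline.fit_rf(split.train, config)
    oob = float(grid_report.set_index(["ntree", "mtry"])
                .loc[(config.ntree, config.mtry), "oob_error"])
    report = rf_pipeline.evaluate(model, split.test, oob_error=oob,
                                  n_permutations=0)
    report.importance = rf_pipeline.variable_importance(
        model, table if importance_on == "all" else split.test,
        n_permutations=n_permutations, rng_seed=seed)
    return {"report": report, "config": config, "grid_report": grid_report,
            "n_presence_kept": len(presence), "table": table,
            "retained": retained, "model": model, "stack": stack}


def run_pipeline(config: dict, out_dir: str | Path, seed: int | None = None) -> dict:
    """Run every stage and write artifacts under ``out_dir``.

    Returns the run log (also written to ``run_log.json``): per-stage
    parameters, timings, headline metrics and artifact hashes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    log: dict = {"seed": seed, "config": config, "stages": {}, "artifacts": {}}
    t0 = time.time()

    def note(stage: str, **info):
        log["stages"][stage] = info
        logger.info("stage %s: %s", stage, info)

    def save_raster(name: str, array, geom):
        path = out / name
        write_ascii_grid(path, array, geom)
        log["artifacts"][name] = _sha256(path)

    # -- synthetic inputs -------------------------------------------------
    scenario_cfg = dict(config.get("scenario", {}))
    scenario_cfg.setdefault("rng_seed", seed)
    if "occ_slopes" in scenario_cfg:
        scenario_cfg["occ_slopes"] = dict(scenario_cfg["occ_slopes"])
    scenario = synthetic.SyntheticScenario(**scenario_cfg)
    stack, climate, conifer = synthetic.generate_stack(scenario)
    geom = stack.geom
    note("synth", scenario=scenario.to_dict(), n_conifer_cells=int(conifer.sum()))

    # -- ecoclimatic index ------------------------------------------------
    ei_cfg = config.get("ei", {})
    params_file = ei_cfg.get("params_file")
    params = (ei_engine.SpeciesParams.from_file(params_file) if params_file
              else ei_engine.WCSB_PARAMS)
    use_pdd = bool(ei_cfg.get("use_pdd", True))
    ei_out = ei_engine.ei_map(climate, geom, params, use_pdd=use_pdd)
    save_raster("ei.asc", ei_out["ei"], geom)
    save_raster("ei_category.asc", ei_out["category"].astype(float), geom)
    note("ei", use_pdd=use_pdd,
         mean_ei=float(np.nanmean(ei_out["ei"])),
         share_suitable=float((ei_out["ei"] >= 10).mean()))

    # -- occurrences ------------------------------------------------------
    presence_raw = synthetic.generate_occurrences(scenario, stack)
    radius = float(config.get("thin", {}).get("radius_km", 10.0))
    presence = occurrence.thin_occurrences(presence_raw, radius_km=radius)
    note("thin", radius_km=radius, n_raw=len(presence_raw), n_kept=len(presence))

    # any cell holding a raw record counts as "recorded" for the exclusion
    absences = occurrence.sample_pseudo_absences(presence_raw, geom,
                                                 n=len(presence), rng_seed=seed)
    data = occurrence.make_occurrence_set(
        np.concatenate([presence["lon"], absences["lon"]]),
        np.concatenate([presence["lat"], absences["lat"]]),
        label=np.concatenate([np.ones(len(presence), int), np.zeros(len(absences), int)]))
    note("absences", n_presence=len(presence), n_absence=len(absences))

    # -- features ---------------------------------------------------------
    table = extract_at_points(stack, data)
    threshold = float(config.get("correlation", {}).get("threshold", 0.8))
    retained = correlation_filter(table.drop(columns="label"), threshold=threshold)
    table = table[["label", *retained]]
    table.to_csv(out / "features.csv", index=False)
    log["artifacts"]["features.csv"] = _sha256(out / "features.csv")
    note("features", retained=retained, n_rows=len(table),
         n_dropped=table.attrs.get("n_dropped", 0))

    # -- split / tune / fit / evaluate ------------------------------------
    frac = float(config.get("split", {}).get("train_fraction", 0.7))
    split = occurrence.stratified_split(table, train_fraction=frac, rng_seed=seed)
    rf_cfg = config.get("rf", {})
    rf_config, grid_report = rf_pipeline.tune_rf(
        split.train,
        ntree_grid=rf_cfg.get("ntree_grid", rf_pipeline.DEFAULT_NTREE_GRID),
        mtry_grid=rf_cfg.get("mtry_grid", rf_pipeline.DEFAULT_MTRY_GRID),
        rng_seed=seed)
    grid_report.to_csv(out / "tuning_grid.csv", index=False)
    log["artifacts"]["tuning_grid.csv"] = _sha256(out / "tuning_grid.csv")
    model = rf_pipeline.fit_rf(split.train, rf_config)
    oob = float(grid_report.set_index(["ntree", "mtry"])
                .loc[(rf_config.ntree, rf_config.mtry), "oob_error"])
    report = rf_pipeline.evaluate(
        model, split.test, oob_error=oob,
        n_permutations=int(rf_cfg.get("n_permutations", 10)), rng_seed=seed)
    report.to_json(out / "eval_report.json")
    log["artifacts"]["eval_report.json"] = _sha256(out / "eval_report.json")
    report.importance.sort_values("mda", ascending=False).to_csv(out / "importance.csv")
    log["artifacts"]["importance.csv"] = _sha256(out / "importance.csv")
    note("rf", ntree=rf_config.ntree, mtry=rf_config.mtry, oob_error=oob,
         accuracy=report.accuracy, auc=report.auc, tss=report.tss,
         n_train=len(split.train), n_test=len(split.test))

    # -- projection -------------------------------------------------------
    prob = rf_pipeline.project_probability_map(model, stack.subset(retained))
    save_raster("probability.asc", prob, geom)
    note("project", mean_probability=float(np.nanmean(prob)))

    log["runtime_s"] = round(time.time() - t0, 2)
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return log
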