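"""End-to-end orchestration: synthetic study system -> model fitting ->
ensemble consensus -> assemblage metrics -> uncertainty partition ->
optional land-conversion filtering.

Everything is driven by a single :class:`RunConfig` whose defaults encode
the study protocol: six modelling methods, 10 repeated 75/25 stratified
splits, four future climate models under two emission scenarios (so 60
current and 240 future projections per species per scenario), consensus
presence at 50% TSS-weighted frequency.  One master seed is fanned out
into named per-stage streams, so runs are bit-reproducible and adding a
species never perturbs another species' results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as am
from .ensemble import ConsensusMap, ProjectionStack, project_stack, scenario_consensus, weighted_frequency
from .grid import write_ascii_grid, write_surface_csv
from .landuse import (
    FineLandscape,
    estimate_transition,
    fit_conversion_suitability,
    habitat_filter,
    project_landuse,
)
from .sdm import METHODS, cross_validate_species
from .synthetic import derive_bioclim, generate_climate, generate_landuse_pair, generate_virtual_species
from .uncertainty import anova_ss, factor_attribution, uncertainty_map

log = logging.getLogger("ensemblesdm")

__all__ = ["RunConfig", "validate_config", "run_pipeline", "PipelineResult"]


@dataclass
class RunConfig:
    """Resolved run configuration; defaults follow the study protocol."""

    n_rows: int = 20
    n_cols: int = 20
    n_species: int = 5
    methods: tuple[str, ...] = METHODS
    climate_models: tuple[str, ...] = ("GCM1", "GCM2", "GCM3", "GCM4")
    scenarios: tuple[str, ...] = ("A2a", "B2a")
    k_repeats: int = 10
    calib_frac: float = 0.75
    consensus_threshold: float = 0.5
    min_presences: int = 10
    seed: int = 0
    outdir: str | None = None
    # toggles
    threshold_on: str = "validation"  # or "calibration"
    weight_mode: str = "per_layer"  # or "method_mean"
    group_by_method: bool = False
    scenario_statistic: str = "median"
    retention_formula: str = "intersection"  # or "additive"
    anova_mode: str = "three_way"  # or "two_way_per_scenario"
    habitat_filtering: bool = False
    # land-conversion sub-config (used when habitat_filtering is on)
    landuse_block: int = 5  # fine cells per coarse cell side
    native_fraction_t0: float = 0.75
    conversion_rate: float = 0.1
    landuse_steps: int = 7  # e.g. a 6-year interval stepped to mid-century
    min_native_fraction: float = 0.5
    warming_deltas: tuple[float, ...] | None = None
    precip_factors: tuple[float, ...] | None = None
    # virtual-species niche geometry (fractions of each predictor's range)
    niche_sigma_frac: tuple[float, float] = (0.12, 0.3)
    niche_scaling_range: tuple[float, float] = (0.7, 1.0)


_RANGES = {
    "calib_frac": (0.0, 1.0, "exclusive"),
    "consensus_threshold": (0.0, 1.0, "right"),
    "conversion_rate": (0.0, 1.0, "inclusive"),
    "native_fraction_t0": (0.0, 1.0, "inclusive"),
    "min_native_fraction": (0.0, 1.0, "inclusive"),
}


def validate_config(raw) -> RunConfig:
    """Build a RunConfig from a YAML string / dict, injecting defaults.

    Unknown keys and out-of-range values are rejected with the offending
    field named; an empty document yields the full default configuration.
    """
    if raw is None:
        raw = {}
    if isinstance(raw, (str, bytes)):
        raw = yaml.safe_load(raw) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping of field names to values")
    valid = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - valid)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    cfg = RunConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
    for name, (lo, hi, kind) in _RANGES.items():
        v = getattr(cfg, name)
        ok = (
            lo < v < hi
            if kind == "exclusive"
            else (lo < v <= hi if kind == "right" else lo <= v <= hi)
        )
        if not ok:
            raise ValueError(f"{name}={v} out of range ({lo}, {hi}, {kind})")
    bad = [m for m in cfg.methods if m not in METHODS]
    if bad:
        raise ValueError(
            f"unknown methods {bad}; valid tags: {', '.join(METHODS)}"
        )
    if cfg.n_rows < 2 or cfg.n_cols < 2:
        raise ValueError("n_rows/n_cols must be >= 2")
    if cfg.k_repeats < 1:
        raise ValueError("k_repeats must be >= 1")
    if cfg.n_species < 1:
        raise ValueError("n_species must be >= 1")
    return cfg


@dataclass
class PipelineResult:
    """In-memory artefacts of a full run."""

    config: RunConfig
    current_climate: object
    future_climates: list
    species: list
    occurrences: object
    records: dict  # species label -> list[FittedRecord]
    evaluation: pd.DataFrame
    current_stacks: dict[str, ProjectionStack]
    future_stacks: dict[str, dict[str, ProjectionStack]]  # species -> scenario -> stack
    consensus_current: dict[str, ConsensusMap]
    consensus_future_by_scenario: dict[str, dict[str, ConsensusMap]]
    consensus_future: dict[str, ConsensusMap]  # across-scenario consensus
    combo_richness: dict  # (method, model, scenario) -> per-cell future richness
    combo_turnover: dict  # (method, model, scenario) -> per-cell turnover
    assemblage: am.AssemblageMaps
    range_change: am.RangeChangeSummary
    summary_table: pd.DataFrame
    anova_components: dict[str, np.ndarray]
    attribution: dict[str, float]
    uncertainty_percent: np.ndarray
    manifest: dict
    landuse: dict | None = None
    filtered_richness: np.ndarray | None = None


def _combo_consensus(stacks_by_scenario, cfg, method, model, scenario):
    """Consensus over the k repeats of one method x climate model x scenario."""
    stack = stacks_by_scenario[scenario]
    sub = [
        lay for lay in stack.layers
        if lay.method == method and lay.climate_model == model
    ]
    s = ProjectionStack(
        species=stack.species, timeframe="future", grid=stack.grid,
        layers=sub, scenario=scenario,
    )
    return weighted_frequency(
        s, threshold=cfg.consensus_threshold, weight_mode="per_layer",
        on_zero_weights="unweighted",
    )


def run_pipeline(config: RunConfig | dict | str | None = None) -> PipelineResult:
    """Execute every stage and (when ``outdir`` is set) write all surfaces,
    CSV tables and a machine-readable manifest."""
    cfg = config if isinstance(config, RunConfig) else validate_config(config)
    # outdir is run-location metadata, not part of the scientific config;
    # keeping it out makes artefacts byte-comparable across locations
    cfg_record = {k: v for k, v in asdict(cfg).items() if k != "outdir"}
    manifest: dict = {"config": _jsonable(cfg_record), "stages": [], "files": []}

    # --- synthetic study system -------------------------------------------
    log.info("stage synthetic_data: grid %dx%d, %d species", cfg.n_rows, cfg.n_cols, cfg.n_species)
    current_mcf, future_mcfs = generate_climate(
        (cfg.n_rows, cfg.n_cols),
        n_future_models=len(cfg.climate_models),
        n_scenarios=len(cfg.scenarios),
        warming_deltas=cfg.warming_deltas,
        precip_factors=cfg.precip_factors,
        seed=cfg.seed,
        model_labels=list(cfg.climate_models),
        scenario_labels=list(cfg.scenarios),
    )
    current_clim = derive_bioclim(current_mcf)
    future_clims = [derive_bioclim(f, grid=current_clim.grid) for f in future_mcfs]
    species, occ = generate_virtual_species(
        cfg.n_species, current_clim, seed=cfg.seed, min_presences=cfg.min_presences,
        sigma_frac=tuple(cfg.niche_sigma_frac),
        scaling_range=tuple(cfg.niche_scaling_range),
    )
    occ.validate_for_modelling()
    manifest["stages"].append(
        {"stage": "synthetic_data", "n_cells": current_clim.grid.n_cells,
         "n_future_climates": len(future_clims),
         "presences": {sp: int(n) for sp, n in zip(occ.species, occ.values.sum(axis=1))}}
    )

    # --- model fitting under cross-validation -----------------------------
    X = current_clim.matrix()
    records, eval_rows = {}, []
    for i, sp in enumerate(occ.species):
        log.info("stage sdm_engine: species %s", sp)
        recs = cross_validate_species(
            sp, occ.values[i].astype(int), X,
            methods=cfg.methods, k=cfg.k_repeats, calib_frac=cfg.calib_frac,
            seed=cfg.seed, threshold_on=cfg.threshold_on,
        )
        records[sp] = recs
        for r in recs:
            eval_rows.append(
                {"species": sp, "method": r.method, "repeat": r.repeat,
                 "threshold": r.threshold,
                 "sensitivity": r.validation.sensitivity,
                 "specificity": r.validation.specificity,
                 "tss": r.tss}
            )
    evaluation = pd.DataFrame(eval_rows)
    manifest["stages"].append(
        {"stage": "sdm_engine",
         "mean_tss": float(evaluation["tss"].mean()),
         "models_fitted": len(evaluation)}
    )

    # --- projection stacks and consensus ----------------------------------
    current_stacks, future_stacks = {}, {}
    consensus_current, cons_fut_scen, consensus_future = {}, {}, {}
    layer_counts = {}
    for sp in occ.species:
        cur_stack, fut_by_scen = project_stack(records[sp], current_clim, future_clims)
        current_stacks[sp] = cur_stack
        future_stacks[sp] = fut_by_scen
        consensus_current[sp] = weighted_frequency(
            cur_stack, threshold=cfg.consensus_threshold,
            weight_mode=cfg.weight_mode, group_by_method=cfg.group_by_method,
        )
        per_scen = {
            scen: weighted_frequency(
                stack, threshold=cfg.consensus_threshold,
                weight_mode=cfg.weight_mode, group_by_method=cfg.group_by_method,
            )
            for scen, stack in fut_by_scen.items()
        }
        cons_fut_scen[sp] = per_scen
        consensus_future[sp] = scenario_consensus(
            list(per_scen.values()), statistic=cfg.scenario_statistic
        )
        layer_counts[sp] = {
            "current": len(cur_stack),
            **{f"future_{scen}": len(stack) for scen, stack in fut_by_scen.items()},
        }
    manifest["stages"].append({"stage": "ensemble_consensus", "layers": layer_counts})

    # --- per-combination consensus richness & turnover --------------------
    combo_richness, combo_turnover, table_rows = {}, {}, []
    current_method_presence = {}
    for m in cfg.methods:
        pres = []
        for sp in occ.species:
            sub = [lay for lay in current_stacks[sp].layers if lay.method == m]
            s = ProjectionStack(
                species=sp, timeframe="current",
                grid=current_clim.grid, layers=sub,
            )
            pres.append(
                weighted_frequency(
                    s, threshold=cfg.consensus_threshold, on_zero_weights="unweighted"
                ).presence
            )
        current_method_presence[m] = np.stack(pres)
    for scen in cfg.scenarios:
        for m in cfg.methods:
            for g in cfg.climate_models:
                fut = np.stack(
                    [
                        _combo_consensus(future_stacks[sp], cfg, m, g, scen).presence
                        for sp in occ.species
                    ]
                )
                cur = current_method_presence[m]
                G, L = am.gains_losses(cur, fut)
                SR = cur.sum(axis=0)
                T = am.turnover(SR, G, L)
                combo_richness[(m, g, scen)] = fut.sum(axis=0)
                combo_turnover[(m, g, scen)] = T
                rc = am.climate_space_change(cur, fut, species=list(occ.species))
                table_rows.append(
                    {"scenario": scen, "method": m, "climate_model": g,
                     "mean_current_richness": float(SR.mean()),
                     "mean_future_richness": float(fut.sum(axis=0).mean()),
                     "delta": float(SR.mean() - fut.sum(axis=0).mean()),
                     "mean_turnover": float(np.mean(T)),
                     "median_range_change_pct": rc.median_change_pct,
                     "interquartile_deviation": rc.interquartile_deviation}
                )
    summary_table = pd.DataFrame(table_rows)

    # --- grand-consensus assemblage metrics --------------------------------
    cur_maps = [consensus_current[sp] for sp in occ.species]
    fut_maps = [consensus_future[sp] for sp in occ.species]
    assemblage = am.assemblage_maps(cur_maps, fut_maps, retention_formula=cfg.retention_formula)
    range_change = am.climate_space_change(cur_maps, fut_maps, species=list(occ.species))
    mean_turnover_map = np.mean(np.stack(list(combo_turnover.values())), axis=0)
    manifest["stages"].append(
        {"stage": "assemblage_metrics",
         "mean_current_richness": float(assemblage.current_richness.mean()),
         "mean_future_richness": float(assemblage.future_richness.mean()),
         "median_range_change_pct": range_change.median_change_pct}
    )

    # --- uncertainty partition ---------------------------------------------
    n_cells = current_clim.grid.n_cells
    shape = (len(cfg.methods), len(cfg.climate_models), len(cfg.scenarios))
    tables = np.empty(shape + (n_cells,))
    for a, m in enumerate(cfg.methods):
        for b, g in enumerate(cfg.climate_models):
            for c, scen in enumerate(cfg.scenarios):
                tables[a, b, c] = combo_richness[(m, g, scen)]
    # factors with a single level carry no variation and leave the design
    all_names = ["method", "climate_model", "scenario"]
    keep_axes = [a for a in range(3) if tables.shape[a] >= 2]
    factor_names = [all_names[a] for a in keep_axes]
    squeeze = tuple(a for a in range(3) if tables.shape[a] < 2)
    tables = tables.squeeze(axis=squeeze) if squeeze else tables
    if len(factor_names) < 2:
        comps = {"total": np.zeros(n_cells), "residual": np.zeros(n_cells)}
        for name in factor_names:
            comps[name] = np.zeros(n_cells)
        attribution: dict[str, float] = {}
    elif cfg.anova_mode == "two_way_per_scenario" and len(factor_names) == 3:
        comps = {k: np.zeros(n_cells) for k in ["method", "climate_model", "residual", "total"]}
        for c in range(len(cfg.scenarios)):
            for i in range(n_cells):
                ss = anova_ss(tables[:, :, c, i], ["method", "climate_model"])
                for k in comps:
                    comps[k][i] += ss[k]
        attribution = _safe_attribution(comps)
    else:
        comps = {k: np.zeros(n_cells) for k in factor_names + ["residual", "total"]}
        for i in range(n_cells):
            ss = anova_ss(tables[..., i], factor_names)
            for k in comps:
                comps[k][i] = ss[k]
        attribution = _safe_attribution(comps)
    try:
        unc_percent = uncertainty_map(comps["total"])
    except ValueError:
        unc_percent = np.zeros(n_cells)  # forecasts agree everywhere
    manifest["stages"].append({"stage": "uncertainty_partition", "attribution": attribution})

    # --- optional land conversion + habitat filtering ----------------------
    landuse_out, filtered_richness = None, None
    if cfg.habitat_filtering:
        log.info("stage land_conversion")
        fine_dims = (cfg.n_rows * cfg.landuse_block, cfg.n_cols * cfg.landuse_block)
        pair = generate_landuse_pair(
            fine_dims, native_fraction_t0=cfg.native_fraction_t0,
            conversion_rate=cfg.conversion_rate, seed=cfg.seed,
        )
        landscape = FineLandscape(
            landuse=pair.t0, covariates=pair.covariates, block=cfg.landuse_block
        )
        trans = estimate_transition(pair.t0, pair.t1)
        converted = (pair.t0 == 0) & (pair.t1 == 1)
        scores = fit_conversion_suitability(landscape, converted, seed=cfg.seed)
        projected = project_landuse(
            pair.t1, trans, n_steps=cfg.landuse_steps, suitability=scores, seed=cfg.seed
        )
        filt_cur = [
            habitat_filter(consensus_current[sp], pair.t1, landscape, cfg.min_native_fraction)
            for sp in occ.species
        ]
        filt_fut = [
            habitat_filter(consensus_future[sp], projected, landscape, cfg.min_native_fraction)
            for sp in occ.species
        ]
        filtered_richness = am.richness(filt_cur)
        landuse_out = {
            "pair": pair, "landscape": landscape, "transition": trans,
            "suitability": scores, "projected": projected,
            "filtered_current": filt_cur, "filtered_future": filt_fut,
            "filtered_future_richness": am.richness(filt_fut),
        }
        manifest["stages"].append(
            {"stage": "land_conversion",
             "p_native_to_anthropic": trans.prob(0, 1),
             "native_cells_t1": int((pair.t1 == 0).sum()),
             "native_cells_projected": int((projected == 0).sum())}
        )

    result = PipelineResult(
        config=cfg, current_climate=current_clim, future_climates=future_clims,
        species=species, occurrences=occ, records=records, evaluation=evaluation,
        current_stacks=current_stacks, future_stacks=future_stacks,
        consensus_current=consensus_current,
        consensus_future_by_scenario=cons_fut_scen,
        consensus_future=consensus_future,
        combo_richness=combo_richness, combo_turnover=combo_turnover,
        assemblage=assemblage, range_change=range_change,
        summary_table=summary_table, anova_components=comps,
        attribution=attribution, uncertainty_percent=unc_percent,
        manifest=manifest, landuse=landuse_out, filtered_richness=filtered_richness,
    )
    if cfg.outdir:
        _write_outputs(result, mean_turnover_map)
    return result


def _safe_attribution(comps):
    try:
        return factor_attribution(comps)
    except ValueError:  # forecasts agree everywhere: nothing to attribute
        return {}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_outputs(res: PipelineResult, mean_turnover_map: np.ndarray) -> None:
    cfg = res.config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    grid = res.current_climate.grid
    files = res.manifest["files"]

    def save_asc(name, values):
        write_ascii_grid(out / name, grid, values)
        files.append(name)

    (out / "config_resolved.yaml").write_text(
        yaml.safe_dump(_jsonable({k: v for k, v in asdict(cfg).items() if k != "outdir"}))
    )
    files.append("config_resolved.yaml")
    write_surface_csv(
        out / "climate_current.csv", grid,
        {v: res.current_climate.values[v] for v in res.current_climate.values},
    )
    files.append("climate_current.csv")
    res.occurrences.to_csv(out / "occurrences.csv")
    files.append("occurrences.csv")
    res.evaluation.to_csv(out / "evaluation.csv", index=False)
    files.append("evaluation.csv")

    rows = []
    for sp, stack in res.current_stacks.items():
        for lay in stack.layers:
            rows.append({"species": sp, "timeframe": "current", "scenario": "",
                         "method": lay.method, "climate_model": "",
                         "repeat": lay.repeat, "weight": max(lay.tss, 0.0)})
    for sp, by_scen in res.future_stacks.items():
        for scen, stack in by_scen.items():
            for lay in stack.layers:
                rows.append({"species": sp, "timeframe": "future", "scenario": scen,
                             "method": lay.method, "climate_model": lay.climate_model,
                             "repeat": lay.repeat, "weight": max(lay.tss, 0.0)})
    pd.DataFrame(rows).to_csv(out / "stack_manifest.csv", index=False)
    files.append("stack_manifest.csv")

    cons_dir = out / "consensus"
    cons_dir.mkdir(exist_ok=True)
    for sp in res.consensus_current:
        for tag, cmap in [("current", res.consensus_current[sp]),
                          ("future_consensus", res.consensus_future[sp])] + [
                          (f"future_{scen}", m)
                          for scen, m in res.consensus_future_by_scenario[sp].items()]:
            write_ascii_grid(cons_dir / f"{sp}_{tag}_freq.asc", grid, cmap.frequency)
            write_ascii_grid(cons_dir / f"{sp}_{tag}_bin.asc", grid, cmap.presence)
            files.extend([f"consensus/{sp}_{tag}_freq.asc", f"consensus/{sp}_{tag}_bin.asc"])

    save_asc("richness_current.asc", res.assemblage.current_richness)
    save_asc("richness_future.asc", res.assemblage.future_richness)
    save_asc("turnover_consensus.asc", res.assemblage.turnover)
    save_asc("turnover_mean.asc", mean_turnover_map)
    save_asc("retention_percent.asc", res.assemblage.retention_percent)
    save_asc("uncertainty_total_percent.asc", res.uncertainty_percent)
    total = res.anova_components["total"]
    for name, ss in res.anova_components.items():
        if name == "total":
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = np.where(total > 0, 100.0 * ss / total, 0.0)
        save_asc(f"uncertainty_{name}_pct.asc", pct)
    res.summary_table.to_csv(out / "summary_table.csv", index=False)
    files.append("summary_table.csv")
    res.range_change.per_species.to_csv(out / "range_change.csv", index=False)
    files.append("range_change.csv")
    pd.DataFrame([res.attribution]).to_csv(out / "attribution.csv", index=False)
    files.append("attribution.csv")

    if res.landuse is not None:
        res.landuse["transition"].to_csv(out / "transition_matrix.csv")
        files.append("transition_matrix.csv")
        np.savetxt(out / "landuse_projected.txt", res.landuse["projected"], fmt="%d")
        files.append("landuse_projected.txt")
        save_asc("richness_filtered_current.asc", res.filtered_richness)
        save_asc("richness_filtered_future.asc", res.landuse["filtered_future_richness"])

    res.manifest["files"] = sorted(files)
    (out / "manifest.json").write_text(
        json.dumps(_jsonable(res.manifest), indent=2, sort_keys=True)
    )
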