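"""End-to-end orchestration: clean -> thin -> screen -> select -> project -> report.

A single :class:`PipelineConfig` drives every stage; there are no hidden
defaults outside it, and the config (plus seeds) is serialized into the
run directory so any run can be reproduced bit-for-bit.  Stage order:

    load -> clean/thin -> screen -> subset x beta search -> fit best
         -> project current + scenarios -> band -> range metrics -> summaries

Each stage appends a line-delimited JSON log entry; a stage failure
aborts with the stage name while preserving partial outputs.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import model_selection as ms
from . import projection as proj
from . import range_metrics as rm
from .grid_io import LayerStack, read_grid, write_grid
from .maxent_engine import DEFAULT_CLASSES, isolated_gain, sample_background
from .occurrence_prep import (
    OccurrenceSet, dedupe_and_clip, load_occurrences, occurrence_cells, thin_to_grid,
)

DEFAULT_SEEDS = {"background": 11, "thinning": 12, "cv": 13, "simulation": 14}


@dataclass
class PipelineConfig:
    occurrences: str | None = None
    current_stack: dict | None = None      # layer name -> raster path
    scenarios: dict = field(default_factory=dict)
    # tag -> {"horizon": year, "gcms": {gcm name -> {layer -> path}}}
    out_dir: str | None = None
    species: str | None = None
    extent: tuple | None = None            # (lon_min, lat_min, lon_max, lat_max)
    screening_threshold: float = 0.8
    subset_sizes: tuple = ms.DEFAULT_SUBSET_SIZES
    beta_grid: tuple = ms.DEFAULT_BETA_GRID
    background_n: int = 10_000
    transform: str = "cloglog"
    clamp: bool = True
    baseline_year: int = 2010
    feature_classes: tuple = DEFAULT_CLASSES
    hinge_knots: int = 50
    delta_report_cutoff: float = 4.0
    centroid_mode: str = "weighted"
    seeds: dict = field(default_factory=lambda: dict(DEFAULT_SEEDS))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.seeds = {**DEFAULT_SEEDS, **(d.get("seeds") or {})}
        for name in ("subset_sizes", "beta_grid", "feature_classes"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


@dataclass
class PipelineResult:
    config: PipelineConfig
    occurrences: OccurrenceSet
    presence_values: pd.DataFrame
    screened_variables: list
    dropped_pairs: list
    isolated_gains: dict
    candidate_table: pd.DataFrame
    best: ms.CandidateModel
    current_map: object
    scenario_projections: dict
    range_table: pd.DataFrame
    shift_table: pd.DataFrame
    summary: pd.DataFrame
    log: list


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _parse_horizon(tag: str, spec: dict) -> int:
    if "horizon" in spec:
        return int(spec["horizon"])
    for token in tag.replace("-", "_").split("_"):
        if token.isdigit() and len(token) == 4:
            return int(token)
    raise ValueError(f"cannot determine horizon year for scenario {tag!r}")


def run(
    stack: LayerStack,
    occurrences: OccurrenceSet,
    scenario_stacks: dict[str, tuple[int, dict[str, LayerStack]]],
    config: PipelineConfig,
    out_dir: str | None = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs.

    ``scenario_stacks`` maps scenario tag to (horizon_year, {gcm ->
    LayerStack}).  When ``out_dir`` is given, all reports, grids, the
    model file, the config and the log are written there (write-once).
    """
    log: list[dict] = []

    def stage(name):
        log.append({"stage": name, "t": time.time()})

    def guard(name, fn, *a, **kw):
        stage(name)
        try:
            return fn(*a, **kw)
        except Exception as exc:
            log[-1]["error"] = str(exc)
            if out_dir:
                _write_log(out_dir, log)
            raise StageError(name, exc) from exc

    cfg = config
    # --- clean + thin ------------------------------------------------------
    def _clean():
        occ = dedupe_and_clip(occurrences, cfg.extent)
        occ = thin_to_grid(occ, stack.template, seed=cfg.seeds["thinning"])
        return occ

    occ = guard("clean_thin", _clean)
    log[-1]["flag_counts"] = occ.flag_counts()

    def _tables():
        rows, cols = occurrence_cells(occ, stack.template)
        pres = pd.DataFrame(stack.value_table(rows, cols), columns=stack.names)
        bg = sample_background(stack, cfg.background_n, seed=cfg.seeds["background"])
        return pres, bg

    pres, background = guard("extract_values", _tables)

    # --- screening ---------------------------------------------------------
    def _screen():
        gains = {
            v: isolated_gain(stack, pres, background, v, beta=1.0,
                             precision="search")
            for v in stack.names
        }
        retained, dropped = ms.correlation_screen(
            background.values, threshold=cfg.screening_threshold, gains=gains
        )
        return gains, retained, dropped

    gains, screened, dropped = guard("screen", _screen)
    log[-1]["screened_variables"] = screened

    # --- model selection ---------------------------------------------------
    def _search():
        return ms.search_candidates(
            stack, pres, background, screened,
            beta_grid=cfg.beta_grid, subset_sizes=cfg.subset_sizes,
            seed=cfg.seeds["cv"], classes=cfg.feature_classes,
            hinge_knots=cfg.hinge_knots,
            delta_report_cutoff=cfg.delta_report_cutoff,
        )

    table, best, candidates = guard("select", _search)
    log[-1]["n_candidates"] = len(candidates)
    log[-1]["n_subsets"] = len(ms.enumerate_subsets(screened, cfg.subset_sizes))
    log[-1]["beta_grid_size"] = len(cfg.beta_grid)

    # --- projection --------------------------------------------------------
    current_map = guard(
        "project_current", proj.project_current, best.model, stack,
        transform=cfg.transform, clamp=cfg.clamp,
    )
    scenario_projections: dict[str, proj.ScenarioProjection] = {}

    def _project_all():
        for tag, (_, gcms) in scenario_stacks.items():
            scenario_projections[tag] = proj.project_scenario(
                best.model, gcms, transform=cfg.transform, clamp=cfg.clamp,
                scenario_tag=tag,
            )

    guard("project_scenarios", _project_all)

    # --- range metrics -----------------------------------------------------
    def _metrics():
        banded_current = rm.classify_bands(current_map)
        range_rows, shift_rows = [], []
        for tag, (horizon, _) in scenario_stacks.items():
            p = scenario_projections[tag]
            comp = rm.compare_ranges(
                banded_current, rm.classify_bands(p.ensemble),
                horizon_year=horizon, baseline_year=cfg.baseline_year,
                centroid_mode=cfg.centroid_mode,
            )
            row = comp.report_row()
            range_rows.append(
                {"species": occ.species, "scenario": tag, **row,
                 "pct_change_raw": comp.pct_change,
                 "pct_retained_raw": comp.pct_retained,
                 "rate_raw": comp.rate_km_per_decade}
            )
            shift_rows.append(
                {"species": occ.species, "scenario": tag,
                 "shift_km": row["shift_km"], "compass": comp.compass,
                 "rate_km_per_decade": row["rate_km_per_decade"]}
            )
        range_df = pd.DataFrame(range_rows)
        shift_df = pd.DataFrame(shift_rows)
        summary_input = range_df.rename(
            columns={"pct_change_raw": "pc", "pct_retained_raw": "pr",
                     "rate_raw": "rt"}
        )[["species", "pc", "pr", "rt"]].rename(
            columns={"pc": "pct_change", "pr": "pct_retained",
                     "rt": "rate_km_per_decade"}
        )
        summary = rm.summarize_scenarios(summary_input)
        return range_df, shift_df, summary

    range_df, shift_df, summary = guard("metrics", _metrics)

    result = PipelineResult(
        config=cfg, occurrences=occ, presence_values=pres,
        screened_variables=screened, dropped_pairs=dropped,
        isolated_gains=gains, candidate_table=table, best=best,
        current_map=current_map, scenario_projections=scenario_projections,
        range_table=range_df, shift_table=shift_df, summary=summary, log=log,
    )
    if out_dir:
        _write_outputs(result, out_dir)
    return result


def _write_log(out_dir, log):
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "pipeline.log.jsonl"), "w") as fh:
        for entry in log:
            fh.write(json.dumps(entry, default=str) + "\n")


def _write_outputs(result: PipelineResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    cfg_path = os.path.join(out_dir, "config.json")
    if os.path.exists(cfg_path):
        raise FileExistsError(f"run directory {out_dir!r} already holds a run")
    with open(cfg_path, "w") as fh:
        json.dump(asdict(result.config), fh, indent=1, default=str)
    result.candidate_table.to_csv(
        os.path.join(out_dir, "candidates.csv"), index=False
    )
    result.range_table.to_csv(os.path.join(out_dir, "range_table.csv"), index=False)
    result.shift_table.to_csv(os.path.join(out_dir, "shift_table.csv"), index=False)
    result.summary.to_csv(os.path.join(out_dir, "summary.csv"), index=False)
    with open(os.path.join(out_dir, "model.json"), "w") as fh:
        fh.write(result.best.model.to_json())
    write_grid(result.current_map, os.path.join(out_dir, "suitability_current.asc"))
    for tag, p in result.scenario_projections.items():
        write_grid(p.ensemble, os.path.join(out_dir, f"suitability_{tag}.asc"))
    result.occurrences.to_frame().to_csv(
        os.path.join(out_dir, "occurrences_flagged.csv"), index=False
    )
    _write_log(out_dir, result.log)


def load_stack_from_paths(layer_paths: dict[str, str], tag: str = "current") -> LayerStack:
    grids = [read_grid(path, name=name) for name, path in layer_paths.items()]
    from .grid_io import align_stack

    return align_stack(grids, scenario_tag=tag)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Path-based entry point: load all inputs named in the config, run."""
    if config.current_stack is None or config.occurrences is None:
        raise ValueError("config must name occurrences and current_stack paths")
    stack = load_stack_from_paths(config.current_stack)
    occ = load_occurrences(config.occurrences, species=config.species)
    scenario_stacks = {}
    for tag, spec in config.scenarios.items():
        horizon = _parse_horizon(tag, spec)
        gcms = {
            g: load_stack_from_paths(paths, tag=f"{tag}_{g}")
            for g, paths in spec["gcms"].items()
        }
        scenario_stacks[tag] = (horizon, gcms)
    return run(stack, occ, scenario_stacks, config, out_dir=config.out_dir)
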