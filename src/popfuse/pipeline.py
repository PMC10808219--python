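"""End-to-end orchestration: harmonize → screen → fuse → adjust → validate.

A run is fully described by a :class:`RunConfig` (loadable from YAML) and a
master seed; every stochastic stage draws its own seed from the master via a
recorded seed table, so reruns with the same config and seed reproduce all
numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adjust as adjust_mod
from . import fusion, metrics, screening, synthetic
from .grids import COUNT, count_to_density, write_grid, write_zone_map
from .harmonize import ProductStack, build_epoch_stack
from .synthetic import WorldConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one pipeline run; paths may be omitted for synthetic runs."""

    seed: int = 0
    out_dir: str = "popfuse_run"
    years: tuple[int, int] = (1990, 2020)
    # synthetic-world settings (used when no input paths are given)
    synthetic: dict = field(default_factory=dict)
    # clustering
    k: int = 2
    cluster_restarts: int = 50
    # model
    model: str = "auto"          # auto | glm | qrm
    tau: float = 0.5
    folds: int = 10
    restarts: int = 200
    clamp_after_adjust: bool = False
    reference_drift: float = 0.02
    write_rasters: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "years" in raw:
            raw["years"] = tuple(raw["years"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def derive_seeds(master: int) -> dict[str, int]:
    """Fan one master seed out into independent per-stage seeds (< 2^31)."""
    ss = np.random.SeedSequence(master)
    names = ["world", "products", "reference", "cluster", "cv"]
    children = ss.spawn(len(names))
    return {name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(names, children)}


@dataclass
class PipelineResult:
    config: RunConfig
    world: synthetic.World
    stack: ProductStack
    validity: pd.DataFrame
    coefficients: dict[int, fusion.FusionCoefficients]
    fused: dict[int, object]            # year -> adjusted PopulationGrid
    fused_raw: dict[int, object]        # year -> pre-adjustment grid
    factors: pd.DataFrame
    report: metrics.ValidationReport
    designs: dict[int, fusion.DesignMatrix]
    manifest: dict
    planted_validity: pd.DataFrame | None = None


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None
                 ) -> PipelineResult:
    """Execute the full fusion pipeline on a synthetic world and write outputs."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed)
    timings: dict[str, float] = {}

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timings[stage] = round(time.perf_counter() - self.t0, 3)
        return _T()

    # --- synthetic world + harmonized product stack -------------------------
    with timed("world"):
        syn = dict(config.synthetic)
        syn.setdefault("seed", seeds["world"])
        if "years" not in syn:
            syn["years"] = tuple(config.years)
        if "product_specs" in syn:
            syn["product_specs"] = [synthetic.ProductSpec(**p)
                                    for p in syn["product_specs"]]
        wc = WorldConfig(**syn)
        world = synthetic.make_world(wc)
        products, planted_validity = synthetic.make_products(world)
        reference = synthetic.make_reference_totals(
            world, drift=config.reference_drift, seed=seeds["reference"])
    with timed("harmonize"):
        epoch_table = _epoch_table_from_specs(wc, config.years)
        stack = build_epoch_stack(products, epoch_table, years=wc.year_list)

    # --- reliability screening ----------------------------------------------
    with timed("screen"):
        metric_frames = []
        zonal_cache: dict[tuple[str, int], pd.Series] = {}
        for year in stack.years:
            ref = world.census.totals_for_year(year)
            sums = {}
            for pid in stack.products_for_year(year):
                sums[pid] = _zonal_cached(zonal_cache, (pid, year), stack, world)
            metric_frames.append(screening.error_metric_table(ref, sums, year))
        metric_table = pd.concat(metric_frames, ignore_index=True)
        validity = screening.flag_validity(metric_table, k=config.k,
                                           seed=seeds["cluster"],
                                           restarts=config.cluster_restarts)
        validity.to_csv(out / "validity.csv", index=False)
        screening.count_valid_products(validity).to_csv(
            out / "valid_product_counts.csv", index=False)

    # --- per-year fusion ------------------------------------------------------
    with timed("fuse"):
        coefficients: dict[int, fusion.FusionCoefficients] = {}
        designs: dict[int, fusion.DesignMatrix] = {}
        fused_raw: dict[int, object] = {}
        for year in stack.years:
            pids = stack.products_for_year(year)
            sums = {pid: zonal_cache[(pid, year)] for pid in pids}
            design = fusion.build_design(sums, world.census, validity, year,
                                         products=pids)
            designs[year] = design
            chosen = _fit_year(design, config, seeds["cv"])
            coefficients[year] = chosen
            fused_raw[year] = fusion.predict_pixels(stack, chosen, year)
        with open(out / "coefficients.json", "w") as fh:
            json.dump({str(y): c.to_dict() for y, c in coefficients.items()},
                      fh, indent=2)

    # --- adjustment -----------------------------------------------------------
    with timed("adjust"):
        fused: dict[int, object] = {}
        factor_frames = []
        for year in stack.years:
            ref = reference.totals_for_year(year)
            adjusted, factors, _ = adjust_mod.adjust_to_reference(
                fused_raw[year], world.zones, ref, year,
                clamp_after_adjust=config.clamp_after_adjust)
            fused[year] = adjusted
            factor_frames.append(factors)
        factors = pd.concat(factor_frames, ignore_index=True)
        factors.to_csv(out / "adjustment_factors.csv", index=False)

    # --- validation -----------------------------------------------------------
    with timed("validate"):
        baselines: dict[str, dict[int, object]] = {"median_composite": {}}
        for year in stack.years:
            baselines["median_composite"][year] = fusion.median_composite(stack, year)
        for spec in wc.product_specs:
            grids = {y: stack.grid(spec.product_id, y) for y in stack.years
                     if spec.product_id in stack.products_for_year(y)}
            if grids:
                baselines[spec.product_id] = grids
        report = metrics.validation_report(
            fused, world.census, world.zones, baselines=baselines,
            level2_zones=world.zones_level2, level2_census=world.census_level2)
        report.to_csv(out / "validation_report.csv")
        report.dtw.to_csv(out / "dtw_distances.csv", index=False)

    # --- raster outputs + manifest --------------------------------------------
    with timed("write"):
        if config.write_rasters:
            raster_dir = out / "rasters"
            for year, grid in fused.items():
                write_grid(grid, raster_dir, dtype="I32")
                density = count_to_density(grid, world.area)
                write_grid(density, raster_dir, dtype="F32")
            write_zone_map(world.zones, raster_dir, stem="zones_level0")

    manifest = {
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "years": list(stack.years),
        "n_countries": wc.n_countries,
        "stage_seconds": timings,
        "outputs": sorted({p.name for p in out.iterdir()} | {"manifest.json"}),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return PipelineResult(config=config, world=world, stack=stack,
                          validity=validity, coefficients=coefficients,
                          fused=fused, fused_raw=fused_raw, factors=factors,
                          report=report, designs=designs, manifest=manifest,
                          planted_validity=planted_validity)


def _zonal_cached(cache, key, stack, world):
    if key not in cache:
        from .grids import zonal_sum
        cache[key] = zonal_sum(stack.grid(*key), world.zones)
    return cache[key]


def _epoch_table_from_specs(wc: WorldConfig, years) -> dict[int, list[str]]:
    """Epoch membership induced by product cadences: a product participates in
    a year when that year lies within (or is bracketed by) its native span."""
    table: dict[int, list[str]] = {}
    for year in wc.year_list:
        pids = []
        for spec in wc.product_specs:
            native = sorted(spec.native_years)
            if len(native) >= 2 and native[0] <= year <= native[-1]:
                pids.append(spec.product_id)
            elif year in native:
                pids.append(spec.product_id)
        if not pids:
            raise ValueError(f"no product covers year {year}")
        table[year] = pids
    return table


def _fit_year(design: fusion.DesignMatrix, config: RunConfig,
              cv_seed: int) -> fusion.FusionCoefficients:
    seed = int((cv_seed + design.year) % (2**31))
    if config.model.lower() == "glm":
        return fusion.cross_validate(design, model="GLM", folds=min(config.folds,
                                     len(design.y_train)), restarts=config.restarts,
                                     seed=seed)
    qrm = fusion.cross_validate(design, model="QRM",
                                folds=min(config.folds, len(design.y_train)),
                                restarts=config.restarts, seed=seed, tau=config.tau)
    if config.model.lower() == "qrm":
        return qrm
    glm = fusion.cross_validate(design, model="GLM",
                                folds=min(config.folds, len(design.y_train)),
                                restarts=config.restarts, seed=seed)
    return fusion.select_model(glm, qrm, design)
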