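"""Self-contained synthetic study system: truth surfaces, census, product suite.

The generator emulates the study conditions the fusion pipeline is built for:
a world of contiguous countries on a regular geographic lattice, a smooth
city-kernel truth population evolving by country-specific exponential growth,
an exact census derived from the truth, and a suite of gridded "products"
that each distort the truth with a distinct, recognizable error structure —
admin-uniform smearing, built-up reallocation, urban blooming, ambient
redistribution, covariate resmoothing — plus multiplicative country-level
bias planted in a known fraction of (country, product) pairs and lognormal
pixel noise everywhere.  The planted bias table is the ground truth for the
reliability-screening stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import (COUNT, AreaGrid, GridGeometry, PopulationGrid, ZoneMap,
                    pixel_area, zonal_sum)
from .harmonize import CensusTable

DISTORTIONS = ("identity", "zone_uniform", "builtup_realloc", "urban_bloom",
               "ambient_shift", "covariate_resmooth")


@dataclass
class ProductSpec:
    product_id: str
    native_years: list[int]
    distortion: str = "zone_uniform"

    def __post_init__(self) -> None:
        if self.distortion not in DISTORTIONS:
            raise ValueError(f"unknown distortion {self.distortion!r}; "
                             f"choose from {DISTORTIONS}")


def default_product_specs() -> list[ProductSpec]:
    """Five products mirroring the real suite's cadence and bias caricatures."""
    return [
        ProductSpec("GHS-POP", [1990, 1995, 2000], "builtup_realloc"),
        ProductSpec("GRUMP", [1990, 1995, 2000], "urban_bloom"),
        ProductSpec("GPWv4", [1990, 1995, 2000, 2005, 2010, 2015, 2020],
                    "zone_uniform"),
        ProductSpec("LandScan", list(range(2000, 2021)), "ambient_shift"),
        ProductSpec("WorldPop", list(range(2000, 2021)), "covariate_resmooth"),
    ]


@dataclass
class WorldConfig:
    """Everything that defines one synthetic world; the seed is mandatory."""

    seed: int
    shape: tuple[int, int] = (60, 120)       # rows x cols
    bbox: tuple[float, float, float, float] = (-60.0, -30.0, 60.0, 30.0)  # W,S,E,N
    n_countries: int = 20
    n_cities: int = 3
    years: tuple[int, int] = (1990, 2020)
    growth_range: tuple[float, float] = (-0.01, 0.03)  # per-year fractional
    product_specs: list[ProductSpec] = field(default_factory=default_product_specs)
    bias_fraction: float = 0.2
    bias_magnitude: float = 3.0
    noise_sigma: float = 0.05                # lognormal sigma of pixel noise
    rural_floor: float = 2.0                 # people per rural pixel, base year
    mean_city_pop: float = 2.0e5

    def __post_init__(self) -> None:
        if not 0 <= self.bias_fraction <= 1:
            raise ValueError("bias_fraction must lie in [0, 1]")
        if self.bias_magnitude <= 1:
            raise ValueError("bias_magnitude must exceed 1")
        rows, cols = self.shape
        if self.n_countries > rows * cols // 16:
            raise ValueError("n_countries exceeds grid capacity")

    @property
    def geometry(self) -> GridGeometry:
        west, south, east, north = self.bbox
        rows, cols = self.shape
        return GridGeometry(west=west, north=north, dx=(east - west) / cols,
                            dy=(north - south) / rows)

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


@dataclass
class World:
    config: WorldConfig
    zones: ZoneMap
    zones_level2: ZoneMap
    area: AreaGrid
    truth: dict[int, PopulationGrid]
    census: CensusTable
    census_level2: CensusTable
    growth_rates: pd.Series  # per country


def _country_codes(n: int) -> list[str]:
    return [f"C{i:03d}" for i in range(1, n + 1)]


def make_world(config: WorldConfig) -> World:
    """Generate zones, areas, annual truth surfaces and exact census tables.

    Countries are Voronoi patches around random seed cells; the base-year
    truth is a sum of Gaussian city kernels over a low rural floor, scaled
    per year by each country's exponential growth rate; the census is the
    exact zonal sum of the truth at level-0 and a 4-quadrant level-2 split.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.shape
    geometry = config.geometry
    codes = _country_codes(config.n_countries)

    # Voronoi countries around distinct random seed cells
    seeds_r = rng.uniform(0, rows, size=config.n_countries)
    seeds_c = rng.uniform(0, cols, size=config.n_countries)
    rr, cc = np.indices((rows, cols))
    d2 = ((rr[None] - seeds_r[:, None, None]) ** 2
          + (cc[None] - seeds_c[:, None, None]) ** 2)
    labels = np.argmin(d2, axis=0) + 1
    zones = ZoneMap(labels=labels, geometry=geometry, level="level0",
                    code_lookup={i + 1: codes[i] for i in range(config.n_countries)})

    # Level-2: four quadrants around each country's centroid
    labels2 = np.zeros_like(labels)
    lookup2: dict[int, str] = {}
    for i, code in enumerate(codes):
        inside = labels == i + 1
        cr, ccol = rr[inside].mean(), cc[inside].mean()
        quadrant = (rr >= cr).astype(int) * 2 + (cc >= ccol).astype(int)
        for q in range(4):
            lab = i * 4 + q + 1
            cells = inside & (quadrant == q)
            if cells.any():
                labels2[cells] = lab
                lookup2[lab] = f"{code}-{q + 1}"
    zones_level2 = ZoneMap(labels=labels2, geometry=geometry, level="level2",
                           code_lookup=lookup2)

    area = pixel_area(geometry, rows, cols)

    # Base-year truth: Gaussian city kernels + rural floor
    base = np.full((rows, cols), config.rural_floor)
    for i in range(config.n_countries):
        inside = labels == i + 1
        idx = np.flatnonzero(inside)
        centers = rng.choice(idx, size=min(config.n_cities, idx.size), replace=False)
        for center in centers:
            r0, c0 = divmod(center, cols)
            sigma = rng.uniform(1.0, 3.0)
            amp = rng.lognormal(mean=np.log(config.mean_city_pop), sigma=0.5)
            kernel = np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))
            base += amp * kernel / kernel.sum()

    lo, hi = config.growth_range
    growth = pd.Series(rng.uniform(lo, hi, size=config.n_countries), index=codes)

    # truth is also needed at product native years outside the run range,
    # so gap-filling always has its knots
    y0, y1 = config.years
    native_years = {y for spec in config.product_specs for y in spec.native_years}
    truth: dict[int, PopulationGrid] = {}
    factor_grid_cache = {code: growth[code] for code in codes}
    for year in sorted(set(config.year_list) | native_years):
        factors = np.ones((rows, cols))
        for i, code in enumerate(codes):
            factors[labels == i + 1] = (1.0 + factor_grid_cache[code]) ** (year - y0)
        truth[year] = PopulationGrid(values=base * factors, geometry=geometry,
                                     unit=COUNT, year=year, product_id="truth")

    census = CensusTable(records=_census_records(truth, zones), level="level0",
                         source_tag="synthetic-truth")
    census2 = CensusTable(records=_census_records(truth, zones_level2),
                          level="level2", source_tag="synthetic-truth")
    return World(config=config, zones=zones, zones_level2=zones_level2, area=area,
                 truth=truth, census=census, census_level2=census2,
                 growth_rates=growth)


def _census_records(truth: dict[int, PopulationGrid], zones: ZoneMap) -> pd.DataFrame:
    rows = []
    for year, grid in sorted(truth.items()):
        for code, total in zonal_sum(grid, zones).items():
            rows.append({"unit_code": code, "year": year, "population": total})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Product distortions
# ---------------------------------------------------------------------------

def _distort(values: np.ndarray, distortion: str, zones: ZoneMap,
             rng: np.random.Generator) -> np.ndarray:
    labels = zones.labels
    if distortion == "identity":
        return values.copy()
    if distortion == "zone_uniform":
        # admin-uniform smearing: country totals spread evenly over the country
        out = np.zeros_like(values)
        for label in np.unique(labels):
            if label == 0:
                continue
            inside = labels == label
            out[inside] = values[inside].sum() / inside.sum()
        return out
    if distortion == "builtup_realloc":
        # reallocate country totals proportionally to a built-up proxy
        proxy = values**0.7
        out = np.zeros_like(values)
        for label in np.unique(labels):
            if label == 0:
                continue
            inside = labels == label
            w = proxy[inside]
            out[inside] = values[inside].sum() * w / w.sum()
        return out
    if distortion == "urban_bloom":
        # nighttime-lights-style blooming: urban mass dilated, rural undercounted
        urban = values > np.percentile(values, 90)
        bloomed = gaussian_filter(np.where(urban, values, 0.0), sigma=1.5)
        return bloomed + np.where(urban, 0.0, 0.7 * values)
    if distortion == "ambient_shift":
        # ambient population drawn toward a smoothed daytime kernel
        return 0.5 * values + 0.5 * gaussian_filter(values, sigma=2.0)
    if distortion == "covariate_resmooth":
        # regression-style resmoothing capped at the observed input range
        sm = gaussian_filter(values, sigma=1.0)
        return np.clip(sm, values.min(), values.max())
    raise ValueError(f"unknown distortion {distortion!r}")


def make_products(world: World, config: WorldConfig | None = None
                  ) -> tuple[dict[tuple[str, int], PopulationGrid], pd.DataFrame]:
    """Distorted native-year product grids plus the planted validity table.

    Each product applies its distortion operator to the truth at its native
    years, multiplies the planted-bias countries by the configured magnitude,
    and adds multiplicative lognormal pixel noise.  The returned validity
    table has valid = False exactly at the planted (country, product) pairs,
    for every year the product participates in.
    """
    config = config or world.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    codes = world.census.unit_codes
    labels = world.zones.labels

    # Reserve a clean core of countries no product is ever biased in, so a
    # training set (all products reliable) exists in every year by design.
    n_biased = int(round(config.bias_fraction * len(codes)))
    n_core = min(len(codes) - n_biased,
                 max(len(config.product_specs) + 3,
                     int(np.ceil(0.3 * len(codes)))))
    core = set(rng.choice(codes, size=n_core, replace=False))
    biasable = sorted(set(codes) - core)
    planted: dict[str, set[str]] = {}
    for spec in config.product_specs:
        biased = rng.choice(biasable, size=min(n_biased, len(biasable)),
                            replace=False)
        planted[spec.product_id] = set(biased)

    grids: dict[tuple[str, int], PopulationGrid] = {}
    validity_rows = []
    for spec in config.product_specs:
        bias_mask = np.zeros_like(labels, dtype=bool)
        for code in planted[spec.product_id]:
            bias_mask |= labels == world.zones.label_of(code)
        for year in spec.native_years:
            if year not in world.truth:
                continue
            values = world.truth[year].values.copy()
            values = _distort(values, spec.distortion, world.zones, rng)
            values = np.where(bias_mask, values * config.bias_magnitude, values)
            if config.noise_sigma > 0:
                values *= rng.lognormal(mean=0.0, sigma=config.noise_sigma,
                                        size=values.shape)
            grids[(spec.product_id, year)] = PopulationGrid(
                values=values, geometry=world.config.geometry, unit=COUNT,
                year=year, product_id=spec.product_id)
        for year in world.config.year_list:
            for code in codes:
                validity_rows.append({
                    "unit_code": code, "product_id": spec.product_id,
                    "year": year,
                    "valid": code not in planted[spec.product_id]})
    return grids, pd.DataFrame(validity_rows)


def make_reference_totals(world: World, drift: float = 0.02,
                          seed: int | None = None) -> CensusTable:
    """UN-style reference totals: truth totals with a signed per-country drift.

    A nonzero drift makes the adjustment factors non-trivial and known, so
    the conservation property is exercised rather than vacuous.
    """
    if drift < 0:
        raise ValueError("drift must be non-negative")
    rng = np.random.default_rng(
        np.random.SeedSequence([seed if seed is not None else world.config.seed, 11]))
    codes = world.census.unit_codes
    signs = rng.choice([-1.0, 1.0], size=len(codes))
    factor = pd.Series(1.0 + signs * drift, index=codes)
    records = world.census.records.copy()
    records["population"] = [
        pop * factor[code]
        for code, pop in zip(records["unit_code"], records["population"])
    ]
    return CensusTable(records=records, level="level0", source_tag="synthetic-reference")
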