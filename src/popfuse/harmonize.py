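"""Census standardization, pixel-level linear gap-filling, and epoch stacks.

Product rasters are released at 5- or 10-year cadence; the fusion model needs
every covariate at every target year.  Missing years are filled per pixel by
linear interpolation between the bracketing native-year knots, and by linear
extrapolation from the two nearest knots outside the native range.  Negative
extrapolated values are retained here — clamping belongs to the adjustment
stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import PopulationGrid, require_aligned

#: Epoch membership used for the published five-product configuration:
#: three long-series products before 2000, all five in 2000, three after.
DEFAULT_EPOCHS = {
    "pre2000": ["GHS-POP", "GRUMP", "GPWv4"],
    "y2000": ["GHS-POP", "GRUMP", "GPWv4", "LandScan", "WorldPop"],
    "post2000": ["GPWv4", "LandScan", "WorldPop"],
}


def default_epoch_table(years=range(1990, 2021)) -> dict[int, list[str]]:
    table = {}
    for year in years:
        if year < 2000:
            table[year] = list(DEFAULT_EPOCHS["pre2000"])
        elif year == 2000:
            table[year] = list(DEFAULT_EPOCHS["y2000"])
        else:
            table[year] = list(DEFAULT_EPOCHS["post2000"])
    return table


@dataclass
class CensusTable:
    """Admin-unit population counts per year (the regression/validation reference)."""

    records: pd.DataFrame  # columns: unit_code, year, population
    level: str = "level0"
    source_tag: str = ""

    def __post_init__(self) -> None:
        required = {"unit_code", "year", "population"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"census table missing columns: {sorted(missing)}")
        df = self.records
        if (df["population"] < 0).any():
            bad = df.loc[df["population"] < 0, "unit_code"].tolist()
            raise ValueError(f"negative population for units: {bad}")
        dups = df.duplicated(subset=["unit_code", "year"])
        if dups.any():
            pairs = df.loc[dups, ["unit_code", "year"]].itertuples(index=False)
            raise ValueError(
                "duplicate (unit_code, year) pairs: "
                + ", ".join(f"({c}, {y})" for c, y in pairs)
            )

    def totals_for_year(self, year: int) -> pd.Series:
        sub = self.records[self.records["year"] == year]
        return pd.Series(sub["population"].to_numpy(dtype=float),
                         index=sub["unit_code"].to_numpy(), name=str(year))

    def get(self, unit_code: str, year: int) -> float:
        s = self.totals_for_year(year)
        return float(s[unit_code])

    @property
    def unit_codes(self) -> list[str]:
        return sorted(self.records["unit_code"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.records["year"].unique())

    @classmethod
    def from_csv(cls, path, level: str = "level0", source_tag: str = "") -> "CensusTable":
        df = pd.read_csv(path, dtype={"unit_code": str})
        return cls(records=df, level=level, source_tag=source_tag)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def match_census(raw: pd.DataFrame, exclusion_list=(), level: str = "level0",
                 source_tag: str = "") -> tuple[CensusTable, dict]:
    """Drop excluded unit codes and validate the remaining census records.

    Returns the cleaned table plus a report listing the dropped codes.
    Duplicated (code, year) pairs or negative populations raise.
    """
    required = {"unit_code", "year", "population"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"raw census table missing columns: {sorted(missing)}")
    excluded = sorted(set(exclusion_list) & set(raw["unit_code"]))
    kept = raw[~raw["unit_code"].isin(set(exclusion_list))].copy()
    table = CensusTable(records=kept.reset_index(drop=True), level=level,
                        source_tag=source_tag)
    report = {"dropped_codes": excluded,
              "n_units_retained": len(table.unit_codes)}
    return table, report


# ---------------------------------------------------------------------------
# Linear gap-filling
# ---------------------------------------------------------------------------

def linear_gapfill(knots: list[tuple[float, np.ndarray | float]],
                   targets: list[float]) -> list[np.ndarray | float]:
    """Fill target times from knot (time, value) pairs by piecewise linear rules.

    For a target inside the knot range, the bracketing pair (t1, y1), (t2, y2)
    gives y = y1 + (y2 - y1)(t - t1)/(t2 - t1); outside the range, the two
    knots nearest that side define the extrapolating line.  Values may be
    scalars or aligned arrays (per-pixel application over whole grids), and may
    go negative — downstream adjustment clamps.
    """
    if len(knots) < 2:
        raise ValueError("gap-filling needs at least two knots")
    times = np.array([t for t, _ in knots], dtype=float)
    if len(np.unique(times)) != len(times):
        raise ValueError("duplicate knot times")
    order = np.argsort(times)
    times = times[order]
    values = [np.asarray(knots[i][1], dtype=float) for i in order]

    out = []
    for t in targets:
        # bracketing pair when interior; the two edge knots when exterior
        j = int(np.searchsorted(times, t))
        if j <= 0:
            i1, i2 = 0, 1
        elif j >= len(times):
            i1, i2 = len(times) - 2, len(times) - 1
        else:
            i1, i2 = j - 1, j
        t1, t2 = times[i1], times[i2]
        y1, y2 = values[i1], values[i2]
        out.append(y1 + (y2 - y1) * ((t - t1) / (t2 - t1)))
    return out


@dataclass
class ProductStack:
    """All fusion covariates: (product, year) -> aligned count grid, plus the epoch table."""

    grids: dict[tuple[str, int], PopulationGrid]
    epoch_table: dict[int, list[str]] = field(default_factory=dict)

    def grid(self, product_id: str, year: int) -> PopulationGrid:
        return self.grids[(product_id, year)]

    def products_for_year(self, year: int) -> list[str]:
        return list(self.epoch_table[year])

    def grids_for_year(self, year: int) -> list[PopulationGrid]:
        return [self.grids[(p, year)] for p in self.epoch_table[year]]

    @property
    def years(self) -> list[int]:
        return sorted(self.epoch_table)


def build_epoch_stack(available: dict[tuple[str, int], PopulationGrid],
                      epoch_table: dict[int, list[str]] | None = None,
                      years=range(1990, 2021)) -> ProductStack:
    """Gap-fill native-year product grids into a complete per-year stack.

    ``available`` maps (product_id, native year) to aligned count grids.  Every
    (product, year) demanded by the epoch table is produced, native grids kept
    verbatim, the rest filled per pixel with :func:`linear_gapfill`.  A pixel
    that is nodata in any knot year is nodata in all filled years for that
    product — interpolation must not fabricate populated cells.
    """
    if epoch_table is None:
        epoch_table = default_epoch_table(years)
    if any(len(products) == 0 for products in epoch_table.values()):
        empty = [y for y, p in epoch_table.items() if not p]
        raise ValueError(f"years with no covariate products: {empty}")
    grids_by_product: dict[str, dict[int, PopulationGrid]] = {}
    for (pid, year), grid in available.items():
        grids_by_product.setdefault(pid, {})[year] = grid

    out: dict[tuple[str, int], PopulationGrid] = {}
    for pid, native in grids_by_product.items():
        require_aligned(*native.values())
    for year, products in epoch_table.items():
        for pid in products:
            native = grids_by_product.get(pid, {})
            if year in native:
                out[(pid, year)] = native[year]
                continue
            if len(native) < 2:
                raise ValueError(
                    f"cannot derive ({pid}, {year}): fewer than two native years available"
                )
            knot_years = sorted(native)
            stack = np.stack([native[y].values for y in knot_years])
            bad = np.isnan(stack).any(axis=0)
            filled = linear_gapfill(list(zip(knot_years, stack)), [year])[0]
            filled[bad] = np.nan
            template = native[knot_years[0]]
            out[(pid, year)] = PopulationGrid(
                values=filled, geometry=template.geometry, unit=template.unit,
                year=year, product_id=pid, nodata=template.nodata,
            )
    missing_warned = [y for y in years if y not in epoch_table]
    if missing_warned:
        warnings.warn(f"epoch table does not cover years: {missing_warned}", stacklevel=2)
    return ProductStack(grids=out, epoch_table=dict(epoch_table))
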