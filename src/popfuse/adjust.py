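"""Census-total adjustment of the fused surface, and negative clamping.

Each country's fused pixel sum is rescaled to the reference national total by
a single factor a_t = reference / pixel_sum, applied to every pixel inside
the country boundary.  By default negatives are clamped to zero *before* the
factors are computed, so the released surface satisfies both stated
guarantees — non-negative pixels and exact national totals; the literal
clamp-after-adjust order (which can break the totals) is available behind
``clamp_after_adjust=True``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .grids import PopulationGrid, ZoneMap, require_aligned, zonal_sum

logger = logging.getLogger(__name__)

FACTOR_COLUMNS = ["unit_code", "year", "a_t", "pixel_sum", "reference_total"]


def adjustment_factor(pixel_sum: float, reference: float) -> float:
    """a_t = reference national total / fused pixel sum within the country."""
    if reference < 0:
        raise ValueError("reference total must be non-negative")
    if pixel_sum <= 0:
        if reference == 0:
            logger.info("empty country with zero reference; factor 1 by convention")
            return 1.0
        raise ValueError(
            f"cannot rescale an empty country (pixel_sum={pixel_sum}) to "
            f"reference {reference}")
    return reference / pixel_sum


def compute_factors(grid: PopulationGrid, zones: ZoneMap, reference: pd.Series,
                    year: int) -> pd.DataFrame:
    """AdjustmentFactors table for every zone present in the reference totals.

    Countries absent from the reference pass through unadjusted (factor 1)
    with a warning-level log, mirroring the exclusion of uninhabited units.
    """
    sums = zonal_sum(grid, zones)
    rows = []
    for code, pixel_sum in sums.items():
        if code not in reference.index:
            logger.warning("no reference total for %s; left unadjusted", code)
            rows.append({"unit_code": code, "year": year, "a_t": 1.0,
                         "pixel_sum": float(pixel_sum),
                         "reference_total": float("nan")})
            continue
        ref = float(reference[code])
        rows.append({"unit_code": code, "year": year,
                     "a_t": adjustment_factor(float(pixel_sum), ref),
                     "pixel_sum": float(pixel_sum), "reference_total": ref})
    return pd.DataFrame(rows, columns=FACTOR_COLUMNS)


def apply_adjustment(grid: PopulationGrid, factors: pd.DataFrame,
                     zones: ZoneMap) -> PopulationGrid:
    """Multiply each pixel by its country's factor; pixels outside any zone pass through."""
    require_aligned(grid, zones)
    by_code = factors.set_index("unit_code")["a_t"]
    max_label = int(zones.labels.max())
    factor_of_label = np.ones(max_label + 1)
    for label, code in zones.code_lookup.items():
        if code in by_code.index:
            factor_of_label[label] = float(by_code[code])
        elif np.any((zones.labels == label) & ~grid.mask & (grid.values > 0)):
            raise ValueError(f"populated zone {code} has no adjustment factor")
    outside = int(np.sum((zones.labels == 0) & ~grid.mask))
    if outside:
        logger.info("%d data pixels outside every zone left unchanged", outside)
    adjusted = grid.values * factor_of_label[zones.labels]
    return grid.with_values(adjusted)


def clamp_nonnegative(grid: PopulationGrid) -> tuple[PopulationGrid, int]:
    """Zero out negative pixels (gap-fill extrapolation artifacts); nodata untouched."""
    negative = grid.values < 0
    n_clamped = int(np.sum(negative))
    if n_clamped:
        logger.info("clamped %d negative pixels to zero", n_clamped)
    return grid.with_values(np.where(negative, 0.0, grid.values)), n_clamped


def adjust_to_reference(grid: PopulationGrid, zones: ZoneMap, reference: pd.Series,
                        year: int, clamp_after_adjust: bool = False
                        ) -> tuple[PopulationGrid, pd.DataFrame, int]:
    """Full stage: clamp, compute factors, rescale (default, conservation-exact order).

    With ``clamp_after_adjust=True`` the literal order — scale first, clamp
    after — is used instead; national totals are then only approximate in
    countries containing negative pixels.
    """
    if clamp_after_adjust:
        factors = compute_factors(grid, zones, reference, year)
        adjusted = apply_adjustment(grid, factors, zones)
        adjusted, n_clamped = clamp_nonnegative(adjusted)
    else:
        clamped, n_clamped = clamp_nonnegative(grid)
        factors = compute_factors(clamped, zones, reference, year)
        adjusted = apply_adjustment(clamped, factors, zones)
    return adjusted, factors, n_clamped
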