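"""Spatial and temporal validation statistics for fused population surfaces.

Covers the goodness-of-fit metrics (R², RMSE, MAE), the relative entropy
(discrete Kullback–Leibler divergence) between normalized predicted and census
count distributions, dynamic-time-warping distance between population curves,
and the Mann–Kendall trend test with Sen's slope, applied both to single
series and per pixel across annual rasters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .grids import PopulationGrid, ZoneMap, require_aligned, zonal_sum
from .harmonize import CensusTable


# ---------------------------------------------------------------------------
# Fit metrics
# ---------------------------------------------------------------------------

@dataclass
class FitMetrics:
    r2: float
    rmse: float
    mae: float
    relative_entropy: float = float("nan")
    n: int = 0
    level: str = "level0"
    year: int | None = None


def fit_metrics(x: np.ndarray, y: np.ndarray, level: str = "level0",
                year: int | None = None) -> FitMetrics:
    """R² = 1 − Σ(xᵢ−yᵢ)²/Σ(x̄−xᵢ)², RMSE and MAE of predictions y against census x.

    A constant census vector leaves R² undefined (NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    sq = (x - y) ** 2
    denom = float(np.sum((x.mean() - x) ** 2))
    r2 = 1.0 - float(np.sum(sq)) / denom if denom > 0 else math.nan
    return FitMetrics(r2=r2, rmse=float(np.sqrt(np.mean(sq))),
                      mae=float(np.mean(np.abs(x - y))), n=x.size,
                      level=level, year=year)


def relative_entropy(x_counts: np.ndarray, y_counts: np.ndarray,
                     epsilon: float = 1e-12) -> float:
    """KL divergence (nats) of the census distribution P from the predicted Q.

    Both count vectors are normalized to probability distributions over the
    same admin units; epsilon is added to the predicted cells before
    renormalization so empty predictions do not divide by zero.
    """
    x = np.asarray(x_counts, dtype=float)
    y = np.asarray(y_counts, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("count vectors must be non-negative")
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("count vectors must have positive sums")
    p = x / x.sum()
    q = y + epsilon
    q = q / q.sum()
    pos = p > 0
    return float(np.sum(p[pos] * np.log(p[pos] / q[pos])))


# ---------------------------------------------------------------------------
# Dynamic time warping
# ---------------------------------------------------------------------------

@dataclass
class DtwConfig:
    """Step weights and normalization of the warping-path cost.

    The default symmetric pattern weights a diagonal step 2 and an expansion
    step 1, and normalizes the minimal path cost by M = len(X) + len(Y).
    """

    diagonal_weight: float = 2.0
    step_weight: float = 1.0
    normalize: bool = True
    window: int | None = None

    def __post_init__(self) -> None:
        if self.diagonal_weight <= 0 or self.step_weight <= 0:
            raise ValueError("step weights must be positive")


def dtw_distance(X: np.ndarray, Y: np.ndarray,
                 config: DtwConfig | None = None) -> float:
    """Minimal weighted cost over monotone warping paths between two curves.

    Local cost is the absolute difference; dynamic programming over the
    (len(X) × len(Y)) lattice with the configured step weights, optionally
    restricted to a |i−j| <= window band.
    """
    if config is None:
        config = DtwConfig()
    x = np.asarray(X, dtype=float)
    y = np.asarray(Y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("series must be non-empty")
    n, m = x.size, y.size
    dw, sw = config.diagonal_weight, config.step_weight
    cost = np.abs(x[:, None] - y[None, :])
    if config.window is not None:
        i, j = np.indices((n, m))
        cost = np.where(np.abs(i - j) <= config.window, cost, np.inf)
    D = np.full((n, m), np.inf)
    D[0, 0] = cost[0, 0]
    for i in range(n):
        for j in range(m):
            if i == j == 0:
                continue
            best = np.inf
            if i > 0 and j > 0:
                best = D[i - 1, j - 1] + dw * cost[i, j]
            if i > 0:
                best = min(best, D[i - 1, j] + sw * cost[i, j])
            if j > 0:
                best = min(best, D[i, j - 1] + sw * cost[i, j])
            D[i, j] = best
    total = D[n - 1, m - 1]
    return float(total / (n + m)) if config.normalize else float(total)


# ---------------------------------------------------------------------------
# Mann–Kendall and Sen's slope
# ---------------------------------------------------------------------------

@dataclass
class TrendResult:
    S: int
    var_S: float
    Z: float
    p_value: float
    sen_slope: float
    significant: bool
    alpha: float = 0.05


def _mk_variance(series: np.ndarray) -> float:
    """Tie-corrected Var(S) = [n(n−1)(2n+5) − Σ t(t−1)(2t+5)]/18."""
    n = series.size
    _, counts = np.unique(series, return_counts=True)
    ties = counts[counts > 1]
    correction = float(np.sum(ties * (ties - 1) * (2 * ties + 5)))
    return (n * (n - 1) * (2 * n + 5) - correction) / 18.0


def mann_kendall(series: np.ndarray, alpha: float = 0.05) -> TrendResult:
    """Non-parametric monotone-trend test on a series ordered in time.

    S sums sgn(Xj − Xk) over all ordered pairs; the normalized statistic uses
    the ±1 continuity correction ((S−1)/√Var for S>0, 0 for S=0, (S+1)/√Var
    for S<0) and the tie-corrected variance; two-sided p from the standard
    normal approximation.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise ValueError("trend inference needs at least 3 observations")
    diffs = np.sign(x[None, :] - x[:, None])
    S = int(np.sum(np.triu(diffs, k=1)))
    var_S = _mk_variance(x)
    if S > 0:
        Z = (S - 1) / math.sqrt(var_S)
    elif S < 0:
        Z = (S + 1) / math.sqrt(var_S)
    else:
        Z = 0.0
    p = 2.0 * (1.0 - norm.cdf(abs(Z)))
    slope = sens_slope(x)
    return TrendResult(S=S, var_S=var_S, Z=Z, p_value=float(p), sen_slope=slope,
                       significant=bool(p < alpha), alpha=alpha)


def sens_slope(series: np.ndarray, times: np.ndarray | None = None) -> float:
    """Median of all pairwise slopes (Xj − Xi)/(tj − ti) over i < j."""
    x = np.asarray(series, dtype=float)
    t = np.arange(x.size, dtype=float) if times is None else np.asarray(times, float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    i, j = np.triu_indices(x.size, k=1)
    dt = t[j] - t[i]
    keep = dt != 0
    if not keep.any():
        raise ValueError("all observation times identical")
    return float(np.median((x[j] - x[i])[keep] / dt[keep]))


def trend_map(grids: list[PopulationGrid], alpha: float = 0.05,
              chunk_rows: int = 32, correction: str | None = None
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel Mann–Kendall Z, Sen's slope, and significance mask over years.

    Pixels that are nodata in any year are nodata throughout.  Returns
    (slope, Z, mask) arrays.  By default each pixel is tested marginally at
    ``alpha`` with no multiple-testing correction; ``correction="bh"``
    switches the mask to Benjamini–Hochberg FDR control across pixels.
    """
    if correction not in (None, "bh"):
        raise ValueError("correction must be None or 'bh'")
    if len(grids) < 3:
        raise ValueError("trend mapping needs at least 3 annual grids")
    require_aligned(*grids)
    cube = np.stack([g.values for g in grids])  # (T, rows, cols)
    T, rows, cols = cube.shape
    slope = np.full((rows, cols), np.nan)
    zmap = np.full((rows, cols), np.nan)
    ii, jj = np.triu_indices(T, k=1)
    zcrit_pairs = (ii, jj)
    for r0 in range(0, rows, chunk_rows):
        block = cube[:, r0:r0 + chunk_rows, :]
        t, br, bc = block.shape
        flat = block.reshape(t, -1)  # (T, P)
        ok = ~np.isnan(flat).any(axis=0)
        if not ok.any():
            continue
        v = flat[:, ok]  # (T, P_ok)
        d = v[zcrit_pairs[1], :] - v[zcrit_pairs[0], :]  # (n_pairs, P_ok)
        S = np.sign(d).sum(axis=0)
        sl = np.median(d / (zcrit_pairs[1] - zcrit_pairs[0])[:, None], axis=0)
        var = _tie_corrected_variance_block(v)
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = np.where(S > 0, (S - 1) / np.sqrt(var),
                         np.where(S < 0, (S + 1) / np.sqrt(var), 0.0))
        out_sl = np.full(flat.shape[1], np.nan)
        out_z = np.full(flat.shape[1], np.nan)
        out_sl[ok] = sl
        out_z[ok] = Z
        slope[r0:r0 + chunk_rows, :] = out_sl.reshape(br, bc)
        zmap[r0:r0 + chunk_rows, :] = out_z.reshape(br, bc)
    if correction == "bh":
        pvals = 2 * (1 - norm.cdf(np.abs(zmap)))
        flat = pvals[~np.isnan(zmap)]
        order = np.sort(flat)
        m = order.size
        passed = order <= alpha * (np.arange(1, m + 1) / m)
        threshold = order[passed].max() if passed.any() else -1.0
        mask = (pvals <= threshold) & ~np.isnan(zmap)
    else:
        zcrit = norm.ppf(1 - alpha / 2)
        mask = np.abs(zmap) > zcrit
        mask &= ~np.isnan(zmap)
    return slope, zmap, mask


def _tie_corrected_variance_block(v: np.ndarray) -> np.ndarray:
    """Vectorized tie-corrected Var(S) for each column series of v (T, P)."""
    T, P = v.shape
    base = T * (T - 1) * (2 * T + 5)
    sv = np.sort(v, axis=0)
    # run lengths of equal consecutive values per column
    new_run = np.ones_like(sv, dtype=bool)
    new_run[1:] = sv[1:] != sv[:-1]
    # tie correction sum over runs t: t(t-1)(2t+5); compute via cumulative trick
    correction = np.zeros(P)
    run_len = np.zeros(P, dtype=np.int64)
    for row in range(T):
        starting = new_run[row]
        ended = starting & (run_len > 1)
        t = run_len[ended]
        correction[ended] += t * (t - 1) * (2 * t + 5)
        run_len = np.where(starting, 1, run_len + 1)
    t = run_len[run_len > 1]
    correction[run_len > 1] += t * (t - 1) * (2 * t + 5)
    return (base - correction) / 18.0


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ["Year", "R2", "RMSE", "MAE", "RelativeEntropy"]


@dataclass
class ValidationReport:
    """Per-year accuracy tables for the fused surface and each baseline."""

    spatial: pd.DataFrame  # columns: Surface, Level, Year, R2, RMSE, MAE, RelativeEntropy, n
    dtw: pd.DataFrame = field(default_factory=pd.DataFrame)  # Surface, unit_code, DTW

    def table_for(self, surface: str, level: str = "level0") -> pd.DataFrame:
        sub = self.spatial[(self.spatial["Surface"] == surface)
                           & (self.spatial["Level"] == level)]
        return (sub[["Year", "R2", "RMSE", "MAE", "RelativeEntropy"]]
                .reset_index(drop=True))

    def to_csv(self, path) -> None:
        self.spatial.to_csv(path, index=False)


def _yearly_rows(surface_name: str, sums_by_year: dict[int, pd.Series],
                 census: CensusTable, level: str) -> list[dict]:
    rows = []
    for year, sums in sorted(sums_by_year.items()):
        ref = census.totals_for_year(year)
        common = [c for c in ref.index if c in sums.index]
        if len(common) < 2:
            continue
        x = ref[common].to_numpy(dtype=float)
        y = sums[common].to_numpy(dtype=float)
        fm = fit_metrics(x, y, level=level, year=year)
        rows.append({"Surface": surface_name, "Level": level, "Year": year,
                     "R2": fm.r2, "RMSE": fm.rmse, "MAE": fm.mae,
                     "RelativeEntropy": relative_entropy(x, y), "n": fm.n})
    return rows


def validation_report(fused: dict[int, PopulationGrid], census: CensusTable,
                      zones: ZoneMap,
                      baselines: dict[str, dict[int, PopulationGrid]] | None = None,
                      level2_zones: ZoneMap | None = None,
                      level2_census: CensusTable | None = None,
                      dtw_config: DtwConfig | None = None) -> ValidationReport:
    """Assemble per-year fit metrics and per-country DTW curve distances.

    The fused surface and every baseline (individual products, median
    composite) are aggregated to admin totals and scored against census at
    level-0, optionally level-2; DTW compares each country's annual total
    curve with its census curve.
    """
    surfaces: dict[str, dict[int, PopulationGrid]] = {"fused": fused}
    surfaces.update(baselines or {})

    rows: list[dict] = []
    sums_cache: dict[str, dict[int, pd.Series]] = {}
    for name, grids in surfaces.items():
        sums = {year: zonal_sum(g, zones) for year, g in grids.items()}
        sums_cache[name] = sums
        rows.extend(_yearly_rows(name, sums, census, "level0"))
        if level2_zones is not None and level2_census is not None:
            sums2 = {year: zonal_sum(g, level2_zones) for year, g in grids.items()}
            rows.extend(_yearly_rows(name, sums2, level2_census, "level2"))
    spatial = pd.DataFrame(rows)

    dtw_rows: list[dict] = []
    for name, sums in sums_cache.items():
        years = sorted(sums)
        if len(years) < 2:
            continue
        codes = set.intersection(*(set(sums[y].index) for y in years))
        for code in sorted(codes):
            pred = np.array([float(sums[y][code]) for y in years])
            ref = np.array([census.get(code, y) if code in
                            census.totals_for_year(y).index else np.nan
                            for y in years])
            if np.isnan(ref).any():
                continue
            dtw_rows.append({"Surface": name, "unit_code": code,
                             "DTW": dtw_distance(ref, pred, dtw_config)})
    return ValidationReport(spatial=spatial, dtw=pd.DataFrame(dtw_rows))
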