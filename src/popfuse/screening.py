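"""Reliability screening of products against census by per-product K-means.

For every (product, year), each country's product total is scored against the
census with four error metrics — APE, SE, SLE and Dif — the metrics are
min-max scaled to [0, 1], and a 2-cluster K-means splits countries into a
"better" and a "worse" group.  The cluster whose centroid lies closer to the
origin of scaled (|APE|, SE, SLE, |Dif|) space is the reliable one: those
countries feed model training, the rest serve as held-out test countries.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

DEFAULT_SEED = 20240124
METRIC_COLUMNS = ["APE", "SE", "SLE", "Dif"]
#: feature space for clustering and the better-centroid rule (magnitudes)
FEATURE_COLUMNS = ["absAPE_scaled", "SE_scaled", "SLE_scaled", "absDif_scaled"]


def error_metrics(X: float, Y: float) -> tuple[float, float, float, float]:
    """Country-level error of a product total Y against the census count X.

    APE = (X − Y)/X, SE = (X − Y)², SLE = (ln(1+X) − ln(1+Y))², Dif = Y − X.
    APE is undefined for X = 0 (returned as NaN; such records are excluded
    from clustering features).
    """
    if Y < 0:
        raise ValueError("product totals must be non-negative")
    diff = X - Y
    ape = diff / X if X > 0 else math.nan
    se = diff * diff
    sle = (math.log1p(X) - math.log1p(Y)) ** 2
    return ape, se, sle, Y - X


def error_metric_table(census: pd.Series, product_sums: dict[str, pd.Series],
                       year: int) -> pd.DataFrame:
    """Tabulate the four metrics for every (country, product) at one year."""
    rows = []
    for pid, sums in product_sums.items():
        for code in census.index:
            if code not in sums.index:
                continue
            ape, se, sle, dif = error_metrics(float(census[code]), float(sums[code]))
            rows.append({"unit_code": code, "product_id": pid, "year": year,
                         "APE": ape, "SE": se, "SLE": sle, "Dif": dif})
    return pd.DataFrame(rows)


def minmax_scale(table: pd.DataFrame, columns=METRIC_COLUMNS,
                 group_keys=("product_id", "year")) -> pd.DataFrame:
    """Scale each metric to [0, 1] within every (product, year) group.

    Constant groups map to 0 with a warning.  Adds ``<col>_scaled`` columns,
    plus ``absAPE_scaled``/``absDif_scaled`` built from the magnitudes of the
    signed metrics so over- and under-estimation are penalized symmetrically.
    """
    out = table.copy()
    work = {col: out[col] for col in columns}
    work["absAPE"] = out["APE"].abs()
    work["absDif"] = out["Dif"].abs()
    for col, series in work.items():
        scaled = np.full(len(out), np.nan)
        for _, idx in out.groupby(list(group_keys)).groups.items():
            v = series.loc[idx].to_numpy(dtype=float)
            finite = np.isfinite(v)
            if finite.sum() == 0:
                continue
            lo, hi = np.nanmin(v), np.nanmax(v)
            if hi == lo:
                warnings.warn(f"constant group for metric {col}; scaled to 0", stacklevel=2)
                s = np.where(finite, 0.0, np.nan)
            else:
                s = (v - lo) / (hi - lo)
            scaled[out.index.get_indexer(idx)] = s
        out[f"{col}_scaled"] = scaled
    return out


def choose_k(features: np.ndarray, k_range=range(2, 6), seed: int = DEFAULT_SEED,
             restarts: int = 10) -> tuple[int, dict[int, float]]:
    """Pick the cluster count maximizing mean silhouette; ties favor smaller k.

    The pipeline fixes k = 2 and keeps this as a diagnostic.
    """
    features = np.asarray(features, dtype=float)
    k_range = list(k_range)
    if len(features) <= max(k_range):
        raise ValueError(f"need more than {max(k_range)} points, got {len(features)}")
    if len(np.unique(features, axis=0)) < 2:
        raise ValueError("all points identical; cluster count undefined")
    scores: dict[int, float] = {}
    for k in k_range:
        labels, _ = kmeans_partition(features, k, seed=seed, restarts=restarts)
        if len(np.unique(labels)) < 2:
            scores[k] = -1.0
            continue
        scores[k] = float(silhouette_score(features, labels))
    best = max(sorted(scores), key=lambda k: (scores[k], -k))
    return best, scores


def kmeans_partition(features: np.ndarray, k: int, seed: int = DEFAULT_SEED,
                     restarts: int = 50, max_iter: int = 300
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Seeded Lloyd K-means, best of ``restarts`` initializations by WCSS."""
    features = np.asarray(features, dtype=float)
    if not np.isfinite(features).all():
        raise ValueError("features must be finite")
    km = KMeans(n_clusters=k, n_init=restarts, max_iter=max_iter,
                random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(features)
    return labels, km.cluster_centers_


def flag_validity(metric_table: pd.DataFrame, k: int = 2, seed: int = DEFAULT_SEED,
                  restarts: int = 50) -> pd.DataFrame:
    """Cluster each (product, year) group and flag its reliable countries.

    Returns a ValidityTable with columns unit_code, product_id, year,
    cluster_label, valid.  The "better" cluster is the one whose centroid has
    the smaller Euclidean norm in scaled magnitude space; a norm tie marks
    both clusters valid (tie-break favors inclusion).  Groups whose metrics
    are all identical (e.g. every product total exact) are wholly valid.
    Records with undefined APE (census zero) are excluded from the features
    and flagged invalid.
    """
    scaled = minmax_scale(metric_table)
    rows = []
    for (pid, year), group in scaled.groupby(["product_id", "year"]):
        feats = group[FEATURE_COLUMNS].to_numpy(dtype=float)
        usable = np.isfinite(feats).all(axis=1)
        sub = group[usable]
        feats = feats[usable]
        for code in group.loc[~usable, "unit_code"]:
            rows.append({"unit_code": code, "product_id": pid, "year": year,
                         "cluster_label": -1, "valid": False})
        if len(sub) == 0:
            continue
        if len(np.unique(feats, axis=0)) < 2:
            # degenerate: no separation to exploit; everything is trusted
            for code in sub["unit_code"]:
                rows.append({"unit_code": code, "product_id": pid, "year": year,
                             "cluster_label": 0, "valid": True})
            continue
        labels, centroids = kmeans_partition(feats, k, seed=seed, restarts=restarts)
        norms = np.linalg.norm(centroids, axis=1)
        best = int(np.argmin(norms))
        tied = np.isclose(norms, norms[best])
        if tied.sum() > 1:
            warnings.warn(
                f"centroid-norm tie for ({pid}, {year}); all clusters marked valid",
                stacklevel=2)
        valid_clusters = set(np.where(tied)[0]) if tied.sum() > 1 else {best}
        for code, label in zip(sub["unit_code"], labels):
            rows.append({"unit_code": code, "product_id": pid, "year": year,
                         "cluster_label": int(label),
                         "valid": int(label) in valid_clusters})
    return pd.DataFrame(rows)


def count_valid_products(validity: pd.DataFrame) -> pd.DataFrame:
    """Per (country, year) count of products whose totals can be trusted."""
    counts = (validity.groupby(["unit_code", "year"])["valid"].sum()
              .astype(int).rename("n_valid").reset_index())
    return counts


@dataclass
class ScreeningReport:
    """Clustering diagnostics serialized next to the validity table."""

    silhouette: dict
    centroids: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"silhouette": self.silhouette, "centroids": self.centroids},
                      fh, indent=2, default=float)
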