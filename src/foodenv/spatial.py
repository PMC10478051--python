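"""Hot-spot and cold-spot detection with the Getis-Ord Gi* statistic.

Spatial weights are built from tract polygons (queen contiguity: any shared
boundary point) or from centroids (fixed distance band), always including
the focal tract itself with weight 1. Gi* z-scores are binned at two-sided
normal 90/95/99% critical values into signed confidence bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree
from scipy.stats import norm
from shapely.strtree import STRtree

from .geo import TractGeometry

__all__ = [
    "SpatialWeights",
    "build_weights",
    "gi_star",
    "bin_confidence",
    "hotspot_table",
    "compare_years",
]

# two-sided standard-normal critical values, fixed to six decimals for
# bit-stable binning
CRIT_90 = 1.644854
CRIT_95 = 1.959964
CRIT_99 = 2.575829


class DegenerateFieldError(ValueError):
    pass


@dataclass(frozen=True)
class SpatialWeights:
    """Sparse symmetric weights with self-inclusion (w_ii = 1)."""

    ids: tuple[str, ...]
    matrix: sparse.csr_matrix  # includes the diagonal
    scheme: str
    isolates: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n(self) -> int:
        return len(self.ids)

    def neighbors(self, tract_id: str) -> list[str]:
        """Non-self neighbours of a tract."""
        i = self.ids.index(tract_id)
        row = self.matrix.getrow(i)
        return [self.ids[j] for j in row.indices if j != i]

    def reorder(self, new_ids: list[str]) -> "SpatialWeights":
        perm = np.array([self.ids.index(t) for t in new_ids])
        m = self.matrix[perm][:, perm].tocsr()
        return SpatialWeights(tuple(new_ids), m, self.scheme, self.isolates)


def build_weights(
    geoms: list[TractGeometry],
    scheme: str = "queen",
    band_distance: float | None = None,
) -> SpatialWeights:
    """Build self-inclusive binary weights.

    queen: tracts sharing any boundary point are neighbours. distance_band:
    tracts whose centroids lie within ``band_distance`` are neighbours; the
    default band is the smallest distance at which every tract has at least
    one non-self neighbour (the max over tracts of the nearest-centroid
    distance).
    """
    n = len(geoms)
    if n < 2:
        raise ValueError("Gi* requires at least two tracts")
    ids = tuple(g.tract_id for g in geoms)
    if len(set(ids)) != n:
        raise ValueError("duplicate tract ids in geometry input")

    rows: list[int] = []
    cols: list[int] = []
    if scheme == "queen":
        polys = [g.polygon for g in geoms]
        tree = STRtree(polys)
        for i, poly in enumerate(polys):
            for j in tree.query(poly, predicate="intersects"):
                j = int(j)
                if j != i:
                    rows.append(i)
                    cols.append(j)
    elif scheme == "distance_band":
        pts = np.array([(g.centroid.x, g.centroid.y) for g in geoms])
        tree = cKDTree(pts)
        if band_distance is None:
            nn_dist, _ = tree.query(pts, k=2)
            band_distance = float(nn_dist[:, 1].max())
        pairs = tree.query_pairs(band_distance, output_type="ndarray")
        for i, j in pairs:
            rows.extend((int(i), int(j)))
            cols.extend((int(j), int(i)))
    else:
        raise ValueError(f"unknown weights scheme {scheme!r}")

    data = np.ones(len(rows) + n)
    rows_all = np.concatenate([np.array(rows, dtype=int), np.arange(n)])
    cols_all = np.concatenate([np.array(cols, dtype=int), np.arange(n)])
    mat = sparse.csr_matrix((data, (rows_all, cols_all)), shape=(n, n))
    mat.data = np.minimum(mat.data, 1.0)  # guard accidental duplicates

    degree = np.asarray(mat.sum(axis=1)).ravel()
    isolates = tuple(ids[i] for i in np.flatnonzero(degree <= 1))
    for t in isolates:
        warnings.warn(f"tract {t} has no neighbour besides itself", stacklevel=2)
    return SpatialWeights(ids, mat, scheme, isolates)


def gi_star(values: np.ndarray, weights: SpatialWeights) -> np.ndarray:
    """Gi* z-scores, self-inclusive.

    For tract i with weights w_ij (w_ii included):

        z_i = (sum_j w_ij x_j - xbar * W_i)
              / (S * sqrt((n * sum_j w_ij^2 - W_i^2) / (n - 1)))

    where W_i = sum_j w_ij, xbar is the global mean and
    S = sqrt(mean(x^2) - xbar^2).
    """
    x = np.asarray(values, dtype=float)
    n = weights.n
    if x.shape != (n,):
        raise ValueError(f"values length {x.shape} does not match {n} tracts")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in field")
    xbar = x.mean()
    s2 = np.var(x)  # two-pass; algebraically mean(x^2) - xbar^2
    if s2 <= 0:
        raise DegenerateFieldError("degenerate field: zero variance")
    s = np.sqrt(s2)

    w = weights.matrix
    lag = w @ x
    wi = np.asarray(w.sum(axis=1)).ravel()
    wi2 = np.asarray(w.multiply(w).sum(axis=1)).ravel()
    spread = n * wi2 - wi**2
    denom = s * np.sqrt(np.maximum(spread, 0.0) / (n - 1))
    # a tract whose neighbourhood covers every tract has spread 0 and a
    # numerator of exactly 0: define its z as 0 rather than 0/0
    z = np.zeros(n)
    ok = spread > 1e-12 * n
    z[ok] = (lag[ok] - xbar * wi[ok]) / denom[ok]
    return z


def bin_confidence(z: float | np.ndarray) -> np.ndarray | int:
    """Signed confidence bin: |z| >= 2.575829 -> 3 (99%), >= 1.959964 -> 2
    (95%), >= 1.644854 -> 1 (90%), else 0; sign follows z."""
    z_arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z_arr)):
        raise ValueError("non-finite z-score")
    mag = np.where(
        np.abs(z_arr) >= CRIT_99,
        3,
        np.where(np.abs(z_arr) >= CRIT_95, 2, np.where(np.abs(z_arr) >= CRIT_90, 1, 0)),
    )
    out = (np.sign(z_arr) * mag).astype(int)
    return int(out) if np.isscalar(z) or out.ndim == 0 else out


def hotspot_table(
    values: pd.Series,
    weights: SpatialWeights,
    year: int | None = None,
) -> pd.DataFrame:
    """Per-tract Gi* results for one year.

    ``values`` is indexed by tract_id; ids must match the weights object
    (any ordering).
    """
    if set(values.index) != set(weights.ids):
        raise ValueError("tract ids of values do not match weights")
    x = values.reindex(list(weights.ids)).to_numpy(dtype=float)
    z = gi_star(x, weights)
    p = 2.0 * norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "tract_id": list(weights.ids),
            "gi_z": z,
            "p_value": p,
            "bin": bin_confidence(z),
        }
    )
    if year is not None:
        out.insert(1, "year", int(year))
    return out


def _transition_label(b0: int, b1: int) -> str:
    if b0 <= -1 and b1 >= 1:
        return "cold->hot"
    if b0 >= 1 and b1 <= -1:
        return "hot->cold"
    if b0 >= 1 and b1 >= 1:
        return "stable-hot"
    if b0 <= -1 and b1 <= -1:
        return "stable-cold"
    if b0 == 0 and b1 >= 1:
        return "emerging-hot"
    if b0 == 0 and b1 <= -1:
        return "emerging-cold"
    return "none"


def compare_years(results_by_year: dict[int, pd.DataFrame]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-year cluster change summary.

    Returns (transitions, yearly_counts): per-tract first/last bins with a
    transition label, and per-year hot/cold tract counts (|bin| >= 1).
    """
    if len(results_by_year) < 2:
        raise ValueError("need results for at least two years")
    years = sorted(results_by_year)
    tract_sets = [set(results_by_year[y]["tract_id"]) for y in years]
    if any(s != tract_sets[0] for s in tract_sets[1:]):
        raise ValueError("mismatched tract sets across years")

    first = results_by_year[years[0]].set_index("tract_id")["bin"]
    last = results_by_year[years[-1]].set_index("tract_id")["bin"]
    tracts = sorted(tract_sets[0])
    transitions = pd.DataFrame(
        {
            "tract_id": tracts,
            "first_year": years[0],
            "last_year": years[-1],
            "first_bin": first.reindex(tracts).astype(int).to_numpy(),
            "last_bin": last.reindex(tracts).astype(int).to_numpy(),
        }
    )
    transitions["transition"] = [
        _transition_label(b0, b1)
        for b0, b1 in zip(transitions["first_bin"], transitions["last_bin"])
    ]

    yearly = pd.DataFrame(
        {
            "year": years,
            "n_hot": [int((results_by_year[y]["bin"] >= 1).sum()) for y in years],
            "n_cold": [int((results_by_year[y]["bin"] <= -1).sum()) for y in years],
        }
    )
    return transitions, yearly
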