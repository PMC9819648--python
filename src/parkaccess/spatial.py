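"""Zone aggregation and spatial autocorrelation of accessibility fields.

Provides population-weighted zone means, k-nearest-neighbour / distance-band
spatial weights, global Moran's I, and local Moran's I (LISA) with
conditional-permutation inference and the usual HH / LL / HL / LH cluster
labels.  Under row-standardized weights the local statistics satisfy
``sum_i I_i = n * I_global``, which the test-suite checks numerically.

Permutation p-values are pseudo p-values,
``p = (#{|I_perm| >= |I_obs|} + 1) / (n_perm + 1)`` (two-tailed), computed
in sorted-site_id order from a single seeded generator so results are
reproducible and independent of input row order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import AccessibilityField, DemandSite, sort_sites

__all__ = [
    "SpatialWeights",
    "LisaResult",
    "aggregate_by_zone",
    "build_weights",
    "global_moran",
    "local_moran",
]


def aggregate_by_zone(
    field: AccessibilityField, demand: Sequence[DemandSite]
) -> pd.DataFrame:
    """Population-weighted mean accessibility per zone.

    Returns a DataFrame (zone_id, value, total_population), one row per
    zone in sorted order.  A zone whose total population is zero has an
    undefined mean and is reported with value NaN.
    """
    demand = sort_sites(demand)
    missing_zone = [s.site_id for s in demand if s.zone_id is None]
    if missing_zone:
        raise ValueError(f"demand sites without zone_id: {missing_zone[:5]}")
    a = field.values
    rows = []
    zones = sorted({s.zone_id for s in demand})
    for z in zones:
        members = [s for s in demand if s.zone_id == z]
        pop = np.array([s.population for s in members])
        try:
            vals = a.loc[[s.site_id for s in members]].to_numpy()
        except KeyError as e:
            raise KeyError(f"accessibility field missing site {e.args[0]!r}")
        total = pop.sum()
        value = float(pop @ vals / total) if total > 0 else float("nan")
        rows.append({"zone_id": z, "value": value, "total_population": float(total)})
    return pd.DataFrame(rows)


@dataclass
class SpatialWeights:
    """Sparse neighbour structure over a fixed, id-sorted set of sites."""

    ids: tuple
    neighbors: list  # list of int arrays (indices into ids)
    weights: list    # matching float arrays
    scheme: str
    row_standardized: bool

    @property
    def n(self) -> int:
        return len(self.ids)

    def dense(self) -> np.ndarray:
        w = np.zeros((self.n, self.n))
        for i, (nbrs, wts) in enumerate(zip(self.neighbors, self.weights)):
            w[i, nbrs] = wts
        return w

    def lag(self, z: np.ndarray) -> np.ndarray:
        """Spatial lag: per-site weighted sum of neighbour values."""
        return np.array(
            [
                float(wts @ z[nbrs]) if len(nbrs) else 0.0
                for nbrs, wts in zip(self.neighbors, self.weights)
            ]
        )


def build_weights(
    sites: Sequence,
    scheme: str = "knn",
    k: int = 8,
    band: Optional[float] = None,
    row_standardize: bool = True,
) -> SpatialWeights:
    """Spatial weights from point sites.

    ``knn``: the k nearest sites by Euclidean distance, distance ties broken
    by site_id order.  ``distance_band``: all sites within ``band``.  Rows
    are standardized to sum to 1 by default (isolated sites keep an empty
    row).  No site neighbours itself.
    """
    sites = sort_sites(sites)
    n = len(sites)
    xy = np.array([[s.x, s.y] for s in sites])
    ids = tuple(s.site_id for s in sites)
    dist = np.hypot(xy[:, 0:1] - xy[None, :, 0], xy[:, 1:2] - xy[None, :, 1])
    np.fill_diagonal(dist, np.inf)

    neighbors: list = []
    weights: list = []
    if scheme == "knn":
        if k < 1 or k >= n:
            raise ValueError(f"knn needs 1 <= k < n sites, got k={k}, n={n}")
        order_idx = np.arange(n)
        for i in range(n):
            # lexsort: distance first, site_id order as tie-break
            order = np.lexsort((order_idx, dist[i]))
            nbrs = np.sort(order[:k])
            neighbors.append(nbrs)
            weights.append(np.ones(k))
    elif scheme == "distance_band":
        if band is None or band <= 0:
            raise ValueError("distance_band requires a positive band")
        for i in range(n):
            nbrs = np.flatnonzero(dist[i] <= band)
            neighbors.append(nbrs)
            weights.append(np.ones(len(nbrs)))
    else:
        raise ValueError(f"unknown weights scheme {scheme!r}")

    if row_standardize:
        weights = [w / w.sum() if len(w) else w for w in weights]
    return SpatialWeights(ids, neighbors, weights, scheme, row_standardize)


def _align(values, w: SpatialWeights) -> np.ndarray:
    if isinstance(values, pd.Series):
        try:
            return values.loc[list(w.ids)].to_numpy(dtype=float)
        except KeyError:
            raise KeyError("values do not cover every site in the weights")
    arr = np.asarray(values, dtype=float)
    if arr.shape != (w.n,):
        raise ValueError(f"expected {w.n} values, got shape {arr.shape}")
    return arr


def global_moran(values, w: SpatialWeights) -> float:
    """Global Moran's I: ``(n/S0) * sum_ij w_ij z_i z_j / sum_i z_i^2``."""
    z = _align(values, w)
    n = w.n
    if n < 3:
        raise ValueError("global Moran's I needs at least 3 sites")
    z = z - z.mean()
    ss = float(z @ z)
    if ss == 0.0:
        raise ValueError("constant field: Moran's I undefined")
    s0 = float(sum(wts.sum() for wts in w.weights))
    num = float(z @ w.lag(z))
    return n / s0 * num / ss


@dataclass
class LisaResult:
    """Local Moran's I per site with permutation inference and cluster labels."""

    table: pd.DataFrame  # columns: site_id, I_local, p_pseudo, cluster
    alpha: float
    n_perm: int

    def counts(self) -> pd.Series:
        return self.table["cluster"].value_counts()


_QUADRANTS = {(True, True): "HH", (False, False): "LL", (True, False): "HL", (False, True): "LH"}


def local_moran(
    values,
    w: SpatialWeights,
    n_perm: int = 999,
    seed: Optional[int] = None,
    alpha: float = 0.05,
) -> LisaResult:
    """Local Moran's I with conditional-permutation pseudo p-values.

    ``I_i = (z_i / m2) * sum_j w_ij z_j`` with ``m2 = sum z^2 / n``.  For
    inference, each site's own value stays fixed while the remaining values
    are permuted (a shared table of ``n_perm`` permutations of the n-1
    other positions); significance is two-tailed at ``alpha``.  Significant
    sites are labelled by their Moran-scatter quadrant (value vs lag):
    HH / LL clusters, HL / LH outliers; everything else, and every site of
    a constant field, is "not significant".
    """
    z_raw = _align(values, w)
    n = w.n
    if n < 3:
        raise ValueError("local Moran's I needs at least 3 sites")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if seed is None:
        raise ValueError("a seed is required for permutation inference")

    z = z_raw - z_raw.mean()
    ss = float(z @ z)
    if ss == 0.0:
        warnings.warn("constant field: every site labelled not significant")
        table = pd.DataFrame(
            {
                "site_id": list(w.ids),
                "I_local": 0.0,
                "p_pseudo": 1.0,
                "cluster": "not significant",
            }
        )
        return LisaResult(table, alpha, n_perm)

    m2 = ss / n
    lag = w.lag(z)
    i_local = z / m2 * lag

    rng = np.random.default_rng(seed)
    # one permutation table shared across sites: rows permute the n-1 "others"
    perm = np.argsort(rng.random((n_perm, n - 1)), axis=1)

    p = np.empty(n)
    for i in range(n):
        nbrs = w.neighbors[i]
        wts = w.weights[i]
        ki = len(nbrs)
        if ki == 0:
            p[i] = 1.0
            continue
        others = np.delete(z, i)
        sampled = others[perm[:, :ki]]          # (n_perm, ki)
        lag_perm = sampled @ wts
        i_perm = z[i] / m2 * lag_perm
        p[i] = (np.count_nonzero(np.abs(i_perm) >= abs(i_local[i])) + 1.0) / (
            n_perm + 1.0
        )

    sig = p < alpha
    labels = [
        _QUADRANTS[(z[i] > 0, lag[i] > 0)]
        if sig[i] and z[i] != 0 and lag[i] != 0
        else "not significant"
        for i in range(n)
    ]
    table = pd.DataFrame(
        {"site_id": list(w.ids), "I_local": i_local, "p_pseudo": p, "cluster": labels}
    )
    return LisaResult(table, alpha, n_perm)
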