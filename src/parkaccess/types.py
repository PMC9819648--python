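"""Core domain containers shared across the package.

All coordinates are planar projected units (meters recommended); all travel
costs are minutes unless the matrix is a Euclidean-distance baseline, in
which case the "cost" carries the same unit as the coordinates and the
catchment threshold is a distance.  Unreachable origin-destination pairs are
encoded as ``numpy.inf`` and always fall outside every catchment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DemandSite",
    "SupplySite",
    "TravelCostMatrix",
    "DecaySpec",
    "ModeMix",
    "AccessibilityField",
    "sort_sites",
    "demand_frame",
    "supply_frame",
]


@dataclass(frozen=True)
class DemandSite:
    """A residential area: a point of demand with a resident population."""

    site_id: str
    x: float
    y: float
    population: float
    zone_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.x) or not math.isfinite(self.y):
            raise ValueError(f"demand site {self.site_id!r}: non-finite coordinates")
        if not math.isfinite(self.population) or self.population < 0:
            raise ValueError(
                f"demand site {self.site_id!r}: population must be a nonnegative "
                f"finite number, got {self.population!r}"
            )


@dataclass(frozen=True)
class SupplySite:
    """A park: a point of supply with a size (area) and a quality score.

    ``supply_scale`` is the facility capacity S (the park area);
    ``weight`` is the competition weight W (a crowd-sourced quality score,
    e.g. a 0-5 Baidu rating) that multiplies capacity in the weighted model.
    Weights are used raw, never normalized; the model is homogeneous of
    degree one in W so any global rescaling of scores rescales every
    accessibility value by the same factor.
    """

    site_id: str
    x: float
    y: float
    supply_scale: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.x) or not math.isfinite(self.y):
            raise ValueError(f"supply site {self.site_id!r}: non-finite coordinates")
        if not math.isfinite(self.supply_scale) or self.supply_scale <= 0:
            raise ValueError(
                f"supply site {self.site_id!r}: supply_scale must be positive, "
                f"got {self.supply_scale!r}"
            )
        if not math.isfinite(self.weight) or self.weight <= 0:
            raise ValueError(
                f"supply site {self.site_id!r}: weight must be positive, "
                f"got {self.weight!r}"
            )


def sort_sites(sites: Sequence) -> list:
    """Return sites sorted by ``site_id`` (the canonical accumulation order)."""
    out = sorted(sites, key=lambda s: s.site_id)
    ids = [s.site_id for s in out]
    if len(set(ids)) != len(ids):
        dup = next(i for k, i in enumerate(ids) if i in ids[:k])
        raise ValueError(f"duplicate site_id {dup!r}")
    return out


def demand_frame(demand: Sequence[DemandSite]) -> pd.DataFrame:
    """Tabulate demand sites (sorted by id) as a DataFrame."""
    d = sort_sites(demand)
    return pd.DataFrame(
        {
            "site_id": [s.site_id for s in d],
            "x": [s.x for s in d],
            "y": [s.y for s in d],
            "population": [s.population for s in d],
            "zone_id": [s.zone_id for s in d],
        }
    )


def supply_frame(supply: Sequence[SupplySite]) -> pd.DataFrame:
    """Tabulate supply sites (sorted by id) as a DataFrame."""
    s = sort_sites(supply)
    return pd.DataFrame(
        {
            "site_id": [p.site_id for p in s],
            "x": [p.x for p in s],
            "y": [p.y for p in s],
            "area": [p.supply_scale for p in s],
            "score": [p.weight for p in s],
        }
    )


@dataclass
class TravelCostMatrix:
    """Dense demand x supply travel-cost matrix for one mode.

    ``metric`` is ``"time"`` (minutes) or ``"euclidean"`` (straight-line
    distance in coordinate units, for the distance-baseline model).
    """

    mode: str
    origin_ids: tuple
    dest_ids: tuple
    cost: np.ndarray
    metric: str = "time"

    def __post_init__(self) -> None:
        self.origin_ids = tuple(self.origin_ids)
        self.dest_ids = tuple(self.dest_ids)
        self.cost = np.asarray(self.cost, dtype=float)
        if self.metric not in ("time", "euclidean"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.cost.shape != (len(self.origin_ids), len(self.dest_ids)):
            raise ValueError(
                f"cost matrix shape {self.cost.shape} does not match "
                f"{len(self.origin_ids)} origins x {len(self.dest_ids)} destinations"
            )
        if np.isnan(self.cost).any():
            raise ValueError("cost matrix contains NaN")
        finite = self.cost[np.isfinite(self.cost)]
        if (finite < 0).any():
            raise ValueError("cost matrix contains negative entries")

    def aligned(self, origin_ids: Sequence[str], dest_ids: Sequence[str]) -> np.ndarray:
        """Cost submatrix reordered to the given origin/destination ids."""
        oidx = {i: k for k, i in enumerate(self.origin_ids)}
        didx = {j: k for k, j in enumerate(self.dest_ids)}
        try:
            rows = [oidx[i] for i in origin_ids]
            cols = [didx[j] for j in dest_ids]
        except KeyError as e:
            raise KeyError(f"site {e.args[0]!r} missing from {self.mode!r} cost matrix")
        return self.cost[np.ix_(rows, cols)]


@dataclass(frozen=True)
class DecaySpec:
    """Distance/time-decay choice: Gaussian kernel or sharp catchment edge.

    ``threshold`` is the catchment limit t0 (minutes, or a distance for the
    Euclidean baseline); the default 39 min is the average daily travel time
    reported for Chengdu.
    """

    kind: str = "gaussian"
    threshold: float = 39.0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "indicator"):
            raise ValueError(f"decay kind must be gaussian or indicator, got {self.kind!r}")
        if not math.isfinite(self.threshold) or self.threshold <= 0:
            raise ValueError(f"threshold must be positive, got {self.threshold!r}")


#: Daily travel-mode split for the Chengdu main urban area.
DEFAULT_MODE_SHARES = {
    "driving": 0.257,
    "transit": 0.432,
    "riding": 0.086,
    "walking": 0.225,
}


@dataclass
class ModeMix:
    """Travel modes and their daily-trip shares, used as convex weights."""

    modes: tuple
    shares: np.ndarray

    def __init__(self, modes: Iterable[str], shares: Iterable[float]):
        self.modes = tuple(modes)
        self.shares = np.asarray(list(shares), dtype=float)
        if len(self.modes) != len(self.shares):
            raise ValueError("modes and shares must have equal length")
        if len(self.modes) != len(set(self.modes)):
            raise ValueError("duplicate mode labels")
        if (self.shares < 0).any() or not np.isfinite(self.shares).all():
            raise ValueError("shares must be nonnegative and finite")
        total = self.shares.sum()
        if total <= 0:
            raise ValueError("shares sum to zero")
        if abs(total - 1.0) > 1e-6:
            warnings.warn(
                f"mode shares sum to {total:.6g}; renormalizing to 1", stacklevel=2
            )
        self.shares = self.shares / total

    @classmethod
    def default(cls) -> "ModeMix":
        return cls(DEFAULT_MODE_SHARES.keys(), DEFAULT_MODE_SHARES.values())

    def share(self, mode: str) -> float:
        try:
            return float(self.shares[self.modes.index(mode)])
        except ValueError:
            raise KeyError(f"mode {mode!r} not in mix")


@dataclass
class AccessibilityField:
    """Per-demand-site accessibility values for one mode (or the composite).

    ``values`` maps demand site_id -> A_i; ``supply_ratios`` maps supply
    site_id -> R_j (empty for composite fields, whose ratios live on the
    per-mode fields).  A site with no reachable supply has value exactly 0.
    """

    mode: str
    values: pd.Series
    supply_ratios: pd.Series = field(
        default_factory=lambda: pd.Series(dtype=float)
    )

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.supply_ratios = self.supply_ratios.astype(float)
        if (self.values < 0).any():
            raise ValueError("accessibility values must be nonnegative")
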