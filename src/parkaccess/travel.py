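"""Travel-cost matrices: Euclidean baseline and per-mode speed models.

Real navigation-API travel times are replaced by simple kinematic models: a
cruise speed plus a fixed access/egress overhead per mode, and for public
transport a set of corridor polylines (subway/bus lines) ridden at line
speed with walk access to the nearest corridor point.  Default speeds are
calibrated so that, at the 39-minute threshold, walking reaches about
2.7 km, riding about 7 km, and driving covers the whole study extent —
the reachability envelopes that drive the single-mode results.

Coordinates are planar meters; speeds are km/h; times are minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import LineString, Point

from .types import DemandSite, SupplySite, TravelCostMatrix, sort_sites

__all__ = [
    "TransitCorridor",
    "ModeSpeedModel",
    "euclidean_matrix",
    "speed_time_matrix",
    "reachable_set",
    "WALK_SPEED_KMH",
    "RIDE_SPEED_KMH",
    "DRIVE_SPEED_KMH",
    "TRANSIT_LINE_SPEED_KMH",
]

# 39-minute reach calibration: 2.7 km walking, 7 km riding.
WALK_SPEED_KMH = 2.7 / 39.0 * 60.0   # ~4.154 km/h
RIDE_SPEED_KMH = 7.0 / 39.0 * 60.0   # ~10.77 km/h
DRIVE_SPEED_KMH = 30.0               # urban driving; covers a 13x10 km extent in <39 min
TRANSIT_LINE_SPEED_KMH = 35.0        # in-vehicle metro/bus corridor speed


@dataclass(frozen=True)
class TransitCorridor:
    """A transit line: a polyline ridden end-to-end at ``line_speed`` km/h."""

    coords: tuple
    line_speed: float

    def __post_init__(self) -> None:
        if self.line_speed <= 0:
            raise ValueError("corridor line_speed must be positive")
        if len(self.coords) < 2:
            raise ValueError("corridor needs at least two vertices")

    @property
    def line(self) -> LineString:
        return LineString(self.coords)


@dataclass(frozen=True)
class ModeSpeedModel:
    """Kinematic travel-time model for one mode.

    Non-transit trips take ``fixed_overhead + 60 * d_km / cruise_speed``
    minutes over the straight-line distance d.  Transit trips take the
    minimum of walking the whole way (at ``corridor_access_speed``) and,
    per corridor, walking to the nearest corridor point, riding along the
    line, and walking from the corridor to the destination (overhead, e.g.
    boarding wait, charged on the ride option only, so transit can never
    cost more than walking).
    """

    mode: str
    cruise_speed: float
    fixed_overhead: float = 0.0
    corridors: tuple = ()
    corridor_access_speed: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cruise_speed <= 0:
            raise ValueError(f"mode {self.mode!r}: cruise_speed must be positive")
        if self.fixed_overhead < 0:
            raise ValueError(f"mode {self.mode!r}: fixed_overhead must be >= 0")
        if self.corridor_access_speed is not None and self.corridor_access_speed <= 0:
            raise ValueError(f"mode {self.mode!r}: corridor_access_speed must be positive")


def _xy(sites: Sequence) -> np.ndarray:
    return np.array([[s.x, s.y] for s in sites], dtype=float)


def _pairwise_dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.hypot(a[:, 0:1] - b[None, :, 0], a[:, 1:2] - b[None, :, 1])


def _minutes(dist_m: np.ndarray, speed_kmh: float) -> np.ndarray:
    return dist_m / 1000.0 / speed_kmh * 60.0


def euclidean_matrix(
    demand: Sequence[DemandSite], supply: Sequence[SupplySite], mode: str = "euclidean"
) -> TravelCostMatrix:
    """Straight-line distance matrix (the distance-baseline model input)."""
    demand = sort_sites(demand)
    supply = sort_sites(supply)
    dist = _pairwise_dist(_xy(demand), _xy(supply))
    return TravelCostMatrix(
        mode=mode,
        origin_ids=[s.site_id for s in demand],
        dest_ids=[s.site_id for s in supply],
        cost=dist,
        metric="euclidean",
    )


def speed_time_matrix(
    demand: Sequence[DemandSite],
    supply: Sequence[SupplySite],
    model: ModeSpeedModel,
) -> TravelCostMatrix:
    """Per-mode travel-time matrix in minutes under a kinematic speed model."""
    demand = sort_sites(demand)
    supply = sort_sites(supply)
    d_xy = _xy(demand)
    s_xy = _xy(supply)
    dist = _pairwise_dist(d_xy, s_xy)

    if not model.corridors:
        minutes = model.fixed_overhead + _minutes(dist, model.cruise_speed)
    else:
        access = model.corridor_access_speed or model.cruise_speed
        minutes = _minutes(dist, access)  # pure-walk fallback
        for corridor in model.corridors:
            line = corridor.line
            # nearest-point projection of every site onto the line
            d_along = np.array([line.project(Point(p)) for p in d_xy])
            s_along = np.array([line.project(Point(p)) for p in s_xy])
            d_gap = np.array([line.distance(Point(p)) for p in d_xy])
            s_gap = np.array([line.distance(Point(p)) for p in s_xy])
            ride = _minutes(
                np.abs(d_along[:, None] - s_along[None, :]), corridor.line_speed
            )
            walk = _minutes(d_gap[:, None] + s_gap[None, :], access)
            option = model.fixed_overhead + walk + ride
            minutes = np.minimum(minutes, option)

    return TravelCostMatrix(
        mode=model.mode,
        origin_ids=[s.site_id for s in demand],
        dest_ids=[s.site_id for s in supply],
        cost=minutes,
        metric="time",
    )


def reachable_set(
    costs: TravelCostMatrix, origin_site: str, threshold: float
) -> set:
    """Destinations within ``threshold`` cost of ``origin_site`` (inclusive)."""
    if origin_site not in costs.origin_ids:
        raise KeyError(f"origin {origin_site!r} not in cost matrix")
    if not math.isfinite(threshold) or threshold < 0:
        raise ValueError(f"threshold must be finite and >= 0, got {threshold!r}")
    row = costs.cost[costs.origin_ids.index(origin_site)]
    return {j for j, c in zip(costs.dest_ids, row) if c <= threshold}
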