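"""Seeded synthetic-city generator.

Emulates the structure of a 13 x 10 km Chengdu-like district: 902
residential areas with census-scale populations, 31 parks with quality
scores, 17 administrative zones on a rectangular grid, and four travel
modes (driving, public transport, riding, walking) whose reach at the
39-minute threshold follows the calibrated speed models in
:mod:`parkaccess.travel`.  The park layout is deliberately uneven — a
configurable share of the total park area (default 70%) sits in a southern
band — so the generated city reproduces the qualitative
"high accessibility in the south, low in the north" gradient that the
model family is designed to expose.

Everything is drawn from one seeded generator: the same config and seed
give byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .travel import (
    DRIVE_SPEED_KMH,
    RIDE_SPEED_KMH,
    TRANSIT_LINE_SPEED_KMH,
    WALK_SPEED_KMH,
    ModeSpeedModel,
    TransitCorridor,
    speed_time_matrix,
)
from .types import DemandSite, ModeMix, SupplySite, TravelCostMatrix

__all__ = ["ScenarioConfig", "City", "generate_city", "generate_mode_costs", "default_speed_models"]


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of the synthetic city; defaults mirror the study-area scale."""

    seed: int = 42
    n_demand: int = 902
    n_supply: int = 31
    extent_km: Tuple[float, float] = (13.0, 10.0)
    #: zones per latitude row, north to south (sums to 17 by default)
    zone_rows: Tuple[int, ...] = (4, 4, 4, 5)
    #: fraction of total park area placed in the south band
    south_area_share: float = 0.7
    #: the south band is the southern ``south_band_frac`` of the extent
    south_band_frac: float = 0.4
    #: log-normal population: median (people) and sigma (log scale)
    pop_median: float = 1000.0
    pop_sigma: float = 0.8
    #: log-normal park area: median (m^2) and sigma
    area_median: float = 50_000.0
    area_sigma: float = 1.1
    #: uniform quality-score bounds (0-5 rating scale)
    score_bounds: Tuple[float, float] = (3.5, 5.0)
    threshold_minutes: float = 39.0
    n_corridors: int = 3

    def __post_init__(self) -> None:
        if self.n_demand <= 0 or self.n_supply <= 0:
            raise ValueError("site counts must be positive")
        if not 0.0 <= self.south_area_share <= 1.0:
            raise ValueError("south_area_share must lie in [0, 1]")
        if not 0.0 < self.south_band_frac < 1.0:
            raise ValueError("south_band_frac must lie in (0, 1)")
        if self.score_bounds[0] <= 0 or self.score_bounds[1] < self.score_bounds[0]:
            raise ValueError("score bounds must be positive and ordered")
        if self.threshold_minutes <= 0:
            raise ValueError("threshold must be positive")
        if any(c <= 0 for c in self.zone_rows):
            raise ValueError("zone_rows entries must be positive")


@dataclass
class City:
    """A generated scenario: sites, zone boxes, transit corridors."""

    demand: List[DemandSite]
    supply: List[SupplySite]
    #: zone_id -> (xmin, ymin, xmax, ymax) in meters
    zones: Dict[str, Tuple[float, float, float, float]]
    corridors: Tuple[TransitCorridor, ...]
    config: ScenarioConfig

    @property
    def south_limit_m(self) -> float:
        """y below which a site is in the "south" band."""
        return self.config.extent_km[1] * 1000.0 * self.config.south_band_frac


def _zone_boxes(config: ScenarioConfig) -> Dict[str, Tuple[float, float, float, float]]:
    w = config.extent_km[0] * 1000.0
    h = config.extent_km[1] * 1000.0
    n_rows = len(config.zone_rows)
    boxes = {}
    idx = 1
    # rows listed north to south; row 0 is the top (largest y)
    for r, ncols in enumerate(config.zone_rows):
        y_hi = h * (n_rows - r) / n_rows
        y_lo = h * (n_rows - r - 1) / n_rows
        for c in range(ncols):
            boxes[f"Z{idx:02d}"] = (w * c / ncols, y_lo, w * (c + 1) / ncols, y_hi)
            idx += 1
    return boxes


def _zone_of(x: float, y: float, boxes) -> str:
    for zid, (x0, y0, x1, y1) in boxes.items():
        if x0 <= x <= x1 and y0 <= y <= y1:
            return zid
    # boundary rounding: snap to the nearest box center
    return min(
        boxes,
        key=lambda z: (x - (boxes[z][0] + boxes[z][2]) / 2) ** 2
        + (y - (boxes[z][1] + boxes[z][3]) / 2) ** 2,
    )


def generate_city(config: ScenarioConfig) -> City:
    """Draw a full synthetic city from the config's seed."""
    rng = np.random.default_rng(config.seed)
    w = config.extent_km[0] * 1000.0
    h = config.extent_km[1] * 1000.0
    boxes = _zone_boxes(config)
    south_y = h * config.south_band_frac

    # residential areas: uniform over the extent
    d_xy = rng.uniform([0, 0], [w, h], size=(config.n_demand, 2))
    pops = config.pop_median * rng.lognormal(0.0, config.pop_sigma, config.n_demand)
    width = len(str(config.n_demand))
    demand = [
        DemandSite(
            site_id=f"R{i:0{width}d}",
            x=float(d_xy[i, 0]),
            y=float(d_xy[i, 1]),
            population=float(np.round(pops[i])),
            zone_id=_zone_of(d_xy[i, 0], d_xy[i, 1], boxes),
        )
        for i in range(config.n_demand)
    ]

    # parks: areas log-normal; the largest parks go south until the south
    # band holds the configured share of total area
    areas = config.area_median * rng.lognormal(0.0, config.area_sigma, config.n_supply)
    order = np.argsort(areas)[::-1]
    total = areas.sum()
    south_flags = np.zeros(config.n_supply, dtype=bool)
    acc = 0.0
    for j in order:
        if acc < config.south_area_share * total:
            south_flags[j] = True
            acc += areas[j]
    scores = rng.uniform(*config.score_bounds, config.n_supply)
    sx = rng.uniform(0, w, config.n_supply)
    sy = np.where(
        south_flags,
        rng.uniform(0, south_y, config.n_supply),
        rng.uniform(south_y, h, config.n_supply),
    )
    swidth = len(str(config.n_supply))
    supply = [
        SupplySite(
            site_id=f"P{j:0{swidth}d}",
            x=float(sx[j]),
            y=float(sy[j]),
            supply_scale=float(np.round(areas[j], 1)),
            weight=float(np.round(scores[j], 1)),
        )
        for j in range(config.n_supply)
    ]

    corridors = _make_corridors(rng, w, h, config.n_corridors)
    return City(demand=demand, supply=supply, zones=boxes, corridors=corridors, config=config)


def _make_corridors(rng, w: float, h: float, n: int) -> Tuple[TransitCorridor, ...]:
    """Transit lines crossing the extent: N-S, E-W, then diagonals, jittered."""
    lines = []
    templates = [
        ((0.5, 0.0), (0.5, 1.0)),   # north-south
        ((0.0, 0.5), (1.0, 0.5)),   # east-west
        ((0.0, 0.0), (1.0, 1.0)),   # diagonal
        ((0.0, 1.0), (1.0, 0.0)),   # anti-diagonal
    ]
    for k in range(n):
        (ax, ay), (bx, by) = templates[k % len(templates)]
        jitter = rng.uniform(-0.08, 0.08, 4)
        a = (np.clip(ax + jitter[0], 0, 1) * w, np.clip(ay + jitter[1], 0, 1) * h)
        mid = ((a[0] + (bx + jitter[2]) * w) / 2, (a[1] + (by + jitter[3]) * h) / 2)
        b = (np.clip(bx + jitter[2], 0, 1) * w, np.clip(by + jitter[3], 0, 1) * h)
        lines.append(TransitCorridor(coords=(a, mid, b), line_speed=TRANSIT_LINE_SPEED_KMH))
    return tuple(lines)


def default_speed_models(corridors: Sequence[TransitCorridor] = ()) -> Dict[str, ModeSpeedModel]:
    """The four calibrated mode models keyed by mode label."""
    return {
        "driving": ModeSpeedModel("driving", cruise_speed=DRIVE_SPEED_KMH),
        "transit": ModeSpeedModel(
            "transit",
            cruise_speed=WALK_SPEED_KMH,
            corridors=tuple(corridors),
            corridor_access_speed=WALK_SPEED_KMH,
        ),
        "riding": ModeSpeedModel("riding", cruise_speed=RIDE_SPEED_KMH),
        "walking": ModeSpeedModel("walking", cruise_speed=WALK_SPEED_KMH),
    }


def generate_mode_costs(city: City) -> Dict[str, TravelCostMatrix]:
    """One travel-time matrix per default mode, using the city's corridors."""
    models = default_speed_models(city.corridors)
    return {
        mode: speed_time_matrix(city.demand, city.supply, model)
        for mode, model in models.items()
    }
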