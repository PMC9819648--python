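"""Readers and writers for the on-disk formats.

Sites travel as CSV (demand: site_id,x,y,population[,zone_id]; supply:
site_id,x,y,area,score) or as GeoJSON Point features with the same
properties.  Origin-destination costs travel as long-format CSV
(origin_id,dest_id,mode,minutes); pairs absent from the file are
unreachable (+inf), never zero.  All floats are serialized with 12
significant digits so writer/reader round-trips are lossless at that
precision and output files are reproducible byte-for-byte.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, List, Sequence, Union

import numpy as np
import pandas as pd

from .scenario import City
from .types import DemandSite, SupplySite, TravelCostMatrix, sort_sites

__all__ = [
    "read_sites",
    "write_sites",
    "read_od",
    "write_od",
    "write_zones_geojson",
    "write_bundle",
    "fmt_float",
]

PathLike = Union[str, Path]

_DEMAND_COLS = ("site_id", "x", "y", "population")
_SUPPLY_COLS = ("site_id", "x", "y", "area", "score")


def fmt_float(x: float) -> str:
    """Canonical 12-significant-digit float rendering used in every writer."""
    if math.isinf(x):
        return "inf"
    return format(float(x), ".12g")


def _records_from_geojson(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    rows = []
    for k, feat in enumerate(gj.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ValueError(f"{path}: feature {k} is not a Point")
        x, y = geom["coordinates"][:2]
        rows.append({"x": x, "y": y, **(feat.get("properties") or {})})
    return pd.DataFrame(rows)


def read_sites(path: PathLike, role: str) -> List:
    """Load demand or supply sites from CSV or GeoJSON, sorted by site_id.

    Validation errors name the offending row; duplicate ids are rejected.
    """
    if role not in ("demand", "supply"):
        raise ValueError(f"role must be demand or supply, got {role!r}")
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        df = _records_from_geojson(path)
    else:
        df = pd.read_csv(path, dtype={"site_id": str, "zone_id": str})
    required = _DEMAND_COLS if role == "demand" else _SUPPLY_COLS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing} for role {role!r}")
    dup = df["site_id"].astype(str).duplicated()
    if dup.any():
        raise ValueError(
            f"{path}: duplicate site_id {df['site_id'][dup].iloc[0]!r} "
            f"(row {int(np.flatnonzero(dup)[0]) + 1})"
        )
    sites = []
    for k, row in df.iterrows():
        try:
            if role == "demand":
                zone = row.get("zone_id")
                if zone is not None and (isinstance(zone, float) and math.isnan(zone)):
                    zone = None
                sites.append(
                    DemandSite(
                        site_id=str(row["site_id"]),
                        x=float(row["x"]),
                        y=float(row["y"]),
                        population=float(row["population"]),
                        zone_id=None if zone is None else str(zone),
                    )
                )
            else:
                sites.append(
                    SupplySite(
                        site_id=str(row["site_id"]),
                        x=float(row["x"]),
                        y=float(row["y"]),
                        supply_scale=float(row["area"]),
                        weight=float(row["score"]),
                    )
                )
        except ValueError as e:
            raise ValueError(f"{path}: row {k + 1}: {e}") from e
    return sort_sites(sites)


def write_sites(sites: Sequence, path: PathLike) -> None:
    """Write sites as CSV (schema chosen by site type), sorted by id."""
    sites = sort_sites(sites)
    path = Path(path)
    with open(path, "w") as fh:
        if sites and isinstance(sites[0], DemandSite):
            fh.write("site_id,x,y,population,zone_id\n")
            for s in sites:
                fh.write(
                    f"{s.site_id},{fmt_float(s.x)},{fmt_float(s.y)},"
                    f"{fmt_float(s.population)},{s.zone_id or ''}\n"
                )
        else:
            fh.write("site_id,x,y,area,score\n")
            for s in sites:
                fh.write(
                    f"{s.site_id},{fmt_float(s.x)},{fmt_float(s.y)},"
                    f"{fmt_float(s.supply_scale)},{fmt_float(s.weight)}\n"
                )


def read_od(path: PathLike) -> Dict[str, TravelCostMatrix]:
    """Load long-format OD costs; one dense matrix per mode present.

    Pairs missing from the file become +inf (unreachable).  Negative
    minutes or NaN raise.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"origin_id": str, "dest_id": str, "mode": str})
    required = ["origin_id", "dest_id", "mode", "minutes"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    bad = df["minutes"] < 0
    if bad.any():
        k = int(np.flatnonzero(bad)[0])
        raise ValueError(f"{path}: row {k + 1}: negative minutes")
    if df["minutes"].isna().any():
        raise ValueError(f"{path}: minutes contains missing values")
    origins = sorted(df["origin_id"].unique())
    out = {}
    for mode, sub in df.groupby("mode"):
        dests = sorted(sub["dest_id"].unique())
        mat = np.full((len(origins), len(dests)), np.inf)
        oi = {o: k for k, o in enumerate(origins)}
        di = {d: k for k, d in enumerate(dests)}
        dupes = sub.duplicated(subset=["origin_id", "dest_id"])
        if dupes.any():
            row = sub[dupes].iloc[0]
            raise ValueError(
                f"{path}: duplicate OD pair ({row['origin_id']}, {row['dest_id']}) "
                f"for mode {mode!r}"
            )
        mat[
            sub["origin_id"].map(oi).to_numpy(), sub["dest_id"].map(di).to_numpy()
        ] = sub["minutes"].to_numpy()
        out[str(mode)] = TravelCostMatrix(
            mode=str(mode), origin_ids=origins, dest_ids=dests, cost=mat, metric="time"
        )
    return out


def write_od(matrices: Union[Dict[str, TravelCostMatrix], TravelCostMatrix], path: PathLike) -> None:
    """Write one or several cost matrices as long-format CSV.

    +inf entries (unreachable) are omitted, matching the read convention.
    """
    if isinstance(matrices, TravelCostMatrix):
        matrices = {matrices.mode: matrices}
    with open(Path(path), "w") as fh:
        fh.write("origin_id,dest_id,mode,minutes\n")
        for mode in sorted(matrices):
            m = matrices[mode]
            for i, o in enumerate(m.origin_ids):
                for j, d in enumerate(m.dest_ids):
                    c = m.cost[i, j]
                    if math.isinf(c):
                        continue
                    fh.write(f"{o},{d},{mode},{fmt_float(c)}\n")


def write_zones_geojson(zones: Dict[str, tuple], path: PathLike) -> None:
    """Write zone bounding boxes as a GeoJSON FeatureCollection of Polygons."""
    feats = []
    for zid in sorted(zones):
        x0, y0, x1, y1 = zones[zid]
        ring = [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
        feats.append(
            {
                "type": "Feature",
                "properties": {"zone_id": zid},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    with open(Path(path), "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)
        fh.write("\n")


def write_bundle(city: City, costs: Dict[str, TravelCostMatrix], outdir: PathLike) -> List[Path]:
    """Write the standard fixture bundle for a generated city.

    demand.csv, supply.csv, zones.geojson, od_<mode>.csv and scenario.config
    (the flat key-value record of the generating configuration).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    write_sites(city.demand, outdir / "demand.csv")
    written.append(outdir / "demand.csv")
    write_sites(city.supply, outdir / "supply.csv")
    written.append(outdir / "supply.csv")
    write_zones_geojson(city.zones, outdir / "zones.geojson")
    written.append(outdir / "zones.geojson")
    for mode in sorted(costs):
        p = outdir / f"od_{mode}.csv"
        write_od(costs[mode], p)
        written.append(p)
    cfgpath = outdir / "scenario.config"
    c = city.config
    with open(cfgpath, "w") as fh:
        fh.write(f"seed: {c.seed}\n")
        fh.write(f"n_demand: {c.n_demand}\n")
        fh.write(f"n_supply: {c.n_supply}\n")
        fh.write(f"extent_km: [{fmt_float(c.extent_km[0])}, {fmt_float(c.extent_km[1])}]\n")
        fh.write(f"south_area_share: {fmt_float(c.south_area_share)}\n")
        fh.write(f"threshold_minutes: {fmt_float(c.threshold_minutes)}\n")
    written.append(cfgpath)
    return written
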