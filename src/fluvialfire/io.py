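"""Readers and writers for the package's on-disk schemas.

Networks, scars and ecoregions travel as GeoJSON-style FeatureCollections
(planar km coordinates); sonde series and tabular outputs as tidy CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .types import (
    BurnScar,
    EcoregionMap,
    FireImpactRecord,
    SondeSeries,
    StreamNetwork,
    StreamSegment,
)


def _dump(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1))


def _load(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# stream networks


def write_network(network: StreamNetwork, path) -> None:
    features = []
    for seg in network.segments:
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[float(x), float(y)] for x, y in seg.coords],
                },
                "properties": {
                    "segment_id": seg.segment_id,
                    "strahler_order": seg.strahler_order,
                    "parent_id": network.topology.get(seg.segment_id),
                },
            }
        )
    fc = {"type": "FeatureCollection", "features": features}
    if network.region is not None:
        fc["bbox"] = list(network.region)
    _dump(fc, path)


def read_network(path) -> StreamNetwork:
    fc = _load(path)
    segments, topology = [], {}
    for f in fc["features"]:
        props = f["properties"]
        segments.append(
            StreamSegment(
                segment_id=props["segment_id"],
                coords=np.asarray(f["geometry"]["coordinates"], dtype=float),
                strahler_order=props.get("strahler_order"),
            )
        )
        topology[props["segment_id"]] = props.get("parent_id")
    region = tuple(fc["bbox"]) if "bbox" in fc else None
    return StreamNetwork(segments=segments, topology=topology, region=region)


# ---------------------------------------------------------------------------
# burn scars


def write_scars(scars: list[BurnScar], path) -> None:
    features = []
    for scar in scars:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(scar.perimeter),
                "properties": {
                    "fire_id": scar.fire_id,
                    "year": scar.year,
                    "severity_class": None,
                },
            }
        )
        for cls, patch in scar.severity_patches:
            if patch.is_empty:
                continue
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(patch),
                    "properties": {
                        "fire_id": scar.fire_id,
                        "year": scar.year,
                        "severity_class": cls,
                    },
                }
            )
    _dump({"type": "FeatureCollection", "features": features}, path)


def read_scars(path) -> list[BurnScar]:
    fc = _load(path)
    perimeters: dict[str, dict] = {}
    patches: dict[str, list] = {}
    order: list[str] = []
    for f in fc["features"]:
        props = f["properties"]
        fid = props["fire_id"]
        if props.get("severity_class") is None:
            perimeters[fid] = {"year": props["year"], "geom": shape(f["geometry"])}
            order.append(fid)
        else:
            patches.setdefault(fid, []).append(
                (props["severity_class"], shape(f["geometry"]))
            )
    return [
        BurnScar(
            fire_id=fid,
            year=perimeters[fid]["year"],
            perimeter=perimeters[fid]["geom"],
            severity_patches=patches.get(fid, []),
        )
        for fid in order
    ]


# ---------------------------------------------------------------------------
# ecoregions


def write_ecoregions(emap: EcoregionMap, path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(emap.regions[name]),
            "properties": {"name": name},
        }
        for name in emap.names
    ]
    fc = {"type": "FeatureCollection", "features": features}
    if emap.region is not None:
        fc["bbox"] = list(emap.region)
    _dump(fc, path)


def read_ecoregions(path) -> EcoregionMap:
    fc = _load(path)
    regions = {
        f["properties"]["name"]: shape(f["geometry"]) for f in fc["features"]
    }
    region = tuple(fc["bbox"]) if "bbox" in fc else None
    return EcoregionMap(regions=regions, region=region)


# ---------------------------------------------------------------------------
# sonde series


def write_do_series(series: list[SondeSeries], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "station_id": s.station_id,
                "distance_km": s.distance_km,
                "timestamp": s.times.strftime("%Y-%m-%dT%H:%M:%S"),
                "do_mgl": s.do_mgl,
            }
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_do_series(path) -> list[SondeSeries]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for sid, sub in df.groupby("station_id", sort=False):
        sub = sub.sort_values("timestamp")
        out.append(
            SondeSeries(
                station_id=str(sid),
                distance_km=float(sub["distance_km"].iloc[0]),
                times=pd.DatetimeIndex(sub["timestamp"]),
                do_mgl=sub["do_mgl"].to_numpy(),
            )
        )
    return sorted(out, key=lambda s: s.distance_km)


# ---------------------------------------------------------------------------
# tabular outputs


def write_fire_impacts(
    records: list[FireImpactRecord],
    path,
    centroids: Optional[dict[str, tuple[float, float]]] = None,
) -> None:
    rows = []
    for r in records:
        row = {
            "fire_id": r.fire_id,
            "year": r.year,
            "ecoregion": r.ecoregion,
            "burned_area_km2": r.burned_area_km2,
            "sl_ba_km": r.sl_ba_km,
        }
        if centroids and r.fire_id in centroids:
            row["centroid_x_km"], row["centroid_y_km"] = centroids[r.fire_id]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fire_impacts(path) -> pd.DataFrame:
    return pd.read_csv(path)
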