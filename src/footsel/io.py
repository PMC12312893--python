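"""Readers and writers for the pipeline's on-disk formats.

Telemetry is CSV (animal_id, timestamp ISO-8601 UTC, x, y in projected
metres).  Vector layers are GeoJSON with a ``class`` property naming the
infrastructure class.  Rasters are ESRI ASCII grids (see :mod:`footsel.grid`).
"""

from __future__ import annotations

import json

import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

TELEMETRY_COLUMNS = ["animal_id", "timestamp", "x", "y"]


def write_telemetry(fixes: pd.DataFrame, path) -> None:
    df = fixes.copy()
    ts = pd.to_datetime(df["timestamp"], utc=True)
    df["timestamp"] = ts.dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    df[TELEMETRY_COLUMNS].to_csv(path, index=False)


def read_telemetry(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TELEMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"telemetry file {path} lacks columns {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df[TELEMETRY_COLUMNS]


def write_geojson_features(layers: dict[str, list[BaseGeometry]], path) -> None:
    """Write class-keyed geometry layers as one GeoJSON FeatureCollection."""
    features = []
    for cls, geoms in layers.items():
        for geom in geoms:
            features.append(
                {"type": "Feature", "properties": {"class": cls},
                 "geometry": mapping(geom)}
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson_features(path) -> dict[str, list[BaseGeometry]]:
    with open(path) as fh:
        collection = json.load(fh)
    layers: dict[str, list[BaseGeometry]] = {}
    for feat in collection.get("features", []):
        cls = feat.get("properties", {}).get("class")
        if cls is None:
            raise ValueError(f"feature without a 'class' property in {path}")
        layers.setdefault(cls, []).append(shape(feat["geometry"]))
    return layers


def write_geojson_polygon(polygon: BaseGeometry, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"type": "Feature", "properties": {}, "geometry": mapping(polygon)}, fh
        )


def read_geojson_polygon(path) -> BaseGeometry:
    with open(path) as fh:
        feat = json.load(fh)
    geom = feat["geometry"] if feat.get("type") == "Feature" else feat
    poly = shape(geom)
    if not poly.is_valid:
        poly = shapely.make_valid(poly)
    return poly
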