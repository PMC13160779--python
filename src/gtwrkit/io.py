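"""Plain-text I/O: GeoJSON region geometries, delimited panels and series."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .errors import InvalidArgumentError
from .synth import STREAM_NAMES, ComponentSeries, RegionGeometry

__all__ = [
    "write_regions_geojson",
    "read_regions_geojson",
    "write_panel",
    "read_panel",
    "write_component_series",
    "read_component_series",
]


def write_regions_geojson(regions: list[RegionGeometry], path, properties=None) -> None:
    """GeoJSON FeatureCollection in planar km coordinates.

    ``properties`` optionally maps region_id -> extra property dict (e.g.
    LISA classes for mapping).
    """
    features = []
    for r in regions:
        props = {"region_id": r.region_id, "centroid_u": r.centroid[0], "centroid_v": r.centroid[1]}
        if properties and r.region_id in properties:
            props.update(properties[r.region_id])
        features.append(
            {"type": "Feature", "geometry": mapping(r.polygon), "properties": props}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_regions_geojson(path) -> list[RegionGeometry]:
    with open(path) as fh:
        fc = json.load(fh)
    regions = []
    for feat in fc["features"]:
        poly = shape(feat["geometry"])
        props = feat.get("properties", {})
        rid = props.get("region_id")
        if rid is None:
            raise InvalidArgumentError(f"feature without region_id in {path}")
        cen = (
            (props["centroid_u"], props["centroid_v"])
            if "centroid_u" in props
            else (poly.centroid.x, poly.centroid.y)
        )
        regions.append(RegionGeometry(region_id=rid, polygon=poly, centroid=cen))
    return regions


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_component_series(series: ComponentSeries, path) -> None:
    """Long form: month, stream, percent_change."""
    rows = [
        {"month": int(m), "stream": name, "percent_change": float(series.streams[name][t])}
        for t, m in enumerate(series.months)
        for name in STREAM_NAMES
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_component_series(path) -> ComponentSeries:
    df = pd.read_csv(path)
    months = np.array(sorted(df["month"].unique()))
    streams = {}
    for name in STREAM_NAMES:
        sub = df[df["stream"] == name].sort_values("month")
        streams[name] = sub["percent_change"].to_numpy()
    return ComponentSeries(months=months, streams=streams)
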