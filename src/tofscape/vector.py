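"""Vector helpers: GeoJSON round-trip and pixel-center rasterization.

Polygons are shapely geometries in the same planar coordinate system as the
rasters.  Rasterization uses the pixel-center rule: a pixel belongs to a
polygon iff its center point falls inside (or on the boundary of) the
geometry, matching the convention of standard burn-in tools.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import shape as shapely_shape, mapping as shapely_mapping
from shapely.geometry.base import BaseGeometry

from .grid import RasterGrid

__all__ = [
    "rasterize_polygons",
    "polygon_mask",
    "read_geojson",
    "write_geojson",
    "validate_geometries",
]


def validate_geometries(geoms: Sequence[BaseGeometry]) -> None:
    for i, g in enumerate(geoms):
        if g is None or g.is_empty:
            continue
        if not g.is_valid:
            raise ValueError(f"invalid geometry at index {i}: {shapely.is_valid_reason(g)}")


def polygon_mask(grid: RasterGrid, geoms: Sequence[BaseGeometry]) -> np.ndarray:
    """Boolean array: True where the pixel center lies inside any geometry."""
    validate_geometries(geoms)
    out = np.zeros(grid.shape, dtype=bool)
    live = [g for g in geoms if g is not None and not g.is_empty]
    if not live:
        return out
    xs, ys = grid.cell_centers()
    union = shapely.union_all(live)
    # covers = contains-or-touches; boundary pixels count as inside
    out = shapely.intersects(union, shapely.points(xs, ys))
    return np.asarray(out, dtype=bool)


def rasterize_polygons(
    grid: RasterGrid, labeled: Mapping[str, BaseGeometry]
) -> tuple[np.ndarray, list[str]]:
    """Burn labeled polygons into an int zone map (0 = outside all).

    Later entries overwrite earlier ones where polygons overlap.  Returns the
    zone array and the label list (zone k <-> labels[k-1]).
    """
    zones = np.zeros(grid.shape, dtype=np.int32)
    labels = list(labeled.keys())
    for k, name in enumerate(labels, start=1):
        zones[polygon_mask(grid, [labeled[name]])] = k
    return zones, labels


def read_geojson(path: str | Path) -> list[tuple[dict, BaseGeometry]]:
    """Read a GeoJSON FeatureCollection as (properties, geometry) pairs."""
    doc = json.loads(Path(path).read_text())
    if doc.get("type") == "FeatureCollection":
        feats = doc["features"]
    elif doc.get("type") == "Feature":
        feats = [doc]
    else:  # bare geometry
        feats = [{"properties": {}, "geometry": doc}]
    return [(f.get("properties") or {}, shapely_shape(f["geometry"])) for f in feats]


def write_geojson(
    path: str | Path,
    features: Sequence[tuple[Mapping, BaseGeometry]],
) -> None:
    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": dict(props),
                "geometry": shapely_mapping(geom),
            }
            for props, geom in features
        ],
    }
    Path(path).write_text(json.dumps(doc))
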