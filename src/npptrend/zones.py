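"""Polygon zone handling: GeoJSON loading and pixel-membership masks.

Zones are administrative or analysis units (e.g. counties) used for zonal
aggregation and regional summaries.  A pixel belongs to a zone when its
center falls inside the polygon (pixel-is-area convention).
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import shape as geojson_shape

from .raster_core import RasterGrid

__all__ = ["load_zones", "zones_from_geojson", "zone_pixel_mask", "square_grid_zones"]


def zones_from_geojson(obj: dict, id_property: str = "zone_id") -> list[tuple]:
    """(id, geometry) pairs from a GeoJSON FeatureCollection dict.

    Falls back to the feature index when ``id_property`` is absent.
    """
    feats = obj.get("features", [])
    out = []
    for k, f in enumerate(feats):
        props = f.get("properties") or {}
        zid = props.get(id_property, f.get("id", k))
        out.append((zid, geojson_shape(f["geometry"])))
    return out


def load_zones(path, id_property: str = "zone_id") -> list[tuple]:
    """Read zones from a GeoJSON file."""
    with open(path) as fh:
        return zones_from_geojson(json.load(fh), id_property)


def zone_pixel_mask(grid: RasterGrid, geom) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside ``geom``."""
    rows, cols = grid.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x, y = grid.transform.pixel_center(rr.ravel(), cc.ravel())
    inside = shapely.contains_xy(geom, x, y)
    return inside.reshape(rows, cols)


def square_grid_zones(n_rows: int, n_cols: int, size: float = 1.0,
                      x0: float = 0.0, y0: float = 0.0) -> list[tuple]:
    """Regular lattice of square polygons, ids row-major from 0.

    ``y0`` is the TOP edge; rows go southward, matching raster order.
    Handy for tests and synthetic county layers.
    """
    from shapely.geometry import box

    zones = []
    for r in range(n_rows):
        for c in range(n_cols):
            zones.append((r * n_cols + c,
                          box(x0 + c * size, y0 - (r + 1) * size,
                              x0 + (c + 1) * size, y0 - r * size)))
    return zones
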