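"""Grid/stack data model, alignment checks, temporal aggregation and masking.

The package works on stacks of co-registered single-band rasters, one grid
per time step (typically one per year).  All per-pixel statistics elsewhere
in the package consume these containers.  Georeferencing follows the usual
north-up raster convention: row-major arrays, pixel-is-area, and a
six-parameter affine transform mapping (col, row) to projected coordinates.

I/O is single-band GeoTIFF (float32 for continuous variables, unsigned
integer for categorical maps) with the nodata sentinel declared in the file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import tifffile

__all__ = [
    "Affine",
    "RasterGrid",
    "RasterStack",
    "SeasonScheme",
    "check_aligned",
    "aggregate",
    "fluctuation_zone_mask",
    "read_grid",
    "read_stack",
    "write_grid",
]

# GeoTIFF tag codes used for round-tripping georeferencing through tifffile.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class Affine(NamedTuple):
    """Six-parameter affine transform, GDAL ordering.

    x = c + a*col + b*row ;  y = f + d*col + e*row.
    For north-up grids b = d = 0, a = cell width > 0, e = cell height < 0.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def north_up(cls, x0: float, y0: float, dx: float, dy: float) -> "Affine":
        """Transform for a north-up grid with top-left corner (x0, y0)."""
        return cls(dx, 0.0, x0, 0.0, -abs(dy), y0)

    def pixel_center(self, row: np.ndarray, col: np.ndarray):
        x = self.c + self.a * (col + 0.5) + self.b * (row + 0.5)
        y = self.f + self.d * (col + 0.5) + self.e * (row + 0.5)
        return x, y


@dataclass
class RasterGrid:
    """One georeferenced 2D field with a missing-data sentinel.

    ``values`` holds reals for continuous variables or integer class codes
    for categorical maps.  ``cell_area`` is the area of one cell in km²;
    area-weighted summaries multiply pixel counts by it.
    """

    values: np.ndarray
    nodata: float = float(np.nan)
    transform: Affine = Affine.north_up(0.0, 0.0, 1.0, 1.0)
    crs_id: str = "EPSG:4326"
    cell_area: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("grid must be 2D with dimensions >= 1x1")
        if not self.cell_area > 0:
            raise ValueError("cell_area must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of non-nodata pixels."""
        v = self.values
        if np.isnan(self.nodata):
            return ~np.isnan(v.astype(float))
        return v != self.nodata

    def masked(self) -> np.ndarray:
        """Float copy with nodata replaced by NaN."""
        out = self.values.astype(float, copy=True)
        out[~self.valid_mask()] = np.nan
        return out

    def with_values(self, values: np.ndarray, nodata: float | None = None) -> "RasterGrid":
        g = replace(self, values=values)
        if nodata is not None:
            g.nodata = nodata
        return g


@dataclass
class RasterStack:
    """Time-ordered, spatially aligned sequence of grids for one variable.

    ``times`` are sortable labels (years as ints, or ``(year, season)``
    tuples, or ``(year, month)``).  Per-pixel statistics that divide by n−2
    require at least three steps.
    """

    grids: list[RasterGrid]
    times: list
    variable: str = ""

    def __post_init__(self):
        if len(self.grids) != len(self.times):
            raise ValueError("grids and times must have equal length")
        if len(self.grids) == 0:
            raise ValueError("empty stack")
        t = list(self.times)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("times must be strictly increasing with no duplicates")
        ref = self.grids[0]
        for g in self.grids[1:]:
            if g.shape != ref.shape or g.transform != ref.transform \
                    or g.crs_id != ref.crs_id or not _same_nodata(g.nodata, ref.nodata):
                raise ValueError("all grids in a stack must share shape/transform/crs/nodata")

    def __len__(self) -> int:
        return len(self.grids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grids[0].shape

    @property
    def template(self) -> RasterGrid:
        return self.grids[0]

    def as_cube(self) -> np.ndarray:
        """(n_time, rows, cols) float cube with nodata as NaN."""
        return np.stack([g.masked() for g in self.grids], axis=0)


def _same_nodata(a: float, b: float) -> bool:
    return (np.isnan(a) and np.isnan(b)) or a == b


# ---------------------------------------------------------------------------
# Season scheme and temporal aggregation
# ---------------------------------------------------------------------------

#: Meteorological seasons; December grouped with Jan/Feb of the same
#: calendar year so that every year in the record has four complete seasons.
METEOROLOGICAL_SEASONS = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}

SEASON_ORDER = ("winter", "spring", "summer", "autumn")


@dataclass
class SeasonScheme:
    """Month→season mapping plus the aggregation rule for one variable.

    ``rule`` is "sum" (fluxes such as productivity or precipitation) or
    "mean" (states such as surface temperature).
    """

    month_to_season: dict = field(default_factory=lambda: dict(METEOROLOGICAL_SEASONS))
    rule: str = "sum"

    def __post_init__(self):
        missing = sorted(set(range(1, 13)) - set(self.month_to_season))
        if missing:
            raise ValueError(f"months {missing} not assigned to any season")
        if self.rule not in ("sum", "mean"):
            raise ValueError(f"unknown aggregation rule {self.rule!r}")


def check_aligned(stacks: Sequence[RasterStack]) -> bool:
    """True iff all stacks share grid geometry, nodata and time labels."""
    if len(stacks) == 0:
        raise ValueError("need at least one stack")
    ref = stacks[0]
    for s in stacks[1:]:
        if list(s.times) != list(ref.times):
            return False
        g, r = s.template, ref.template
        if g.shape != r.shape or g.transform != r.transform \
                or g.crs_id != r.crs_id or not _same_nodata(g.nodata, r.nodata):
            return False
    return True


def aggregate(monthly: RasterStack, scheme: SeasonScheme) -> tuple[RasterStack, RasterStack]:
    """Collapse a monthly stack to seasonal and annual stacks.

    Seasonal value = rule applied over the season's months of that year;
    annual value = rule over all 12 months.  A pixel is nodata in an output
    grid whenever any contributing month is nodata there.
    """
    by_year: dict[int, dict[int, RasterGrid]] = {}
    for g, t in zip(monthly.grids, monthly.times):
        year, month = t
        by_year.setdefault(year, {})[month] = g

    tpl = monthly.template
    seasonal_grids, seasonal_times = [], []
    annual_grids, annual_times = [], []
    for year in sorted(by_year):
        months = by_year[year]
        missing = sorted(set(range(1, 13)) - set(months))
        if missing:
            raise ValueError(f"year {year} is missing months {missing}")
        for si, season in enumerate(SEASON_ORDER):
            mlist = [m for m, s in scheme.month_to_season.items() if s == season]
            seasonal_grids.append(_reduce([months[m] for m in mlist], scheme.rule, tpl))
            seasonal_times.append((year, si, season))
        annual_grids.append(_reduce([months[m] for m in range(1, 13)], scheme.rule, tpl))
        annual_times.append(year)

    seasonal = RasterStack(seasonal_grids, seasonal_times, monthly.variable)
    annual = RasterStack(annual_grids, annual_times, monthly.variable)
    return seasonal, annual


def _reduce(grids: list[RasterGrid], rule: str, template: RasterGrid) -> RasterGrid:
    cube = np.stack([g.masked() for g in grids], axis=0)
    with np.errstate(invalid="ignore"):
        out = cube.sum(axis=0) if rule == "sum" else cube.mean(axis=0)
    out[np.isnan(cube).any(axis=0)] = np.nan
    g = RasterGrid(out, nodata=np.nan, transform=template.transform,
                   crs_id=template.crs_id, cell_area=template.cell_area)
    if not np.isnan(template.nodata):
        v = out.copy()
        v[np.isnan(v)] = template.nodata
        g = RasterGrid(v, nodata=template.nodata, transform=template.transform,
                       crs_id=template.crs_id, cell_area=template.cell_area)
    return g


# ---------------------------------------------------------------------------
# Fluctuation zone
# ---------------------------------------------------------------------------

def fluctuation_zone_mask(annual_precip: RasterStack, threshold: float = 400.0) -> RasterGrid:
    """Mask of pixels swept by the annual ``threshold``-mm precipitation line.

    A pixel is in the zone iff its annual precipitation is >= threshold in at
    least one year AND < threshold in at least one other, i.e. the isohyet
    crosses it at least once over the record.  The default 400 mm is the
    semi-humid/semi-arid divide.  Pixels with any nodata year are excluded.
    """
    if len(annual_precip) < 2:
        raise ValueError("fluctuation zone needs at least two annual grids")
    cube = annual_precip.as_cube()
    valid = ~np.isnan(cube).any(axis=0)
    with np.errstate(invalid="ignore"):
        above = (cube >= threshold).any(axis=0)
        below = (cube < threshold).any(axis=0)
    mask = above & below & valid
    tpl = annual_precip.template
    return RasterGrid(mask.astype(np.uint8), nodata=255, transform=tpl.transform,
                      crs_id=tpl.crs_id, cell_area=tpl.cell_area)


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def write_grid(grid: RasterGrid, path) -> None:
    """Write one grid as a single-band GeoTIFF.

    Georeferencing goes into the standard GeoTIFF tags (pixel scale,
    tiepoint, GDAL nodata); crs id and cell area ride in the image
    description.  Values round-trip bit-exactly (dtype is preserved).
    """
    t = grid.transform
    if t.b != 0 or t.d != 0:
        raise ValueError("only north-up (non-rotated) transforms are written")
    desc = json.dumps({"crs_id": grid.crs_id, "cell_area": grid.cell_area})
    if np.isnan(grid.nodata):
        nodata_str = "nan"
    else:
        nd = float(grid.nodata)
        nodata_str = str(int(nd)) if nd.is_integer() else repr(nd)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (abs(t.a), abs(t.e), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.c, t.f, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, nodata_str),
    ]
    tifffile.imwrite(path, grid.values, description=desc, extratags=extratags)


def read_grid(path) -> RasterGrid:
    """Read a single-band GeoTIFF written by :func:`write_grid` (or similar)."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray()
        tags = page.tags
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value if _TAG_MODEL_PIXEL_SCALE in tags else (1.0, 1.0, 0.0)
        tie = tags[_TAG_MODEL_TIEPOINT].value if _TAG_MODEL_TIEPOINT in tags else (0, 0, 0, 0.0, 0.0, 0.0)
        nodata = np.nan
        if _TAG_GDAL_NODATA in tags:
            s = tags[_TAG_GDAL_NODATA].value
            nodata = float("nan") if s.strip().lower() == "nan" else float(s)
        crs_id, cell_area = "EPSG:4326", 1.0
        if "ImageDescription" in tags:
            try:
                meta = json.loads(tags["ImageDescription"].value)
                crs_id = meta.get("crs_id", crs_id)
                cell_area = float(meta.get("cell_area", cell_area))
            except (ValueError, TypeError):
                pass
    transform = Affine(scale[0], 0.0, tie[3], 0.0, -abs(scale[1]), tie[4])
    return RasterGrid(values, nodata=nodata, transform=transform,
                      crs_id=crs_id, cell_area=cell_area)


def read_stack(paths: Iterable, variable: str, times: Sequence | None = None) -> RasterStack:
    """Read an ordered list of single-band files into one stack.

    ``times`` defaults to 0..n−1.  Inputs must agree on shape, transform,
    crs and nodata; a mismatch raises.
    """
    grids = [read_grid(p) for p in paths]
    if not grids:
        raise ValueError("no input paths")
    if times is None:
        times = list(range(len(grids)))
    return RasterStack(grids, list(times), variable)
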