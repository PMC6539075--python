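"""Second-order partial correlation between two raster time series.

Vegetation productivity responds to several covarying climate drivers at
once, so the plain correlation between productivity and any single driver is
confounded by the others.  The second-order partial correlation removes the
linear influence of two control variables by recursion on first-order
coefficients:

    r_xy·1  = (r_xy − r_x1·r_y1) / √(1−r_x1²)·√(1−r_y1²)
    r_xy·12 = (r_xy·1 − r_x2·1·r_y2·1) / √(1−r_x2·1²)·√(1−r_y2·1²)

which is algebraically identical to correlating the residuals of x and y
after regressing each on both controls.  Significance uses

    T = r·√(n−q−1) / √(1−r²),   df = n − q − 1,

with q the number of control variables (q = 2 here, so df = n − 3).  Note
the more common convention for a second-order partial correlation is
df = n − 4; ``df_offset`` restores it if wanted.  p-values are two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .raster_core import RasterGrid, RasterStack, check_aligned
from .zones import zone_pixel_mask

__all__ = [
    "UndefinedCorrelationError",
    "PartialCorrSurface",
    "SIG_CLASSES",
    "pearson_r",
    "partial_r_first",
    "partial_r_second",
    "partial_t_test",
    "partial_corr_map",
    "regional_summary",
]

SIG_CLASSES = {1: "sig-positive", 2: "nonsig", 3: "sig-negative", 0: "nodata"}


class UndefinedCorrelationError(ValueError):
    """A correlation is undefined (zero variance, or |r| = 1 mid-recursion)."""


@dataclass
class PartialCorrSurface:
    """Per-pixel second-order partial correlation of target vs y."""

    r: RasterGrid
    t_stat: RasterGrid
    p_value: RasterGrid
    sig_class: RasterGrid  # codes per SIG_CLASSES
    target_name: str
    y_name: str
    control_names: tuple[str, str]
    n: int
    alpha: float = 0.01


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("series must have equal length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    den = math.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if den == 0:
        raise UndefinedCorrelationError("zero variance in pearson_r")
    return float((xc * yc).sum() / den)


def partial_r_first(r_xy: float, r_x1: float, r_y1: float) -> float:
    """First-order partial correlation of x,y controlling for variable 1."""
    den = math.sqrt(1 - r_x1 ** 2) * math.sqrt(1 - r_y1 ** 2)
    if den == 0:
        raise UndefinedCorrelationError("|r| = 1 with a control variable")
    return (r_xy - r_x1 * r_y1) / den


def partial_r_second(x, y, c1, c2) -> float:
    """Second-order partial correlation of x,y controlling for c1 and c2."""
    x, y, c1, c2 = (np.asarray(v, dtype=float) for v in (x, y, c1, c2))
    if not (x.size == y.size == c1.size == c2.size):
        raise ValueError("all four series must share one length")
    if x.size < 5:
        raise ValueError("need n >= 5 for two controls")
    r_xy = pearson_r(x, y)
    r_x1 = pearson_r(x, c1)
    r_y1 = pearson_r(y, c1)
    r_x2 = pearson_r(x, c2)
    r_y2 = pearson_r(y, c2)
    r_12 = pearson_r(c1, c2)
    r_xy_1 = partial_r_first(r_xy, r_x1, r_y1)
    r_x2_1 = partial_r_first(r_x2, r_x1, r_12)
    r_y2_1 = partial_r_first(r_y2, r_y1, r_12)
    return partial_r_first(r_xy_1, r_x2_1, r_y2_1)


def partial_t_test(r: float, n: int, q: int = 2, df_offset: int = 0) -> tuple[float, float]:
    """T statistic and two-sided p for a partial correlation coefficient.

    df = n − q − 1 + df_offset; the default offset 0 follows the printed
    formula with q = number of control variables.  |r| = 1 gives T = ±inf,
    p = 0.
    """
    df = n - q - 1 + df_offset
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if abs(r) >= 1.0:
        return math.copysign(math.inf, r), 0.0
    t = r * math.sqrt(df) / math.sqrt(1 - r ** 2)
    p = 2 * stats.t.sf(abs(t), df)
    return t, float(p)


# ---------------------------------------------------------------------------
# Per-pixel maps
# ---------------------------------------------------------------------------

def _corr_fields(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r along axis 0 of two (n, rows, cols) cubes, NaN where undefined."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        den = np.sqrt((ac ** 2).sum(axis=0) * (bc ** 2).sum(axis=0))
        return np.where(den > 0, (ac * bc).sum(axis=0) / den, np.nan)


def _partial_first_fields(r_xy, r_x1, r_y1):
    with np.errstate(invalid="ignore", divide="ignore"):
        den = np.sqrt((1 - r_x1 ** 2) * (1 - r_y1 ** 2))
        return np.where(den > 0, (r_xy - r_x1 * r_y1) / den, np.nan)


def partial_corr_map(target: RasterStack, y: RasterStack,
                     controls: tuple[RasterStack, RasterStack],
                     alpha: float = 0.01, q: int = 2,
                     df_offset: int = 0) -> PartialCorrSurface:
    """Per-pixel second-order partial correlation map with T significance.

    ``target`` and ``y`` are the correlated pair (e.g. NPP and
    precipitation); ``controls`` are the two variables regressed away (e.g.
    ET and LST).  Pixels where any series is constant or has missing steps
    come out as nodata.  Default alpha 0.01 matches the usual mapping
    threshold for these surfaces.
    """
    c1, c2 = controls
    stacks = [target, y, c1, c2]
    if not check_aligned(stacks):
        raise ValueError("input stacks are not aligned")
    n = len(target)
    if n < 5:
        raise ValueError("need n >= 5 time steps")

    cubes = [s.as_cube() for s in stacks]
    ok = ~np.any([np.isnan(c).any(axis=0) for c in cubes], axis=0)
    tx, ty, tc1, tc2 = cubes

    r_xy = _corr_fields(tx, ty)
    r_x1 = _corr_fields(tx, tc1)
    r_y1 = _corr_fields(ty, tc1)
    r_x2 = _corr_fields(tx, tc2)
    r_y2 = _corr_fields(ty, tc2)
    r_12 = _corr_fields(tc1, tc2)

    r_xy_1 = _partial_first_fields(r_xy, r_x1, r_y1)
    r_x2_1 = _partial_first_fields(r_x2, r_x1, r_12)
    r_y2_1 = _partial_first_fields(r_y2, r_y1, r_12)
    r = _partial_first_fields(r_xy_1, r_x2_1, r_y2_1)
    r = np.where(ok, r, np.nan)
    # fp dust can push |r| a hair over 1 on degenerate pixels
    r = np.clip(r, -1.0, 1.0)

    df = n - q - 1 + df_offset
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df) / np.sqrt(1 - r ** 2)
    p = np.where(np.isnan(t), np.nan, np.where(np.isinf(t), 0.0,
                 2 * stats.t.sf(np.abs(np.where(np.isinf(t), 0.0, t)), df)))

    cls = np.zeros(r.shape, dtype=np.uint8)
    valid = ~np.isnan(r) & ~np.isnan(p)
    cls[valid & (p < alpha) & (r > 0)] = 1
    cls[valid & (p >= alpha)] = 2
    cls[valid & (p < alpha) & (r <= 0)] = 3

    tpl = target.template
    return PartialCorrSurface(
        r=tpl.with_values(r, nodata=np.nan),
        t_stat=tpl.with_values(t, nodata=np.nan),
        p_value=tpl.with_values(p, nodata=np.nan),
        sig_class=tpl.with_values(cls, nodata=0),
        target_name=target.variable, y_name=y.variable,
        control_names=(c1.variable, c2.variable), n=n, alpha=alpha,
    )


def regional_summary(surface: PartialCorrSurface, zones: list[tuple]) -> pd.DataFrame:
    """Zonal summary of a partial-correlation surface.

    One row per (zone_id, polygon): max/min/mean of r over valid pixels and
    the cell-area-weighted areas (km²) of positive and negative pixels.
    Zones without valid pixels yield a NaN row.
    """
    r = surface.r.masked()
    cell_area = surface.r.cell_area
    rows = []
    for zid, geom in zones:
        sel = zone_pixel_mask(surface.r, geom)
        vals = r[sel]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            rows.append({"zone": zid, "max": np.nan, "min": np.nan, "mean": np.nan,
                         "positive_area": np.nan, "negative_area": np.nan})
            continue
        rows.append({
            "zone": zid,
            "max": float(vals.max()),
            "min": float(vals.min()),
            "mean": float(vals.mean()),
            "positive_area": float((vals > 0).sum() * cell_area),
            "negative_area": float((vals < 0).sum() * cell_area),
        })
    return pd.DataFrame(rows).set_index("zone")
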