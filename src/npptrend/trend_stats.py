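"""Per-pixel temporal statistics: OLS trend, F significance, CV, RARC.

Each statistic is computed independently at every pixel of a time stack.
The trend is the ordinary least-squares slope of value against time index
i = 1..n (steps are annual, so slopes are per year); its significance is the
standard regression F test with one regressor,

    F = R²/(1−R²) · (n−2),

referred to F(1, n−2).  Variability is the coefficient of variation
CV = sd/mean (sample sd, divisor n−1), and the relative inter-annual rate of
change RARC = 100·slope/mean in %/yr, which removes the between-pixel
differences in absolute productivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .raster_core import RasterGrid, RasterStack

__all__ = [
    "TrendSurface",
    "TREND_CLASSES",
    "pixel_slope",
    "trend_f_test",
    "pixel_cv",
    "rarc",
    "classify_trend",
    "compute_trend_surface",
]

#: Class codes for the four-way trend map.
TREND_CLASSES = {
    1: "sig-increase",
    2: "nonsig-increase",
    3: "nonsig-decrease",
    4: "sig-decrease",
    0: "nodata",
}


@dataclass
class TrendSurface:
    """Per-pixel trend statistics for one stack."""

    slope: RasterGrid
    f_stat: RasterGrid
    p_value: RasterGrid
    cv: RasterGrid
    rarc: RasterGrid
    mean: RasterGrid
    trend_class: RasterGrid  # codes per TREND_CLASSES
    n: int
    alpha: float = 0.05


def _valid_cube(stack: RasterStack) -> tuple[np.ndarray, np.ndarray]:
    """Cube with NaN nodata plus per-pixel mask of fully valid series.

    Pixels with any missing step are dropped entirely: the time index of the
    printed regression assumes a complete series.
    """
    cube = stack.as_cube()
    ok = ~np.isnan(cube).any(axis=0)
    return cube, ok


def pixel_slope(stack: RasterStack) -> RasterGrid:
    """Least-squares slope of value on time index i = 1..n, per pixel."""
    if len(stack) < 3:
        raise ValueError("need at least 3 time steps for a trend")
    cube, ok = _valid_cube(stack)
    n = cube.shape[0]
    i = np.arange(1, n + 1, dtype=float)[:, None, None]
    with np.errstate(invalid="ignore"):
        num = n * (i * cube).sum(axis=0) - i.sum() * cube.sum(axis=0)
        den = n * (i ** 2).sum() - i.sum() ** 2
        slope = num / den
    slope[~ok] = np.nan
    return stack.template.with_values(slope, nodata=np.nan)


def trend_f_test(stack: RasterStack, slope_grid: RasterGrid | None = None) -> tuple[RasterGrid, RasterGrid]:
    """Regression F statistic and upper-tail p-value of the per-pixel trend.

    R² = 1 exactly (a perfectly linear series) yields F = +inf and p = 0.
    """
    cube, ok = _valid_cube(stack)
    n = cube.shape[0]
    if n < 4:
        raise ValueError("F test needs n >= 4")
    i = np.arange(1, n + 1, dtype=float)[:, None, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        ic = i - i.mean()
        cc = cube - cube.mean(axis=0)
        sxy = (ic * cc).sum(axis=0)
        sxx = (ic ** 2).sum()
        syy = (cc ** 2).sum(axis=0)
        r2 = np.where(syy > 0, sxy ** 2 / (sxx * syy), 0.0)
        r2 = np.clip(r2, 0.0, 1.0)
        f = np.where(r2 < 1.0, r2 / (1.0 - r2) * (n - 2), np.inf)
    p = np.where(np.isinf(f), 0.0, stats.f.sf(np.where(np.isinf(f), 0.0, f), 1, n - 2))
    f[~ok] = np.nan
    p = np.where(ok, p, np.nan)
    tpl = stack.template
    return tpl.with_values(f, nodata=np.nan), tpl.with_values(p, nodata=np.nan)


def pixel_cv(stack: RasterStack) -> RasterGrid:
    """Coefficient of variation sd/mean per pixel (sample sd, divisor n−1).

    Pixels with zero temporal mean are nodata (the ratio is undefined).
    """
    cube, ok = _valid_cube(stack)
    if cube.shape[0] < 2:
        raise ValueError("CV needs n >= 2")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = cube.mean(axis=0)
        sd = cube.std(axis=0, ddof=1)
        cv = np.where(mean != 0, sd / mean, np.nan)
    cv[~ok] = np.nan
    return stack.template.with_values(cv, nodata=np.nan)


def rarc(slope_grid: RasterGrid, mean_grid: RasterGrid) -> RasterGrid:
    """Relative inter-annual rate of change, 100·slope/mean in %/yr."""
    s = slope_grid.masked()
    m = mean_grid.masked()
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(m != 0, 100.0 * s / m, np.nan)
    return slope_grid.with_values(out, nodata=np.nan)


def classify_trend(slope_grid: RasterGrid, p_grid: RasterGrid,
                   alpha: float = 0.05) -> RasterGrid:
    """Four-way class map from sign(slope) × significance at ``alpha``.

    A slope of exactly zero is classed as a (non-)significant increase would
    be, i.e. on the non-decrease side; with continuous data this is a
    measure-zero tie-break.
    """
    s = slope_grid.masked()
    p = p_grid.masked()
    cls = np.zeros(s.shape, dtype=np.uint8)
    ok = ~np.isnan(s) & ~np.isnan(p)
    sig = p < alpha
    cls[ok & (s >= 0) & sig] = 1
    cls[ok & (s >= 0) & ~sig] = 2
    cls[ok & (s < 0) & ~sig] = 3
    cls[ok & (s < 0) & sig] = 4
    return slope_grid.with_values(cls, nodata=0)


def compute_trend_surface(stack: RasterStack, alpha: float = 0.05) -> TrendSurface:
    """All per-pixel trend statistics for one stack in a single pass."""
    slope = pixel_slope(stack)
    f, p = trend_f_test(stack, slope)
    cv = pixel_cv(stack)
    cube, ok = _valid_cube(stack)
    mean_vals = cube.mean(axis=0)
    mean_vals[~ok] = np.nan
    mean = stack.template.with_values(mean_vals, nodata=np.nan)
    return TrendSurface(
        slope=slope, f_stat=f, p_value=p, cv=cv,
        rarc=rarc(slope, mean), mean=mean,
        trend_class=classify_trend(slope, p, alpha),
        n=len(stack), alpha=alpha,
    )
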