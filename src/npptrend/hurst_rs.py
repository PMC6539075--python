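"""Rescaled-range (R/S) Hurst-exponent estimation and persistence maps.

For a series x(1..n) and window length τ, the growing *anchored* prefix
window [1..τ] gives

    mean     m(τ) = (1/τ) Σ_{t≤τ} x(t)
    profile  X(t,τ) = Σ_{s≤t} (x(s) − m(τ))
    range    R(τ) = max_t X(t,τ) − min_t X(t,τ)
    scale    S(τ) = √((1/τ) Σ_{t≤τ} (x(t) − m(τ))²)      (divisor τ)

and the Hurst exponent H is the slope of log(R/S) on log(τ):
R(τ)/S(τ) ≈ (cτ)^H.  H > 0.5 indicates long-range persistence (future
changes tend to continue the past trend), H < 0.5 anti-persistence, and
H = 0.5 a memoryless series.

The anchored form (every window starts at t = 1) is the one used for short
annual records; the classical Mandelbrot–Wallis estimator, which averages
R/S over non-overlapping blocks of each length, is available as
``method="block"``.  R/S estimates are biased at small n — calibration
against exact fractional Gaussian noise is part of the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster_core import RasterGrid, RasterStack

__all__ = [
    "RSCurve",
    "HurstFit",
    "PERSISTENCE_CLASSES",
    "default_taus",
    "rs_curve",
    "hurst_exponent",
    "hurst_map",
    "classify_persistence",
]

PERSISTENCE_CLASSES = {
    1: "persistent-increase",
    2: "persistent-decrease",
    3: "anti-persistent",
    4: "random",
    0: "nodata",
}


@dataclass
class RSCurve:
    """R/S values over window lengths, with degenerate windows recorded."""

    taus: np.ndarray
    rs_values: np.ndarray
    skipped_taus: list


@dataclass
class HurstFit:
    """Least-squares fit of log(R/S) on log(τ)."""

    h: float
    intercept: float
    fit_r2: float
    n_points: int


def default_taus(n: int, max_points: int = 64) -> np.ndarray:
    """Window lengths used for estimation: all of 2..n for short series,
    ~``max_points`` log-spaced lengths otherwise (an O(n²) full sweep buys
    nothing statistically on long series)."""
    if n <= max_points:
        return np.arange(2, n + 1)
    taus = np.unique(np.geomspace(2, n, max_points).round().astype(int))
    return taus[taus >= 2]


def _anchored_rs(x: np.ndarray, taus: np.ndarray):
    csum = np.cumsum(x)
    rs = np.full(taus.size, np.nan)
    for k, tau in enumerate(taus):
        m = csum[tau - 1] / tau
        profile = csum[:tau] - m * np.arange(1, tau + 1)
        r = profile.max() - profile.min()
        s = np.sqrt(np.mean((x[:tau] - m) ** 2))
        if s > 0:
            rs[k] = r / s
    return rs


def _block_rs(x: np.ndarray, taus: np.ndarray):
    n = x.size
    rs = np.full(taus.size, np.nan)
    for k, tau in enumerate(taus):
        nblocks = n // tau
        vals = []
        for b in range(nblocks):
            seg = x[b * tau:(b + 1) * tau]
            m = seg.mean()
            profile = np.cumsum(seg - m)
            s = np.sqrt(np.mean((seg - m) ** 2))
            if s > 0:
                vals.append((profile.max() - profile.min()) / s)
        if vals:
            rs[k] = np.mean(vals)
    return rs


def rs_curve(series, taus=None, method: str = "anchored") -> RSCurve:
    """R/S over window lengths for one series.

    ``taus`` defaults to :func:`default_taus`.  Windows with S = 0 (constant
    prefix) are skipped and listed in ``skipped_taus``; fewer than 3 usable
    windows is an estimation error.
    """
    x = np.asarray(series, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 4:
        raise ValueError("need at least 4 valid values")
    taus = default_taus(x.size) if taus is None else np.asarray(taus, dtype=int)
    if (taus < 2).any() or (np.diff(taus) <= 0).any():
        raise ValueError("taus must be strictly increasing and >= 2")
    if taus.max() > x.size:
        raise ValueError("tau exceeds series length")
    if method == "anchored":
        rs = _anchored_rs(x, taus)
    elif method == "block":
        rs = _block_rs(x, taus)
    else:
        raise ValueError(f"unknown R/S method {method!r}")
    ok = ~np.isnan(rs)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 usable window lengths")
    return RSCurve(taus=taus[ok], rs_values=rs[ok],
                   skipped_taus=list(taus[~ok]))


def hurst_exponent(series, taus=None, method: str = "anchored") -> HurstFit:
    """Hurst exponent by OLS of log(R/S) on log(τ)."""
    curve = rs_curve(series, taus=taus, method=method)
    lx = np.log(curve.taus.astype(float))
    ly = np.log(curve.rs_values)
    ok = np.isfinite(ly)
    lx, ly = lx[ok], ly[ok]
    if lx.size < 3:
        raise ValueError("fewer than 3 finite log-log points")
    xc = lx - lx.mean()
    yc = ly - ly.mean()
    sxx = (xc ** 2).sum()
    h = float((xc * yc).sum() / sxx)
    intercept = float(ly.mean() - h * lx.mean())
    syy = (yc ** 2).sum()
    r2 = float((xc * yc).sum() ** 2 / (sxx * syy)) if syy > 0 else 1.0
    return HurstFit(h=h, intercept=intercept, fit_r2=r2, n_points=lx.size)


def hurst_map(stack: RasterStack, taus=None) -> tuple[RasterGrid, RasterGrid]:
    """Per-pixel anchored R/S Hurst exponent and fit R² for a stack.

    Pixels with missing steps, constant prefixes everywhere, or fewer than
    3 usable windows degrade to nodata.  Vectorized over pixels.
    """
    cube = stack.as_cube()
    n, rows, cols = cube.shape
    if n < 4:
        raise ValueError("need at least 4 time steps")
    taus = default_taus(n) if taus is None else np.asarray(taus, dtype=int)
    flat = cube.reshape(n, -1)
    ok_pix = ~np.isnan(flat).any(axis=0)

    csum = np.cumsum(flat, axis=0)
    log_rs = np.full((taus.size, flat.shape[1]), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        for k, tau in enumerate(taus):
            m = csum[tau - 1] / tau
            profile = csum[:tau] - m[None, :] * np.arange(1, tau + 1)[:, None]
            r = profile.max(axis=0) - profile.min(axis=0)
            s = np.sqrt(np.mean((flat[:tau] - m[None, :]) ** 2, axis=0))
            rs = np.where(s > 0, r / s, np.nan)
            log_rs[k] = np.where(rs > 0, np.log(rs), np.nan)

    lx = np.log(taus.astype(float))[:, None]
    valid = np.isfinite(log_rs)
    npts = valid.sum(axis=0)
    # masked per-pixel OLS of log(R/S) on log(tau)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = valid.astype(float)
        sw = w.sum(axis=0)
        mx = (w * lx).sum(axis=0) / sw
        my = np.nansum(np.where(valid, log_rs, 0.0), axis=0) / sw
        dx = (lx - mx[None, :]) * w
        dy = np.where(valid, log_rs - my[None, :], 0.0)
        sxx = (dx ** 2).sum(axis=0)
        sxy = (dx * dy).sum(axis=0)
        syy = (dy ** 2).sum(axis=0)
        h = sxy / sxx
        r2 = np.where(syy > 0, sxy ** 2 / (sxx * syy), 1.0)

    bad = ~ok_pix | (npts < 3) | ~np.isfinite(h)
    h[bad] = np.nan
    r2[bad] = np.nan
    tpl = stack.template
    return (tpl.with_values(h.reshape(rows, cols), nodata=np.nan),
            tpl.with_values(r2.reshape(rows, cols), nodata=np.nan))


def classify_persistence(h_grid: RasterGrid, slope_grid: RasterGrid,
                         threshold: float = 0.5) -> RasterGrid:
    """Persistence class map from the Hurst surface and the trend sign.

    H > threshold → persistent, sub-classed by the sign of the past trend
    (the series is expected to keep moving the same way); H < threshold →
    anti-persistent; H = threshold exactly → random.
    """
    h = h_grid.masked()
    s = slope_grid.masked()
    cls = np.zeros(h.shape, dtype=np.uint8)
    ok = ~np.isnan(h) & ~np.isnan(s)
    cls[ok & (h > threshold) & (s >= 0)] = 1
    cls[ok & (h > threshold) & (s < 0)] = 2
    cls[ok & (h < threshold)] = 3
    cls[ok & (h == threshold)] = 4
    return h_grid.with_values(cls, nodata=0)
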