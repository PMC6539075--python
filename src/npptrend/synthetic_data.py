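"""Synthetic inputs with known ground truth for the whole pipeline.

Real inputs to this kind of analysis (satellite NPP/ET products, interpolated
station precipitation, land-surface temperature, categorical land-use maps)
are rarely redistributable, so every generator here produces stand-ins whose
structure is known exactly: per-pixel linear trends plus noise, a specified
4×4 cross-variable covariance among {NPP, precipitation, LST, ET}, temporal
autocorrelation with a known Hurst exponent, a smooth west–east precipitation
gradient whose threshold isoline shifts between years, and a 7-class
landscape pair with specified transition probabilities.

All generators are pure functions of (config, seed): the same seed yields
bit-identical output.

Default magnitudes mirror a semi-arid grassland/farmland transition zone:
mean productivity ≈ 1640 g C/m² with an upward trend of ≈ 20.6 g C/m² per
year, annual precipitation around the 400 mm divide, and 16 annual steps
(2000–2015).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster_core import Affine, RasterGrid, RasterStack

__all__ = [
    "VARIABLES",
    "LANDUSE_CLASSES",
    "ClimateSimConfig",
    "LanduseSimConfig",
    "simulate_fgn",
    "fgn_autocovariance",
    "simulate_climate",
    "simulate_precip_gradient",
    "simulate_landuse_pair",
    "landuse_pair_from_counts",
]

VARIABLES = ("npp", "precip", "lst", "et")

LANDUSE_CLASSES = ("farmland", "forest", "grassland", "water",
                   "desert", "built-up", "bare")


def _default_covariance() -> np.ndarray:
    # Correlations chosen to mimic a water-limited system: productivity
    # tracks precipitation and ET, temperature couples weakly/negatively.
    sd = np.array([236.0, 60.0, 0.8, 40.0])  # NPP, precip(mm), LST(°C), ET(mm)
    corr = np.array([
        [1.00, 0.40, 0.20, 0.50],
        [0.40, 1.00, -0.30, 0.60],
        [0.20, -0.30, 1.00, -0.20],
        [0.50, 0.60, -0.20, 1.00],
    ])
    return corr * np.outer(sd, sd)


@dataclass
class ClimateSimConfig:
    """Configuration for the correlated four-variable climate simulator.

    ``means``/``trends``/``covariance`` are ordered (NPP, precip, LST, ET).
    ``hurst`` sets the temporal autocorrelation of every pixel series
    (0.5 = white noise).  ``nodata_fraction`` knocks out whole pixels across
    all variables and years, as cloud/QA masking would.
    """

    n_years: int = 16
    shape: tuple[int, int] = (40, 40)
    means: np.ndarray = field(default_factory=lambda: np.array([1640.19, 400.0, 8.0, 300.0]))
    covariance: np.ndarray = field(default_factory=_default_covariance)
    trends: np.ndarray = field(default_factory=lambda: np.array([20.57, 0.0, 0.0, 0.0]))
    hurst: float = 0.5
    nodata_fraction: float = 0.0
    seed: int = 0
    start_year: int = 2000
    cell_area: float = 1.0
    transform: Affine = Affine.north_up(0.0, 0.0, 1.0, 1.0)

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.trends = np.asarray(self.trends, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.n_years < 4:
            raise ValueError("n_years must be >= 4")
        if not (0.0 < self.hurst < 1.0):
            raise ValueError("hurst must lie in (0, 1)")
        if not (0.0 <= self.nodata_fraction < 1.0):
            raise ValueError("nodata_fraction must lie in [0, 1)")
        if self.covariance.shape != (4, 4) or not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric 4x4")
        w = np.linalg.eigvalsh(self.covariance)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError("covariance must be positive semidefinite")


@dataclass
class LanduseSimConfig:
    """Configuration for the categorical landscape-pair simulator."""

    classes: tuple = LANDUSE_CLASSES
    transition_matrix: np.ndarray = field(
        default_factory=lambda: 0.9 * np.eye(7) + 0.1 / 6 * (1 - np.eye(7)))
    class_prior: np.ndarray = field(default_factory=lambda: np.full(7, 1 / 7))
    shape: tuple[int, int] = (100, 100)
    cell_area: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.class_prior = np.asarray(self.class_prior, dtype=float)
        k = len(self.classes)
        if self.transition_matrix.shape != (k, k):
            raise ValueError("transition matrix shape must match class count")
        if (self.transition_matrix < 0).any() or \
                not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must be probabilities summing to 1")
        if not np.isclose(self.class_prior.sum(), 1.0, atol=1e-10):
            raise ValueError("class prior must sum to 1")


# ---------------------------------------------------------------------------
# Fractional Gaussian noise
# ---------------------------------------------------------------------------

def fgn_autocovariance(h: float, lags: np.ndarray) -> np.ndarray:
    """Autocovariance of unit-variance fGn: γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})."""
    k = np.abs(np.asarray(lags, dtype=float))
    return 0.5 * (np.abs(k + 1) ** (2 * h) - 2 * k ** (2 * h) + np.abs(k - 1) ** (2 * h))


def _circulant_eigenvalues(n: int, hurst: float) -> np.ndarray:
    gamma = fgn_autocovariance(hurst, np.arange(n))
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant embedding, length 2n-2
    lam = np.fft.fft(row).real
    # fGn embedding is provably nonnegative-definite; clip fp dust.
    return np.clip(lam, 0.0, None)


def simulate_fgn(n: int, hurst: float, seed, size: int = 1) -> np.ndarray:
    """Exact-covariance fractional Gaussian noise via circulant embedding.

    Returns an array of shape ``(size, n)`` (squeezed to ``(n,)`` when
    ``size == 1``) of stationary unit-variance Gaussian series whose
    autocovariance is exactly that of fGn with exponent ``hurst``.
    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if not (0.0 < hurst < 1.0):
        raise ValueError("hurst must lie in (0, 1)")
    if n < 1:
        raise ValueError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 1:
        out = rng.standard_normal((size, 1))
        return out[0] if size == 1 else out

    lam = _circulant_eigenvalues(n, hurst)
    m = lam.size  # 2n - 2
    half = m // 2  # = n - 1
    # Davies–Harte synthesis: hermitian spectral noise with variances lam.
    w = np.zeros((size, m), dtype=complex)
    w[:, 0] = np.sqrt(lam[0]) * rng.standard_normal(size)
    w[:, half] = np.sqrt(lam[half]) * rng.standard_normal(size)
    a = rng.standard_normal((size, half - 1))
    b = rng.standard_normal((size, half - 1))
    w[:, 1:half] = np.sqrt(lam[1:half] / 2) * (a + 1j * b)
    w[:, half + 1:] = np.conj(w[:, half - 1:0:-1])
    x = np.fft.fft(w, axis=1).real[:, :n] / np.sqrt(m)
    return x[0] if size == 1 else x


# ---------------------------------------------------------------------------
# Correlated climate stacks
# ---------------------------------------------------------------------------

def simulate_climate(config: ClimateSimConfig) -> dict[str, RasterStack]:
    """Generate aligned NPP/precipitation/LST/ET stacks with known structure.

    Per pixel, the 4-variable series is mean + trend·i + correlated noise
    (i = 1..n_years): innovations are fGn in time, independent across
    variables, then mixed by the covariance square root so cross-variable
    covariance matches ``config.covariance`` while each temporal marginal
    stays fGn with exponent ``config.hurst``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.shape
    npix = rows * cols
    n = cfg.n_years

    # (4*npix, n) unit-variance fGn innovations, then mix across variables.
    eps = simulate_fgn(n, cfg.hurst, rng, size=4 * npix).reshape(4, npix, n)
    w_eig, v_eig = np.linalg.eigh(cfg.covariance)
    sqrt_cov = v_eig @ np.diag(np.sqrt(np.clip(w_eig, 0.0, None))) @ v_eig.T
    mixed = np.einsum("vw,wpn->vpn", sqrt_cov, eps)

    i_idx = np.arange(1, n + 1, dtype=float)
    series = cfg.means[:, None, None] + cfg.trends[:, None, None] * i_idx[None, None, :] + mixed

    nodata_pix = np.zeros(npix, dtype=bool)
    if cfg.nodata_fraction > 0:
        k = int(round(cfg.nodata_fraction * npix))
        nodata_pix[rng.choice(npix, size=k, replace=False)] = True

    years = list(range(cfg.start_year, cfg.start_year + n))
    out: dict[str, RasterStack] = {}
    for vi, name in enumerate(VARIABLES):
        grids = []
        for ti in range(n):
            vals = series[vi, :, ti].copy()
            vals[nodata_pix] = np.nan
            grids.append(RasterGrid(vals.reshape(rows, cols), nodata=np.nan,
                                    transform=cfg.transform, cell_area=cfg.cell_area))
        out[name] = RasterStack(grids, years, variable=name)
    return out


def simulate_precip_gradient(n_years: int, shape: tuple[int, int],
                             isoline_positions, threshold: float = 400.0,
                             gradient: float = 5.0, noise_sd: float = 0.0,
                             seed: int = 0, start_year: int = 2000) -> RasterStack:
    """West–east precipitation gradient whose threshold isoline shifts yearly.

    In year t the field is ``threshold + gradient·(col + 0.5 −
    isoline_positions[t])`` so the threshold contour sits exactly at column
    offset ``isoline_positions[t]`` (in cells from the west edge).  With
    integer positions and zero noise, the set of pixels crossed by the
    contour over the record is a vertical band exactly
    ``max(pos) − min(pos)`` cells wide.
    """
    pos = np.asarray(isoline_positions, dtype=float)
    if pos.size != n_years:
        raise ValueError("need one isoline position per year")
    rng = np.random.default_rng(seed)
    rows, cols = shape
    col_centers = np.arange(cols) + 0.5
    grids = []
    for t in range(n_years):
        base = threshold + gradient * (col_centers - pos[t])
        vals = np.tile(base, (rows, 1))
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
        grids.append(RasterGrid(vals, nodata=np.nan))
    return RasterStack(grids, list(range(start_year, start_year + n_years)),
                       variable="precip")


# ---------------------------------------------------------------------------
# Categorical landscapes
# ---------------------------------------------------------------------------

def simulate_landuse_pair(config: LanduseSimConfig) -> tuple[RasterGrid, RasterGrid]:
    """Draw a (start, end) categorical grid pair from prior and transitions."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    k = len(cfg.classes)
    rows, cols = cfg.shape
    start = rng.choice(k, size=rows * cols, p=cfg.class_prior)
    end = np.empty_like(start)
    for i in range(k):
        sel = start == i
        if sel.any():
            end[sel] = rng.choice(k, size=int(sel.sum()), p=cfg.transition_matrix[i])
    nodata = 255
    g = dict(nodata=nodata, cell_area=cfg.cell_area)
    return (RasterGrid(start.reshape(rows, cols).astype(np.uint8), **g),
            RasterGrid(end.reshape(rows, cols).astype(np.uint8), **g))


def landuse_pair_from_counts(counts: np.ndarray, cell_area: float = 1.0) -> tuple[RasterGrid, RasterGrid]:
    """Construct a grid pair whose exact cross-tabulation equals ``counts``.

    ``counts[i, j]`` is the number of cells of class i at date 1 that are
    class j at date 2 (each cell covering ``cell_area`` km²).  The cells are
    laid out row-major into the smallest near-square grid; any remainder is
    nodata in both grids.  Useful for turning a published transfer matrix
    into a raster realization.
    """
    counts = np.asarray(counts)
    if (counts < 0).any() or counts.sum() == 0:
        raise ValueError("counts must be nonnegative with positive total")
    total = int(counts.sum())
    start = np.empty(total, dtype=np.uint8)
    end = np.empty(total, dtype=np.uint8)
    pos = 0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            c = int(counts[i, j])
            start[pos:pos + c] = i
            end[pos:pos + c] = j
            pos += c
    cols = int(np.ceil(np.sqrt(total)))
    rows = int(np.ceil(total / cols))
    pad = rows * cols - total
    nodata = 255
    start = np.concatenate([start, np.full(pad, nodata, dtype=np.uint8)]).reshape(rows, cols)
    end = np.concatenate([end, np.full(pad, nodata, dtype=np.uint8)]).reshape(rows, cols)
    return (RasterGrid(start, nodata=nodata, cell_area=cell_area),
            RasterGrid(end, nodata=nodata, cell_area=cell_area))
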