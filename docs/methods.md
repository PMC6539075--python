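# Methods

This note documents the statistical models implemented in `npptrend`, the
defaults chosen where the literature leaves a choice open, and what the
synthetic-data generator does and does not emulate.

## Data model

All statistics operate on `RasterStack`s: time-ordered sequences of
co-registered single-band grids (`RasterGrid`) sharing shape, affine
transform, CRS and nodata sentinel.  Grids are row-major, north-up,
pixel-is-area; georeferencing is the standard six-parameter affine.  Any
statistic at a pixel uses only that pixel's temporal series; pixels with a
missing step are dropped from per-pixel regressions entirely rather than
gap-filled, because the regressions assume an evenly spaced index.

Monthly stacks collapse to seasons and years with a per-variable rule
(sum for fluxes such as NPP and precipitation, mean for states such as
LST).  Seasons are meteorological (MAM/JJA/SON/DJF), with December grouped
with January/February of the *same* calendar year so every year in a
bounded record has four complete seasons; the alternative (December joining
the following winter) discards one season at each end of the record.

## Fluctuation-zone masking

The study-area mask for an isohyet (default 400 mm — the semi-humid/
semi-arid divide) is defined per pixel: a pixel is in the zone iff its
annual precipitation is ≥ threshold in at least one year and < threshold in
at least one other.  This per-pixel crossing test is an exact, order-free
equivalent of sweeping the annual contour lines across the record, and is
invariant under reordering of the years by construction.

## Trend statistics

Slope is the closed-form OLS estimator of value on the time index
i = 1..n.  Significance uses the regression F statistic
F = R²/(1−R²)·(t−k−1)/k with k = 1 regressor and t = n samples, where R is
the Pearson correlation between the series and the time index, so
F ~ F(1, n−2) under the null.  A perfectly linear series (R² = 1) is
reported as F = +∞, p = 0.  CV uses the sample standard deviation
(divisor n−1), the unbiased small-n choice; pixels with zero temporal mean
are nodata since the ratio is undefined.  RARC = 100·slope/mean expresses
the trend as %/yr, making pixels with different absolute productivity
comparable.  The four-way trend class is sign(slope) × (p < α), α = 0.05 by
default; an exact zero slope (measure zero for continuous data) falls on
the increase side.

No autocorrelation-robust alternative (Mann–Kendall, prewhitening) is
provided: the module implements the plain OLS+F chain, and the Hurst module
is the instrument for temporal-memory questions.

## Second-order partial correlation

The coefficient is computed by the textbook recursion from zero- and
first-order coefficients; the test suite verifies it equals the
residual-regression definition (correlate the residuals of x and y after
regressing each on both controls) to machine precision, and that it is
symmetric under exchanging the controls.

Significance uses T = r√(n−q−1)/√(1−r²) with q = 2 interpreted as the
number of *control* variables, giving df = n−3 at n = 16.  The conventional
df for a second-order partial correlation is n−4; `df_offset=-1` restores
it.  The default follows the formula as commonly printed in the applied
literature; at n = 16 the practical effect is a mildly anticonservative
test (measured null rejection ≈ 1.4% at nominal 1%, which the calibration
suite's ±1 point band covers).  p-values are two-sided, since both positive
and negative significant areas are mapped.  In map operations, degenerate
pixels (constant series, |r| = 1 intermediates) become nodata rather than
raising, so nodata-rich rasters never abort a run.

## Rescaled-range Hurst estimation

The implemented form uses *anchored* growing prefix windows: for each
window length τ the window is always [1..τ], with the mean, cumulative
deviation profile, range R(τ) = max−min of the profile, and the population
standard deviation S(τ) (divisor τ).  H is the OLS slope of log(R/S) on
log(τ).  τ = 1 is always excluded (S = 0); any τ whose prefix is constant
is skipped, and a series needs ≥ 3 usable windows to fit.  The classical
Mandelbrot–Wallis estimator (averaging R/S over non-overlapping blocks of
each length) is available as `method="block"` for comparison; the two
coincide at τ = n.

Window lengths default to every τ = 2..n for short series (n ≤ 64, the
per-pixel regime for annual records) and to ~64 log-spaced lengths for
longer series — a full O(n²) sweep adds cost but no statistical
information to the log-log fit.

**Known bias.**  R/S estimation is biased upward on short series: on
i.i.d. noise the mean estimate is ≈ 0.67 at n = 16 and ≈ 0.55 at n = 2000,
converging slowly from above.  The calibration suite therefore checks
recovery on *exact* fractional Gaussian noise (circulant-embedding
construction, so the true H is known) at n = 10⁴, where the estimator is
within ±0.1 of H ∈ {0.3, 0.5, 0.8} and strictly rank-ordered.  Persistence
classes on 16-step records should accordingly be read as relative ordering,
not calibrated absolute memory: the H = 0.5 boundary on short records is
generous toward "persistent".

Persistence classification: H > 0.5 → persistent (sub-classed by the sign
of the fitted trend, since persistence means the past trend continues),
H < 0.5 → anti-persistent, H = 0.5 exactly → random.

## Spatial autocorrelation

Global Moran's I and local Moran I_i are implemented in the forms whose sum
identity Σᵢ Iᵢ = I·S₀ holds exactly (the local denominator is Σ(xᵢ−x̄)²,
not divided by n); that identity, a naive O(n²) double-loop oracle, and the
checkerboard value I = −1 on rook weights are all asserted numerically.
Weights default to queen contiguity with row standardization — the dominant
convention for county-level LISA analyses — with rook and raw-binary
variants available.  Inference defaults to 999 conditional permutations
(value at the focal unit held fixed, all others shuffled), one-sided toward
the observed side, with the +1/(m+1) pseudo-p convention; an
analytic-normal z-score for the global statistic is reported alongside.
LISA significance is labelled at 0.1% and 1% by default.  Units with no
neighbours keep an empty weights row and an undefined local p.

## Land-use transfer matrices

The transfer matrix is the exact cross-tabulation of two aligned
categorical grids multiplied by cell area, carried in km² as floats (cell
area may be fractional).  Row sums equal class areas at the first date,
column sums at the second; reversing the dates transposes the matrix.
Retention shares are 100·diag/total, rounded only at the reporting layer
(2 decimals by default) so internal arithmetic never accumulates rounding
error.  The largest off-diagonal conversion breaks ties in row-major order.
`npptrend.datasets.landuse_transfer_2000_2015` ships a published 7-class
example whose summaries (retention shares 48.29/17.77/12.46%, smallest
retained class 6.94×10⁴ km², largest conversion 8,956 km² farmland→desert)
are reproduced exactly from a pixel-grid realization in the tests.

## Synthetic data

`simulate_climate` draws, per pixel, a 4-variable series
mean + trend·i + noise, where the noise is fractional Gaussian noise in
time (exact autocovariance via circulant embedding — important because R/S
calibration needs a simulator whose true H is correct, which ad-hoc
cumulative-sum constructions do not provide) and is mixed across variables
by the covariance square root, so cross-variable covariance matches the
configured 4×4 matrix while each temporal marginal stays fGn.  Defaults
mirror a semi-arid transition zone: 16 annual steps from 2000, mean NPP
1640.19 g C/m² with a 20.57 g C/m²·yr upward trend, precipitation centred
on 400 mm, and moderate NPP–precip/ET coupling.  `simulate_precip_gradient`
produces a west–east gradient whose threshold isoline sits at a prescribed
column each year, so the fluctuation zone has a known width.
`simulate_landuse_pair` draws a start grid from a class prior and an end
grid from a row-stochastic transition matrix;
`landuse_pair_from_counts` inverts a transfer matrix into grids exactly.

What the generator does *not* emulate: sensor artifacts, cloud masks and
orbital gaps; spatial autocorrelation of the noise field (pixels are
independent draws, so map-level tests exercise per-pixel estimators, not
spatial smoothing); non-Gaussian heavy tails; and seasonality within the
annual series.  Tests passing on these synthetics therefore validate the
estimators' arithmetic and sampling calibration, not robustness to real
remote-sensing artifacts.

## Problem sizes and runtime choices

Calibration suites use 2,000 pixels at n = 16 (the per-pixel regime of an
annual 2000–2015 record) for type-I-error checks, 200 replicates at
n = 10⁴ for Hurst recovery, and 999 permutations for Moran nulls — sizes at
which the binomial/Monte-Carlo error is comfortably inside each asserted
band while the whole suite runs in seconds.  All generators and permutation
tests are deterministic given their seed; the pipeline manifest records
sha256 checksums so a re-run can be verified bit-for-bit.
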