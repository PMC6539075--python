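"""Partial correlation: recursion vs residual-regression oracle, maps, zones."""

import math

import numpy as np
import pytest
from shapely.geometry import box

from npptrend.partial_correlation import (
    UndefinedCorrelationError,
    partial_corr_map,
    partial_r_first,
    partial_r_second,
    partial_t_test,
    pearson_r,
    regional_summary,
)
from npptrend.raster_core import RasterStack

from conftest import make_stack


def residual_partial_corr(x, y, controls):
    """Independent oracle: correlate OLS residuals of x and y on controls."""
    design = np.column_stack([np.ones(len(x))] + list(controls))
    bx, *_ = np.linalg.lstsq(design, x, rcond=None)
    by, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ bx
    ry = y - design @ by
    return np.corrcoef(rx, ry)[0, 1]


class TestScalars:
    def test_pearson_identity_and_sign(self, rng):
        x = rng.normal(size=30)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_pearson_matches_two_pass_formula(self, rng):
        x, y = rng.normal(size=(2, 50))
        xc, yc = x - x.mean(), y - y.mean()
        ref = (xc * yc).sum() / math.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        assert pearson_r(x, y) == pytest.approx(ref, abs=1e-12)

    def test_pearson_zero_variance_errors(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r(np.ones(10), np.arange(10.0))

    def test_first_order_independent_control_reduces_to_pearson(self):
        assert partial_r_first(0.4, 0.0, 0.0) == pytest.approx(0.4)

    def test_first_order_annihilates_spurious_correlation(self):
        assert partial_r_first(0.3 * 0.5, 0.3, 0.5) == pytest.approx(0.0)

    def test_first_order_matches_residual_oracle(self, rng):
        x, y, c = rng.normal(size=(3, 40))
        got = partial_r_first(pearson_r(x, y), pearson_r(x, c), pearson_r(y, c))
        assert got == pytest.approx(residual_partial_corr(x, y, [c]), abs=1e-10)


class TestSecondOrder:
    def test_uncorrelated_controls_reduce_to_pearson(self, rng):
        n = 200_000  # sampling error in r is ~1/sqrt(n)
        x = rng.normal(size=n)
        y = x + rng.normal(size=n)
        c1, c2 = rng.normal(size=(2, n))
        assert partial_r_second(x, y, c1, c2) == pytest.approx(pearson_r(x, y), abs=0.01)

    def test_conditional_independence_gives_zero(self, rng):
        n = 10_000
        c1, c2 = rng.normal(size=(2, n))
        x = 2.0 * c1 - c2 + rng.normal(size=n)
        y = -c1 + 0.5 * c2 + rng.normal(size=n)
        assert abs(partial_r_second(x, y, c1, c2)) < 0.05

    @pytest.mark.parametrize("n", [16, 200])
    def test_matches_residual_regression_oracle(self, rng, n):
        for _ in range(100):
            x, y, c1, c2 = rng.normal(size=(4, n))
            got = partial_r_second(x, y, c1, c2)
            want = residual_partial_corr(x, y, [c1, c2])
            assert got == pytest.approx(want, abs=1e-10)

    def test_control_exchange_symmetry(self, rng):
        x, y, c1, c2 = rng.normal(size=(4, 30))
        a = partial_r_second(x, y, c1, c2)
        b = partial_r_second(x, y, c2, c1)
        assert a == pytest.approx(b, abs=1e-10)


class TestTTest:
    def test_zero_r(self):
        t, p = partial_t_test(0.0, 16)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_printed_formula_arithmetic(self):
        t, p = partial_t_test(0.5, 16, q=2)
        assert t == pytest.approx(0.5 * math.sqrt(13) / math.sqrt(0.75))
        assert 0 < p < 1

    def test_sign_follows_r(self):
        for r in (-0.7, -0.2, 0.3, 0.9):
            t, _ = partial_t_test(r, 20)
            assert math.copysign(1, t) == math.copysign(1, r)

    def test_perfect_correlation_sentinel(self):
        t, p = partial_t_test(1.0, 16)
        assert math.isinf(t) and p == 0.0

    def test_conventional_df_offset(self):
        t13, _ = partial_t_test(0.5, 16, df_offset=0)
        t12, _ = partial_t_test(0.5, 16, df_offset=-1)
        assert t12 == pytest.approx(0.5 * math.sqrt(12) / math.sqrt(0.75))
        assert t12 < t13


class TestMap:
    def test_noise_controls_leave_plain_correlation(self, rng):
        n = 200
        shared = rng.normal(size=(n, 6, 6))
        x = shared + 0.5 * rng.normal(size=(n, 6, 6))
        y = shared + 0.5 * rng.normal(size=(n, 6, 6))
        c1 = rng.normal(size=(n, 6, 6))
        c2 = rng.normal(size=(n, 6, 6))
        surf = partial_corr_map(make_stack(x), make_stack(y, variable="precip"),
                                (make_stack(c1, variable="et"), make_stack(c2, variable="lst")))
        plain = np.empty((6, 6))
        for r in range(6):
            for c in range(6):
                plain[r, c] = pearson_r(x[:, r, c], y[:, r, c])
        assert np.nanmax(np.abs(surf.r.values - plain)) < 0.05

    def test_invariants_on_simulated_climate(self, climate_small):
        s = climate_small
        surf = partial_corr_map(s["npp"], s["precip"], (s["et"], s["lst"]))
        r, p = surf.r.masked(), surf.p_value.masked()
        ok = ~np.isnan(r)
        assert ok.any()
        assert (np.abs(r[ok]) <= 1.0).all()
        assert ((p[ok] >= 0) & (p[ok] <= 1)).all()
        # nodata pixels of the inputs stay nodata in the surface
        in_nodata = np.isnan(s["npp"].as_cube()).any(axis=0)
        assert np.isnan(r[in_nodata]).all()

    def test_misaligned_stacks_error(self, rng):
        a = make_stack(rng.normal(size=(6, 4, 4)))
        b = make_stack(rng.normal(size=(6, 5, 5)))
        with pytest.raises(ValueError, match="aligned"):
            partial_corr_map(a, a, (b, a))


class TestRegionalSummary:
    def _surface(self, r_values):
        rows, cols = r_values.shape
        cube = np.random.default_rng(0).normal(size=(8, rows, cols))
        surf = partial_corr_map(make_stack(cube), make_stack(cube * 0.5 + 1, variable="y"),
                                (make_stack(np.random.default_rng(1).normal(size=(8, rows, cols))),
                                 make_stack(np.random.default_rng(2).normal(size=(8, rows, cols)))))
        surf.r.values[:] = r_values
        return surf

    def test_constant_zone(self):
        surf = self._surface(np.full((4, 4), 0.3))
        zone = [("z", box(0, -4, 4, 0))]
        df = regional_summary(surf, zone)
        row = df.loc["z"]
        assert row["max"] == row["min"] == row["mean"] == pytest.approx(0.3)
        assert row["negative_area"] == 0.0 and row["positive_area"] == 16.0

    def test_sign_split_between_zones(self):
        vals = np.zeros((4, 4))
        vals[:, :2] = 0.5
        vals[:, 2:] = -0.5
        surf = self._surface(vals)
        zones = [("west", box(0, -4, 2, 0)), ("east", box(2, -4, 4, 0))]
        df = regional_summary(surf, zones)
        assert df.loc["west", "negative_area"] == 0.0
        assert df.loc["east", "positive_area"] == 0.0

    def test_area_conservation(self, rng):
        vals = rng.normal(size=(6, 6))
        surf = self._surface(vals)
        zones = [("a", box(0, -6, 3, 0)), ("b", box(3, -6, 6, 0))]
        df = regional_summary(surf, zones)
        total = df[["positive_area", "negative_area"]].to_numpy().sum()
        assert total == pytest.approx((vals != 0).sum() * surf.r.cell_area)

    def test_empty_zone_nan_row(self):
        surf = self._surface(np.full((4, 4), 0.3))
        df = regional_summary(surf, [("off", box(100, 100, 101, 101))])
        assert df.loc["off"].isna().all()
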