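"""Moran's I / LISA against naive double-loop oracles and exact identities."""

import numpy as np
import pytest

from npptrend.raster_core import RasterGrid
from npptrend.spatial_autocorr import (
    WeightMatrix,
    build_weights,
    global_moran,
    lattice_weights,
    local_moran,
    zonal_aggregate,
)
from npptrend.zones import square_grid_zones


def naive_global_moran(x, w_dense):
    """Literal double-loop evaluation of the global statistic."""
    n = len(x)
    z = x - x.mean()
    num = sum(w_dense[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return n * num / (np.sum(z ** 2) * w_dense.sum())


def naive_local_moran(x, w_dense):
    n = len(x)
    z = x - x.mean()
    ssz = np.sum(z ** 2)
    return np.array([n * z[i] * sum(w_dense[i, j] * z[j] for j in range(n)) / ssz
                     for i in range(n)])


class TestZonalAggregate:
    def test_uniform_raster(self):
        grid = RasterGrid(np.full((6, 6), 3.5))
        zones = square_grid_zones(2, 2, size=3.0)
        vals = zonal_aggregate(grid, zones, "mean")
        assert (vals == 3.5).all()

    def test_max_at_least_mean(self, rng):
        grid = RasterGrid(rng.normal(size=(8, 8)))
        zones = square_grid_zones(2, 2, size=4.0)
        assert (zonal_aggregate(grid, zones, "max")
                >= zonal_aggregate(grid, zones, "mean")).all()

    def test_matches_brute_force_pixel_scan(self, rng):
        vals = rng.normal(size=(6, 6))
        grid = RasterGrid(vals)
        zones = square_grid_zones(3, 3, size=2.0)
        got = zonal_aggregate(grid, zones, "mean")
        for zid, _ in zones:
            r, c = divmod(zid, 3)
            want = vals[2 * r:2 * r + 2, 2 * c:2 * c + 2].mean()
            assert got[zid] == pytest.approx(want)

    def test_empty_zone_missing(self):
        grid = RasterGrid(np.ones((2, 2)))
        from shapely.geometry import box
        vals = zonal_aggregate(grid, [("far", box(50, 50, 51, 51))])
        assert np.isnan(vals["far"])


class TestWeights:
    def test_rook_2x2_squares(self):
        zones = square_grid_zones(2, 2)
        w = build_weights(zones, "rook", row_standardize=False)
        counts = np.asarray((w.weights > 0).sum(axis=1)).ravel()
        np.testing.assert_array_equal(counts, [2, 2, 2, 2])

    def test_queen_adds_diagonals(self):
        zones = square_grid_zones(2, 2)
        w = build_weights(zones, "queen", row_standardize=False)
        counts = np.asarray((w.weights > 0).sum(axis=1)).ravel()
        np.testing.assert_array_equal(counts, [3, 3, 3, 3])

    def test_row_standardized_rows_sum_to_one(self):
        w = build_weights(square_grid_zones(3, 4), "queen", row_standardize=True)
        np.testing.assert_allclose(np.asarray(w.weights.sum(axis=1)).ravel(), 1.0)

    def test_symmetric_before_standardization(self):
        w = build_weights(square_grid_zones(3, 3), "rook", row_standardize=False)
        assert (w.weights != w.weights.T).nnz == 0

    def test_lattice_matches_polygon_contiguity(self):
        wp = build_weights(square_grid_zones(3, 3), "rook", row_standardize=False)
        wl = lattice_weights(3, 3, "rook", row_standardize=False)
        assert (wp.weights != wl.weights).nnz == 0

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            WeightMatrix(np.eye(3))


class TestGlobalMoran:
    def test_checkerboard_is_minus_one(self):
        w = lattice_weights(6, 6, "rook", row_standardize=True)
        x = (np.indices((6, 6)).sum(axis=0) % 2).ravel() * 2.0 - 1.0
        res = global_moran(x, w, permutations=0)
        assert res.i == pytest.approx(-1.0, abs=1e-12)

    def test_matches_naive_oracle(self, rng):
        for n_side in (4, 7):
            w = lattice_weights(n_side, n_side, "queen", row_standardize=True)
            x = rng.normal(size=n_side * n_side)
            res = global_moran(x, w, permutations=0)
            assert res.i == pytest.approx(
                naive_global_moran(x, w.weights.toarray()), abs=1e-12)

    def test_permutation_mean_near_expectation(self, rng):
        w = lattice_weights(7, 7, "queen")
        x = rng.normal(size=49)
        res = global_moran(x, w, permutations=999, seed=11)
        assert res.sim_mean == pytest.approx(res.expected_i, abs=0.01)

    def test_affine_invariance(self, rng):
        w = lattice_weights(5, 5, "queen")
        x = rng.normal(size=25)
        i1 = global_moran(x, w, permutations=0).i
        i2 = global_moran(-3.0 * x + 7.0, w, permutations=0).i
        assert i1 == pytest.approx(i2, abs=1e-12)

    def test_constant_attribute_errors(self):
        w = lattice_weights(3, 3)
        with pytest.raises(ValueError, match="constant"):
            global_moran(np.ones(9), w)

    def test_clustered_field_positive_and_significant(self, rng):
        # left half low, right half high -> strong positive autocorrelation
        x = (np.tile(np.repeat([0.0, 4.0], 4), (8, 1)).ravel()
             + rng.normal(scale=0.5, size=64))
        w = lattice_weights(8, 8, "queen")
        res = global_moran(x, w, permutations=999, seed=5)
        assert res.i > 0.5 and res.p < 0.01 and res.z > 2


class TestLocalMoran:
    def test_sum_identity_with_global(self, rng):
        w = lattice_weights(6, 6, "queen")
        x = rng.normal(size=36)
        i_glob = global_moran(x, w, permutations=0).i
        lres = local_moran(x, w, permutations=0)
        assert lres.local_i.sum() == pytest.approx(i_glob * w.s0, abs=1e-10)

    def test_matches_naive_oracle(self, rng):
        w = lattice_weights(5, 5, "rook")
        x = rng.normal(size=25)
        lres = local_moran(x, w, permutations=0)
        np.testing.assert_allclose(lres.local_i,
                                   naive_local_moran(x, w.weights.toarray()),
                                   atol=1e-12)

    def test_high_surrounded_by_high_is_hh(self):
        x = np.zeros(25)
        x[[6, 7, 8, 11, 12, 13, 16, 17, 18]] = 5.0  # 3x3 high block center
        w = lattice_weights(5, 5, "queen")
        lres = local_moran(x, w, permutations=99, seed=1)
        assert lres.quadrant[12] == "HH" and lres.local_i[12] > 0

    def test_sign_flip_swaps_quadrants(self, rng):
        w = lattice_weights(5, 5, "queen")
        x = rng.normal(size=25)
        a = local_moran(x, w, permutations=0)
        b = local_moran(-x, w, permutations=0)
        np.testing.assert_allclose(a.local_i, b.local_i, atol=1e-12)
        swap = {"HH": "LL", "LL": "HH", "HL": "LH", "LH": "HL"}
        assert all(swap[q1] == q2 for q1, q2 in zip(a.quadrant, b.quadrant))

    def test_sig_classes_at_both_levels(self, rng):
        w = lattice_weights(6, 6, "queen")
        x = rng.normal(size=36)
        lres = local_moran(x, w, permutations=199, seed=2)
        assert set(lres.sig_class) <= {"p<0.001", "p<0.01", "ns"}
        assert ((lres.p >= 1 / 200) & (lres.p <= 1.0)).all()
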