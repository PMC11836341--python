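"""Pixelwise gamma (SVI-SPEI temporal correlation) against naive oracles."""

import numpy as np
import pytest

from divdrought.drought_metrics import SPEIStack
from divdrought.raster_grid import GridSpec
from divdrought.sensitivity import (
    DRY_SEASON_MONTHS,
    dry_season_gamma,
    monthly_gamma_maps,
    pixel_gamma,
    positive_area_proportion,
)
from divdrought.vegetation_indices import SVIStack


def naive_gamma(x, y):
    """Two-pass textbook Pearson correlation, written independently of the
    vectorized implementation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[keep], y[keep]
    xb, yb = x.mean(), y.mean()
    num = np.sum((x - xb) * (y - yb))
    den = np.sqrt(np.sum((x - xb) ** 2) * np.sum((y - yb) ** 2))
    return num / den


def stacks_from_series(svi_series, spei_series, months=(1,)):
    """Build 1-pixel stacks carrying the given series in the given months."""
    n = len(svi_series)
    years = list(range(2000, 2000 + n))
    grid = GridSpec(1, 1)
    svi = np.full((n, 12, 1, 1), np.nan)
    spei = np.full((n, 12, 1, 1), np.nan)
    for m in months:
        svi[:, m - 1, 0, 0] = svi_series
        spei[:, m - 1, 0, 0] = spei_series
    sv = SVIStack(grid, years, svi, np.zeros((12, 1, 1)), np.ones((12, 1, 1)))
    sp = SPEIStack(grid, years, spei, 1)
    return sv, sp


class TestPixelGamma:
    def test_self_correlation_is_one(self):
        s = [0.1, -0.2, 0.3, 0.0, -0.4, 0.2]
        sv, sp = stacks_from_series(s, s)
        out = pixel_gamma(sv, sp, {1}, min_samples=2)
        assert out.gamma.values[0, 0] == pytest.approx(1.0)

    def test_anticorrelation_is_minus_one(self):
        s = np.array([0.1, -0.2, 0.3, 0.0, -0.4, 0.2])
        sv, sp = stacks_from_series(s, -s)
        out = pixel_gamma(sv, sp, {1}, min_samples=2)
        assert out.gamma.values[0, 0] == pytest.approx(-1.0)

    def test_toy_series_matches_oracle(self):
        svi = [0.1, -0.2, 0.3, 0.0, -0.4, 0.2]
        spei = [0.2, -0.1, 0.4, 0.1, -0.5, 0.1]
        sv, sp = stacks_from_series(svi, spei)
        out = pixel_gamma(sv, sp, {1}, min_samples=2)
        assert out.gamma.values[0, 0] == pytest.approx(naive_gamma(svi, spei), abs=1e-10)
        assert out.n_samples[0, 0] == 6

    def test_many_random_series_match_oracle(self, rng):
        n_pix = 1000
        grid = GridSpec(1, n_pix)
        years = list(range(2000, 2019))
        svi = np.full((19, 12, 1, n_pix), np.nan)
        spei = np.full((19, 12, 1, n_pix), np.nan)
        for m in DRY_SEASON_MONTHS:
            svi[:, m - 1] = rng.normal(size=(19, 1, n_pix))
            spei[:, m - 1] = rng.normal(size=(19, 1, n_pix))
        # punch some missing slots
        miss = rng.random((19, 12, 1, n_pix)) < 0.1
        svi[miss] = np.nan
        sv = SVIStack(grid, years, svi, np.zeros((12, 1, n_pix)), np.ones((12, 1, n_pix)))
        sp = SPEIStack(grid, years, spei, 1)
        out = pixel_gamma(sv, sp, DRY_SEASON_MONTHS, min_samples=10)
        midx = [m - 1 for m in sorted(DRY_SEASON_MONTHS)]
        for j in rng.choice(n_pix, 60, replace=False):
            expect = naive_gamma(svi[:, midx, 0, j].ravel(), spei[:, midx, 0, j].ravel())
            assert out.gamma.values[0, j] == pytest.approx(expect, abs=1e-10)

    def test_affine_invariance_and_sign_flip(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        sv, sp = stacks_from_series(x, y)
        base = pixel_gamma(sv, sp, {1}, 2).gamma.values[0, 0]
        sv2, sp2 = stacks_from_series(2.5 * x + 1.0, 0.5 * y - 3.0)
        assert pixel_gamma(sv2, sp2, {1}, 2).gamma.values[0, 0] == pytest.approx(base, abs=1e-12)
        sv3, sp3 = stacks_from_series(-x, y)
        assert pixel_gamma(sv3, sp3, {1}, 2).gamma.values[0, 0] == pytest.approx(-base, abs=1e-12)

    def test_zero_variance_invalid(self):
        sv, sp = stacks_from_series([0.3] * 6, [0.1, -0.2, 0.3, 0.0, -0.4, 0.2])
        out = pixel_gamma(sv, sp, {1}, 2)
        assert not out.gamma.valid[0, 0]

    def test_min_samples_guard(self):
        sv, sp = stacks_from_series([0.1, -0.2, 0.3], [0.2, -0.1, 0.4])
        out = pixel_gamma(sv, sp, {1}, min_samples=5)
        assert not out.gamma.valid[0, 0]

    def test_empty_month_set_rejected(self):
        sv, sp = stacks_from_series([0.1, 0.2], [0.1, 0.2])
        with pytest.raises(ValueError):
            pixel_gamma(sv, sp, set(), 2)

    def test_p_value_matches_scipy(self, rng):
        from scipy import stats

        x = rng.normal(size=15)
        y = 0.5 * x + rng.normal(size=15)
        sv, sp = stacks_from_series(x, y)
        out = pixel_gamma(sv, sp, {1}, 2)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert out.gamma.values[0, 0] == pytest.approx(r_ref, abs=1e-12)
        assert out.p_value.values[0, 0] == pytest.approx(p_ref, rel=1e-8)


class TestMonthlyMaps:
    def test_coupling_confined_to_planted_month(self, rng):
        years = list(range(2000, 2019))
        grid = GridSpec(1, 1)
        spei = rng.normal(size=(19, 12, 1, 1))
        svi = rng.normal(size=(19, 12, 1, 1))
        svi[:, 0] = 0.95 * spei[:, 0] + 0.05 * svi[:, 0]  # January coupling only
        sv = SVIStack(grid, years, svi, np.zeros((12, 1, 1)), np.ones((12, 1, 1)))
        sp = SPEIStack(grid, years, spei, 1)
        maps = monthly_gamma_maps(sv, sp, min_samples=10)
        assert maps[1].gamma.values[0, 0] > 0.9
        assert abs(maps[7].gamma.values[0, 0]) < 0.6

    def test_constant_month_invalid_others_fine(self, rng):
        years = list(range(2000, 2019))
        grid = GridSpec(1, 1)
        spei = rng.normal(size=(19, 12, 1, 1))
        svi = rng.normal(size=(19, 12, 1, 1))
        svi[:, 2] = 0.4  # March constant across years
        sv = SVIStack(grid, years, svi, np.zeros((12, 1, 1)), np.ones((12, 1, 1)))
        sp = SPEIStack(grid, years, spei, 1)
        maps = monthly_gamma_maps(sv, sp, min_samples=10)
        assert not maps[3].gamma.valid[0, 0]
        assert maps[4].gamma.valid[0, 0]

    def test_n_samples_counts_joint_years(self, rng):
        x = rng.normal(size=19)
        y = rng.normal(size=19)
        x[3] = np.nan
        y[7] = np.nan
        sv, sp = stacks_from_series(x, y)
        out = pixel_gamma(sv, sp, {1}, 2)
        assert out.n_samples[0, 0] == 17


class TestDrySeason:
    def test_equals_pixel_gamma_with_dry_month_set(self, rng):
        years = list(range(2000, 2019))
        grid = GridSpec(2, 2)
        svi = rng.normal(size=(19, 12, 2, 2))
        spei = rng.normal(size=(19, 12, 2, 2))
        sv = SVIStack(grid, years, svi, np.zeros((12, 2, 2)), np.ones((12, 2, 2)))
        sp = SPEIStack(grid, years, spei, 1)
        a = dry_season_gamma(sv, sp, 30)
        b = pixel_gamma(sv, sp, DRY_SEASON_MONTHS, 30)
        np.testing.assert_array_equal(a.gamma.values, b.gamma.values)
        assert a.n_samples[0, 0] == 6 * 19


class TestPositiveProportion:
    def _map(self, gammas):
        from divdrought.raster_grid import MaskedRaster
        from divdrought.sensitivity import SensitivityMap

        arr = np.asarray(gammas, float).reshape(1, -1)
        grid = GridSpec(*arr.shape)
        valid = ~np.isnan(arr)
        return SensitivityMap(grid, MaskedRaster(grid, arr, valid),
                              valid.astype(int) * 19, MaskedRaster(grid, arr * 0, valid))

    def test_all_positive(self):
        assert positive_area_proportion(self._map([0.2, 0.4, 0.9])) == 1.0

    def test_counting(self):
        assert positive_area_proportion(self._map([0.2, -0.3, 0.1, -0.1])) == 0.5

    def test_zero_counts_as_non_positive(self):
        assert positive_area_proportion(self._map([0.0, 0.5])) == 0.5

    def test_no_valid_pixels_rejected(self):
        with pytest.raises(ValueError):
            positive_area_proportion(self._map([np.nan, np.nan]))
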