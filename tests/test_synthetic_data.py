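"""Generator properties: determinism, planted structure, internal consistency."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from divdrought.drought_metrics import aridity_index, drought_frequency
from divdrought.synthetic_data import (
    SyntheticConfig,
    gen_climate_and_truth,
    gen_diversity_field,
    gen_mask_and_zones,
    gen_reflectance_scene,
    gen_spei,
    gen_vi_stack,
    generate_all,
)


@pytest.fixture(scope="module")
def cfg():
    return SyntheticConfig(seed=11, n_rows=40, n_cols=40, n_scenes=1)


@pytest.fixture(scope="module")
def truth_bundle(cfg):
    return gen_climate_and_truth(cfg)


class TestDiversityField:
    def test_deterministic_given_seed(self, cfg):
        a = gen_diversity_field(cfg)
        b = gen_diversity_field(SyntheticConfig(seed=11, n_rows=40, n_cols=40, n_scenes=1))
        np.testing.assert_array_equal(a, b)
        c = gen_diversity_field(SyntheticConfig(seed=12, n_rows=40, n_cols=40))
        assert not np.array_equal(a, c)

    def test_spans_unit_interval(self, cfg):
        D = gen_diversity_field(cfg)
        assert D.min() == pytest.approx(0.0) and D.max() == pytest.approx(1.0)

    def test_spatially_autocorrelated(self, cfg):
        D = gen_diversity_field(cfg)
        lag1 = pearsonr(D[:, :-1].ravel(), D[:, 1:].ravel()).statistic
        assert lag1 > 0.5


class TestReflectanceScene:
    def test_diversity_raises_spectral_variance(self, cfg):
        flat_lo = gen_reflectance_scene(np.zeros((40, 40)), cfg, 0)
        flat_hi = gen_reflectance_scene(np.ones((40, 40)), cfg, 0)

        def mean_window_sd(scene):
            return np.mean([b.values.std() for b in scene.bands])

        assert mean_window_sd(flat_hi) > 5 * mean_window_sd(flat_lo)

    def test_monoculture_scene_is_noise_floor(self, cfg):
        scene = gen_reflectance_scene(np.zeros((40, 40)), cfg, 0)
        sds = [b.values.std() for b in scene.bands]
        assert max(sds) < 3 * cfg.refl_noise_sd

    def test_reflectance_within_physical_range(self, cfg):
        scene = gen_reflectance_scene(gen_diversity_field(cfg), cfg, 0)
        for b in scene.bands:
            assert b.values.min() >= 0.0 and b.values.max() <= 1.0


class TestSpei:
    def test_deterministic(self, cfg, truth_bundle):
        ai = truth_bundle[3].ai_coarse
        a = gen_spei(cfg, ai)[1].values
        b = gen_spei(cfg, ai)[1].values
        np.testing.assert_array_equal(a, b)

    def test_humid_cells_standardized_over_study_window(self, cfg, truth_bundle):
        # the wettest column has no planted drying trend, so its study-window
        # per-month moments stay near (0, 1)
        spei1 = gen_spei(cfg, truth_bundle[3].ai_coarse)[1]
        col = spei1.values[:, :, :, -1]
        mean = np.nanmean(col, axis=0)
        sd = np.nanstd(col, axis=0, ddof=1)
        assert np.abs(mean).max() < 0.5
        assert np.abs(sd - 1).max() < 0.35

    def test_lag1_autocorrelation_near_phi_in_humid_cells(self, cfg, truth_bundle):
        spei1 = gen_spei(cfg, truth_bundle[3].ai_coarse)[1]
        series = spei1.values[:, :, 0, -1].ravel()
        r = pearsonr(series[:-1], series[1:]).statistic
        assert abs(r - cfg.ar1_phi) < 0.15

    def test_arid_cells_droughtier_than_humid_in_study_window(self, cfg, truth_bundle):
        spei12 = gen_spei(cfg, truth_bundle[3].ai_coarse)[12]
        freq = drought_frequency(spei12).frequency.values
        assert freq[:, 0].mean() > freq[:, -1].mean()

    def test_timescales_progressively_smoother(self, cfg, truth_bundle):
        spei = gen_spei(cfg, truth_bundle[3].ai_coarse)

        def lag1(stack):
            s = stack.values[:, :, 0, 0].ravel()
            s = s[~np.isnan(s)]
            return pearsonr(s[:-1], s[1:]).statistic

        assert lag1(spei[1]) < lag1(spei[3]) < lag1(spei[6])


class TestViCoupling:
    def test_planted_sensitivity_recovered_by_correlation(self, cfg, truth_bundle):
        from divdrought.drought_metrics import SPEIStack
        from divdrought.sensitivity import dry_season_gamma
        from divdrought.synthetic_data import coarse_to_fine
        from divdrought.vegetation_indices import standardize_svi

        s = np.full((40, 40), 0.6)
        spei1 = gen_spei(cfg, truth_bundle[3].ai_coarse)[1]
        vi = gen_vi_stack(s, spei1, cfg)
        svi = standardize_svi(vi, min_years=10)
        fine = SPEIStack(cfg.grid(), cfg.study_years, coarse_to_fine(spei1.values, cfg), 1)
        g = dry_season_gamma(svi, fine, 30)
        assert np.nanmean(g.gamma.values) == pytest.approx(0.6, abs=0.05)

    def test_uncoupled_pixels_center_on_zero(self, cfg, truth_bundle):
        from divdrought.drought_metrics import SPEIStack
        from divdrought.sensitivity import dry_season_gamma
        from divdrought.synthetic_data import coarse_to_fine
        from divdrought.vegetation_indices import standardize_svi

        spei1 = gen_spei(cfg, truth_bundle[3].ai_coarse)[1]
        vi = gen_vi_stack(np.zeros((40, 40)), spei1, cfg)
        svi = standardize_svi(vi, min_years=10)
        fine = SPEIStack(cfg.grid(), cfg.study_years, coarse_to_fine(spei1.values, cfg), 1)
        g = dry_season_gamma(svi, fine, 30)
        assert abs(np.nanmean(g.gamma.values)) < 0.05

    def test_vi_within_index_range(self, cfg, truth_bundle):
        spei1 = gen_spei(cfg, truth_bundle[3].ai_coarse)[1]
        vi = gen_vi_stack(truth_bundle[3].sensitivity_field, spei1, cfg)
        v = vi.vi[~np.isnan(vi.vi)]
        assert v.min() >= -1.0 and v.max() <= 1.0


class TestClimateTruth:
    def test_aridity_round_trip(self, cfg, truth_bundle):
        p, pet, cgrid, truth = truth_bundle
        out = aridity_index(p, pet, cgrid)
        err = np.abs(out.ai.values - truth.ai_coarse)
        assert err.max() <= 0.02

    def test_diversity_sensitivity_negatively_coupled_within_strata(self, cfg, truth_bundle):
        _, _, _, truth = truth_bundle
        dry = truth.ai_field < 0.5
        r = pearsonr(truth.diversity_field[dry], truth.sensitivity_field[dry]).statistic
        assert r < -0.5

    def test_benefit_stronger_in_dry_strata(self, cfg, truth_bundle):
        _, _, _, truth = truth_bundle
        dry = truth.ai_field < 0.45
        wet = truth.ai_field > 0.75
        r_dry = pearsonr(truth.diversity_field[dry], truth.sensitivity_field[dry]).statistic
        r_wet = pearsonr(truth.diversity_field[wet], truth.sensitivity_field[wet]).statistic
        assert r_dry < r_wet


class TestMaskZones:
    def test_zones_partition_grid(self, cfg):
        D = gen_diversity_field(cfg)
        _, zones, _ = gen_mask_and_zones(cfg, D)
        total = sum(geom.area for _, geom in zones.zones)
        assert total == pytest.approx(cfg.n_rows * cfg.n_cols)
        for i, (_, a) in enumerate(zones.zones):
            for _, b in zones.zones[i + 1 :]:
                assert a.intersection(b).area == pytest.approx(0.0)

    def test_richness_one_row_per_zone(self, cfg):
        D = gen_diversity_field(cfg)
        _, zones, richness = gen_mask_and_zones(cfg, D)
        assert len(richness) == len(zones.zones)
        assert set(richness.zone_id) == {z for z, _ in zones.zones}

    def test_forest_fraction_near_target(self, cfg):
        mask, _, _ = gen_mask_and_zones(cfg, gen_diversity_field(cfg))
        assert mask.is_forest.mean() == pytest.approx(cfg.forest_fraction, abs=0.05)


class TestBundle:
    def test_generate_all_consistent_shapes(self, cfg):
        ds = generate_all(cfg)
        assert ds.vi_stack.vi.shape == (cfg.n_years, 12, 40, 40)
        assert ds.scenes[0].grid.shape == (280, 280)
        assert ds.spei[12].values.shape[2:] == ds.coarse_grid.shape
        assert len(ds.richness) == cfg.zone_partition**2

    def test_generate_all_reproducible(self, cfg):
        a = generate_all(cfg)
        b = generate_all(cfg)
        np.testing.assert_array_equal(a.vi_stack.vi, b.vi_stack.vi)
        np.testing.assert_array_equal(a.truth.sensitivity_field, b.truth.sensitivity_field)
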