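"""End-to-end orchestration of the diversity-drought-resistance analysis.

Stage order mirrors the analysis design: diversity mapping from reflectance
scenes, vegetation-index standardization, pixelwise drought sensitivity
(per month and pooled dry season), climate and drought-frequency grids,
non-overlapping moving-window correlation, and the dryness-trend summary.
``run_pipeline`` executes everything on a synthetic dataset (or one loaded
from files by the CLI) and returns a machine-readable report.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .drought_metrics import aridity_index, drought_frequency, label_drought_years
from .raster_grid import MaskedRaster, resample_nearest
from .sensitivity import DRY_SEASON_MONTHS, dry_season_gamma, monthly_gamma_maps, positive_area_proportion
from .spectral_diversity import DiversityMap, aggregate_diversity, average_diversity, window_cv
from .synthetic_data import SyntheticConfig, SyntheticDataset, generate_all
from .vegetation_indices import standardize_svi
from .window_analysis import block_relationship, negative_proportion, trend_vs_dryness
from .zonal_validation import richness_correlation, zonal_stats

__all__ = ["PipelineConfig", "run_pipeline", "diversity_from_scenes"]


@dataclass
class PipelineConfig:
    """Analysis parameters; defaults are the study's standard choices."""

    window_size: int = 7
    min_valid: int = 10
    block_sizes: tuple[int, ...] = (30, 40, 50, 60)
    main_block_size: int = 50
    min_pixels: int = 30
    min_years: int = 10
    min_samples_monthly: int = 10
    min_samples_pooled: int = 30
    dry_months: frozenset = DRY_SEASON_MONTHS
    spei_timescales: tuple[int, ...] = (1, 3, 6)
    drought_threshold: float = -0.5
    seed: int = 0


def diversity_from_scenes(scenes, forest_mask_fine, target_grid, cfg: PipelineConfig) -> DiversityMap:
    """Per-scene windowed CV, multi-scene average, block-mean aggregation
    to the analysis grid."""
    maps = [window_cv(s, forest_mask_fine, cfg.window_size, cfg.min_valid) for s in scenes]
    return aggregate_diversity(average_diversity(maps), target_grid)


def _fine_forest_mask(dataset: SyntheticDataset):
    """Forest mask on the reflectance grid (1-km mask replicated)."""
    from .raster_grid import ForestMask

    f = dataset.cfg.fine_factor
    fine = np.repeat(np.repeat(dataset.forest_mask.is_forest, f, axis=0), f, axis=1)
    return ForestMask(dataset.cfg.fine_grid(), fine)


def run_pipeline(pcfg: PipelineConfig | None = None, dataset: SyntheticDataset | None = None,
                 sim_cfg: SyntheticConfig | None = None) -> dict:
    """Run every stage and return the report dictionary.

    Works on a prepared :class:`SyntheticDataset`; when none is given one
    is generated from ``sim_cfg`` (default config at ``pcfg.seed``).
    """
    pcfg = pcfg or PipelineConfig()
    if dataset is None:
        dataset = generate_all(sim_cfg or SyntheticConfig(seed=pcfg.seed))
    scfg = dataset.cfg
    grid = scfg.grid()

    # --- diversity -------------------------------------------------------
    dmap = diversity_from_scenes(dataset.scenes, _fine_forest_mask(dataset), grid, pcfg)

    # --- vegetation anomalies -------------------------------------------
    svi = standardize_svi(dataset.vi_stack, min_years=pcfg.min_years)

    # --- climate grids ---------------------------------------------------
    climate = aridity_index(dataset.p_annual, dataset.pet_annual, dataset.coarse_grid)
    spei12 = dataset.spei[12]
    freq = drought_frequency(spei12, pcfg.drought_threshold)
    ai_1km = resample_nearest(climate.ai, grid)
    freq_1km = resample_nearest(freq.frequency, grid)
    year_labels = label_drought_years(spei12)

    # --- drought sensitivity --------------------------------------------
    report: dict = {
        "pipeline_config": {k: (sorted(v) if isinstance(v, frozenset) else v)
                            for k, v in asdict(pcfg).items()},
        "seed": scfg.seed,
        "grid": {"n_rows": grid.n_rows, "n_cols": grid.n_cols},
        "drought_years": {str(y): lab for y, lab in year_labels.items()},
        "monthly_positive_proportion": {},
        "dry_season": {},
        "blocks": {},
        "trend": {},
    }
    masked_valid = dataset.forest_mask.is_forest
    gamma_maps = {}
    for k in pcfg.spei_timescales:
        spei_1km_vals = np.stack([
            np.stack([resample_nearest(
                MaskedRaster.from_nodata(dataset.coarse_grid, dataset.spei[k].values[y, m], float("nan")),
                grid).masked_values() for m in range(12)])
            for y in range(len(scfg.study_years))])
        from .drought_metrics import SPEIStack

        spei_fine = SPEIStack(grid, scfg.study_years, spei_1km_vals, k)
        monthly = monthly_gamma_maps(svi, spei_fine, pcfg.min_samples_monthly)
        report["monthly_positive_proportion"][f"spei_{k}"] = {
            str(m): _safe_prop(monthly[m], masked_valid) for m in range(1, 13)
        }
        g = dry_season_gamma(svi, spei_fine, pcfg.min_samples_pooled, pcfg.dry_months)
        g = _apply_forest_mask(g, masked_valid)
        gamma_maps[k] = g
        report["dry_season"][f"spei_{k}"] = {
            "positive_proportion": positive_area_proportion(g),
            "n_valid_pixels": int(g.gamma.valid.sum()),
        }

    # --- moving windows --------------------------------------------------
    covs = {"ai": ai_1km, "drought_freq": freq_1km}
    g_main = gamma_maps[pcfg.spei_timescales[0]]
    for bs in pcfg.block_sizes:
        blocks = block_relationship(dmap, g_main, covs, bs, pcfg.min_pixels)
        entry = {"n_blocks": len(blocks)}
        if blocks:
            entry["negative_proportion"] = negative_proportion(blocks)
        report["blocks"][str(bs)] = entry
        if bs == pcfg.main_block_size and len(blocks) >= 3:
            for covname in ("ai", "drought_freq"):
                t = trend_vs_dryness(blocks, covname)
                report["trend"][covname] = {
                    "slope": t.slope, "slope_se": t.slope_se, "intercept": t.intercept,
                    "spearman_rho": t.spearman_rho, "spearman_p": t.spearman_p,
                    "n_blocks": t.n_blocks, "proportion_negative": t.proportion_negative,
                }

    # --- zonal validation ------------------------------------------------
    ztab = zonal_stats(dmap, dataset.zones)
    report["zonal"] = richness_correlation(ztab, dataset.richness)
    return report


def _apply_forest_mask(smap, is_forest):
    out_valid = smap.gamma.valid & is_forest
    gamma = np.where(out_valid, smap.gamma.values, np.nan)
    from .raster_grid import MaskedRaster as MR
    from .sensitivity import SensitivityMap

    return SensitivityMap(smap.grid, MR(smap.grid, gamma, out_valid), smap.n_samples,
                          smap.p_value, smap.vi_kind, smap.spei_timescale, smap.month_set)


def _safe_prop(smap, is_forest) -> float | None:
    m = _apply_forest_mask(smap, is_forest)
    try:
        return positive_area_proportion(m)
    except ValueError:
        return None
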