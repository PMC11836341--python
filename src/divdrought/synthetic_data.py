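"""Synthetic study-area generator with recorded ground truth.

Every input the analysis pipeline consumes — multiband reflectance scenes,
monthly drought-index stacks, coupled vegetation-index series, annual
P/PET climate stacks, a forest mask, zone polygons with a richness table —
is generated here from a handful of planted fields, so each stage and the
end-to-end result can be validated against known truth:

* a spatially smooth latent diversity field ``D`` in [0, 1] drives local
  spectral heterogeneity (more species signatures mixed per neighborhood);
* an aridity gradient runs west to east; drought sensitivity is planted as
  ``s = clip(base_sens - b(AI) * D + noise)`` with the diversity benefit
  slope ``b`` decreasing toward the humid end, so diversity confers more
  drought resistance where the climate is drier;
* monthly vegetation anomalies are coupled to the one-month drought index
  with coefficient ``s`` in dry-season months and ``wet_coupling * s``
  otherwise;
* the drought index is an AR(1) water-balance proxy standardized per
  calendar month over a 1990-2018 calibration window.  A drying trend
  scaled by aridity makes the 2000-2018 study window register elevated
  drought frequency in arid cells — the behavior a long-calibration
  standardized index shows over a recent drying period.

Everything is a pure function of the config (including its seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .raster_grid import ForestMask, GridSpec, MaskedRaster, block_aggregate
from .drought_metrics import SPEIStack, multi_timescale_spei
from .spectral_diversity import ReflectanceScene
from .vegetation_indices import MonthlyVIStack
from .zonal_validation import ZoneSet

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "default_benefit_slope",
    "gen_diversity_field",
    "gen_reflectance_scene",
    "gen_spei",
    "gen_vi_stack",
    "gen_climate_and_truth",
    "gen_mask_and_zones",
    "generate_all",
]


def default_benefit_slope(ai: np.ndarray) -> np.ndarray:
    """Diversity-benefit slope b(AI) = 0.8 * (1.05 - AI), clipped to [0, 0.8]:
    strongest where the climate is driest, near zero at the humid end."""
    return np.clip(0.8 * (1.05 - np.asarray(ai, dtype=float)), 0.0, 0.8)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic study area.

    The defaults describe the emulated study conditions: a 120 x 120 km
    domain at 1 km, reflectance at 1/7 km, 10 spectral bands, up to 15
    species, 19 study years (2000-2018) inside a 29-year drought-index
    calibration window, a dry season of Jan-Apr + Nov-Dec, and an aridity
    gradient spanning semi-arid to humid (0.2-1.0).
    """

    seed: int = 0
    n_rows: int = 120
    n_cols: int = 120
    cell_size: float = 1.0            # km
    fine_factor: int = 7              # reflectance cells per km
    coarse_factor: int = 20           # km per climate/drought-index cell
    n_bands: int = 10
    n_species: int = 15
    study_start_year: int = 2000
    n_years: int = 19
    calib_start_year: int = 1990
    n_climate_years: int = 31         # annual P/PET record length
    dry_months: frozenset = frozenset({1, 2, 3, 4, 11, 12})
    ai_range: tuple[float, float] = (0.2, 1.0)
    base_sens: float = 0.7
    benefit_slope_fn: Callable[[np.ndarray], np.ndarray] = default_benefit_slope
    wet_coupling: float = 0.1
    ar1_phi: float = 0.5
    regional_weight: float = 0.7      # spatial coherence of the monthly proxy
    regime_amp: float = 0.3           # shared interannual (drought-year) component
    drying_max: float = 1.5           # sd of drying over calibration at the arid end
    diversity_blur: float = 8.0       # Gaussian blur radius of the latent field, cells
    refl_noise_sd: float = 0.01
    sens_noise_sd: float = 0.03
    vi_month_sd: float = 0.05
    forest_fraction: float = 0.9
    n_scenes: int = 3
    zone_partition: int = 4           # pseudo-counties per axis

    @property
    def study_years(self) -> list[int]:
        return list(range(self.study_start_year, self.study_start_year + self.n_years))

    @property
    def calib_years(self) -> list[int]:
        return list(range(self.calib_start_year, self.study_start_year + self.n_years))

    def grid(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, self.cell_size, (0.0, 0.0), "synthetic-km")

    def fine_grid(self) -> GridSpec:
        return GridSpec(self.n_rows * self.fine_factor, self.n_cols * self.fine_factor,
                        self.cell_size / self.fine_factor, (0.0, 0.0), "synthetic-km")

    def coarse_grid(self) -> GridSpec:
        return self.grid().scaled(self.coarse_factor)

    def rng(self, *key) -> np.random.Generator:
        """Independent deterministic stream per artifact (stable across
        processes: strings are keyed by CRC32, not the salted builtin hash)."""
        ints = [zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in key]
        return np.random.default_rng(np.random.SeedSequence([int(self.seed) % (2**31), *ints]))


@dataclass
class GroundTruth:
    """Planted fields, recorded exactly as used by the generator."""

    diversity_field: np.ndarray       # [0, 1], 1-km grid
    sensitivity_field: np.ndarray     # [0, 0.95], 1-km grid
    ai_field: np.ndarray              # 1-km grid
    ai_coarse: np.ndarray             # climate grid
    species_signatures: np.ndarray    # (n_species, n_bands)
    species_count: np.ndarray         # local pool size k per 1-km cell


def gen_diversity_field(cfg: SyntheticConfig) -> np.ndarray:
    """Latent diversity: low-pass-filtered white noise rescaled to [0, 1]."""
    rng = cfg.rng("diversity")
    noise = rng.standard_normal((cfg.n_rows, cfg.n_cols))
    smooth = gaussian_filter(noise, sigma=cfg.diversity_blur, mode="reflect")
    lo, hi = smooth.min(), smooth.max()
    if hi - lo < 1e-12:
        return np.full_like(smooth, 0.5)
    return (smooth - lo) / (hi - lo)


def _species_signatures(cfg: SyntheticConfig) -> np.ndarray:
    """Fixed per-seed species signature table, ordered from the spectral
    centroid outward so that the nested prefix pools used by
    :func:`gen_reflectance_scene` grow in spread as the pool size grows
    (the monotonicity the spectral variation hypothesis rests on)."""
    rng = cfg.rng("signatures")
    centroid = rng.uniform(0.28, 0.38, size=cfg.n_bands)
    signs = rng.choice([-1.0, 1.0], size=(cfg.n_species, cfg.n_bands))
    radius = np.linspace(0.0, 1.0, cfg.n_species)[:, None]
    jitter = rng.uniform(0.6, 1.0, size=(cfg.n_species, cfg.n_bands))
    sigs = centroid[None] + 0.27 * radius * signs * jitter
    return np.clip(sigs, 0.05, 0.6)


def species_count_field(cfg: SyntheticConfig, D: np.ndarray) -> np.ndarray:
    """Local species-pool size k = 1 + round(D * (n_species - 1))."""
    return 1 + np.round(np.asarray(D) * (cfg.n_species - 1)).astype(int)


def gen_reflectance_scene(D: np.ndarray, cfg: SyntheticConfig, scene_index: int = 0) -> ReflectanceScene:
    """Fine-grid reflectance scene whose local spectral variance grows with D.

    Each fine pixel draws one signature uniformly from the nested local
    pool of the first k species (k set by the 1-km diversity value), plus
    Gaussian sensor noise, clipped to [0, 1].  Neighboring pixels share the
    pool but draw independently.
    """
    sigs = _species_signatures(cfg)
    k_coarse = species_count_field(cfg, D)
    f = cfg.fine_factor
    k_fine = np.repeat(np.repeat(k_coarse, f, axis=0), f, axis=1)
    rng = cfg.rng("scene", scene_index)
    u = rng.random(k_fine.shape)
    idx = np.minimum((u * k_fine).astype(int), k_fine - 1)
    refl = sigs[idx]  # (fr, fc, n_bands)
    refl = refl + rng.normal(0.0, cfg.refl_noise_sd, size=refl.shape)
    refl = np.clip(refl, 0.0, 1.0)
    grid = cfg.fine_grid()
    bands = [MaskedRaster.full(grid, np.ascontiguousarray(refl[:, :, b])) for b in range(cfg.n_bands)]
    return ReflectanceScene(grid, bands)


def _ar1(rng: np.random.Generator, n_steps: int, shape: tuple, phi: float) -> np.ndarray:
    out = np.empty((n_steps, *shape))
    out[0] = rng.standard_normal(shape)
    innov_sd = np.sqrt(1.0 - phi * phi)
    for t in range(1, n_steps):
        out[t] = phi * out[t - 1] + innov_sd * rng.standard_normal(shape)
    return out


def gen_spei(cfg: SyntheticConfig, ai_coarse: np.ndarray) -> dict[int, SPEIStack]:
    """Monthly drought-index stacks at 1/3/6/12-month timescales.

    The monthly water-balance proxy per coarse cell mixes a shared regional
    AR(1) series (weight ``regional_weight``) with a local AR(1) series,
    plus a shared interannual component (drought/wet years) and a drying
    trend whose amplitude scales with planted aridity.  Each timescale is a
    trailing mean re-standardized per calendar month over the calibration
    years; the returned stacks cover the study years only.
    """
    cgrid = cfg.coarse_grid()
    if np.asarray(ai_coarse).shape != cgrid.shape:
        raise ValueError("ai_coarse must be on the coarse grid")
    calib = cfg.calib_years
    n_cal = len(calib)
    T = n_cal * 12
    rng = cfg.rng("spei")
    w = float(np.clip(cfg.regional_weight, 0.0, 1.0))
    regional = _ar1(rng, T, (), cfg.ar1_phi)
    local = _ar1(rng, T, cgrid.shape, cfg.ar1_phi)
    proxy = w * regional[:, None, None] + np.sqrt(1.0 - w * w) * local
    yearly = rng.standard_normal(n_cal)
    proxy += cfg.regime_amp * np.repeat(yearly, 12)[:, None, None]
    lo, hi = cfg.ai_range
    dryness = np.clip(1.0 - (np.asarray(ai_coarse, float) - lo) / max(hi - lo, 1e-12), 0.0, 1.0)
    ramp = np.linspace(0.0, 1.0, T)
    proxy = proxy - cfg.drying_max * dryness[None] * ramp[:, None, None]
    proxy = proxy.reshape(n_cal, 12, *cgrid.shape)
    n_study = cfg.n_years
    out: dict[int, SPEIStack] = {}
    for k in (1, 3, 6, 12):
        full = multi_timescale_spei(proxy, cgrid, calib, k)
        out[k] = SPEIStack(cgrid, cfg.study_years, full.values[n_cal - n_study:], k)
    return out


def coarse_to_fine(values: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """Replicate coarse-grid cells onto the 1-km grid (nearest neighbor on
    aligned grids), cropping the padded edge."""
    f = cfg.coarse_factor
    rep = np.repeat(np.repeat(values, f, axis=-2), f, axis=-1)
    return rep[..., : cfg.n_rows, : cfg.n_cols]


def gen_vi_stack(s: np.ndarray, spei1: SPEIStack, cfg: SyntheticConfig) -> MonthlyVIStack:
    """Monthly VI series coupled to the one-month drought index.

    VI(i, j) = mu_i + sigma * u with a seasonal sinusoid mu_i in
    [0.3, 0.8], sigma = ``vi_month_sd`` and u = c_i z + sqrt(1 - c_i^2) e,
    where z is the cell's one-month index, e is standard normal, and the
    coupling c_i equals the planted sensitivity s in dry-season months and
    ``wet_coupling * s`` otherwise.
    """
    s = np.clip(np.asarray(s, dtype=float), 0.0, 0.95)
    grid = cfg.grid()
    if s.shape != grid.shape:
        raise ValueError("sensitivity field must be on the 1-km grid")
    z = coarse_to_fine(spei1.values, cfg)  # (years, 12, rows, cols)
    months = np.arange(1, 13)
    mu = 0.55 + 0.25 * np.cos(2.0 * np.pi * (months - 8) / 12.0)
    c = np.where(np.isin(months, list(cfg.dry_months)), 1.0, cfg.wet_coupling)[None, :, None, None] * s[None, None]
    rng = cfg.rng("vi")
    eps = rng.standard_normal(z.shape)
    u = c * z + np.sqrt(1.0 - c * c) * eps
    vi = mu[None, :, None, None] + cfg.vi_month_sd * u
    vi = np.clip(vi, -1.0, 1.0)
    vi[np.isnan(z)] = np.nan
    return MonthlyVIStack(grid, cfg.study_years, vi, vi_kind="NDVI")


def gen_climate_and_truth(cfg: SyntheticConfig, D: np.ndarray | None = None):
    """Annual P/PET stacks on the coarse grid plus the full ground truth.

    The aridity field is a smooth west-east gradient over ``ai_range``
    (plus small smooth noise); PET is a constant 1000 mm/yr and annual
    precipitation is AI * PET with 1% multiplicative noise, so the aridity
    index computed from the generated stacks recovers the planted field.
    The planted sensitivity is s = clip(base_sens - b(AI) * D + noise).
    """
    if D is None:
        D = gen_diversity_field(cfg)
    grid = cfg.grid()
    rng = cfg.rng("climate")
    lo, hi = cfg.ai_range
    gradient = np.linspace(lo, hi, cfg.n_cols)[None, :] * np.ones((cfg.n_rows, 1))
    bump = gaussian_filter(rng.standard_normal(grid.shape), sigma=cfg.diversity_blur, mode="reflect")
    bump = 0.02 * bump / max(np.abs(bump).max(), 1e-12)
    ai_field = np.clip(gradient + bump, 0.01, None)
    ai_coarse = block_aggregate(MaskedRaster.full(grid, ai_field), cfg.coarse_factor).values
    pet = np.full((cfg.n_climate_years, *ai_coarse.shape), 1000.0)
    p = ai_coarse[None] * pet * (1.0 + 0.01 * rng.standard_normal(pet.shape))
    b = cfg.benefit_slope_fn(ai_field)
    s = np.clip(cfg.base_sens - b * np.asarray(D) + rng.normal(0.0, cfg.sens_noise_sd, grid.shape),
                0.0, 0.95)
    truth = GroundTruth(
        diversity_field=np.asarray(D, float),
        sensitivity_field=s,
        ai_field=ai_field,
        ai_coarse=ai_coarse,
        species_signatures=_species_signatures(cfg),
        species_count=species_count_field(cfg, D),
    )
    return p, pet, cfg.coarse_grid(), truth


def gen_mask_and_zones(cfg: SyntheticConfig, D: np.ndarray):
    """Forest mask with random non-forest holes, rectangular pseudo-county
    zones on a ``zone_partition``^2 partition, and a richness table.

    Zone richness is the sum of the local species-pool size over the
    zone's cells with 5% multiplicative noise — the survey analogue of the
    planted diversity.
    """
    grid = cfg.grid()
    rng = cfg.rng("mask")
    is_forest = rng.random(grid.shape) < cfg.forest_fraction
    mask = ForestMask(grid, is_forest)

    k = species_count_field(cfg, D)
    npart = cfg.zone_partition
    row_edges = np.linspace(0, cfg.n_rows, npart + 1).astype(int)
    col_edges = np.linspace(0, cfg.n_cols, npart + 1).astype(int)
    zones = []
    rows = []
    x0g, y0g = grid.origin
    for i in range(npart):
        for j in range(npart):
            r0, r1 = row_edges[i], row_edges[i + 1]
            c0, c1 = col_edges[j], col_edges[j + 1]
            zid = f"zone_{i}_{j}"
            geom = box(x0g + c0 * grid.cell_size, y0g - r1 * grid.cell_size,
                       x0g + c1 * grid.cell_size, y0g - r0 * grid.cell_size)
            zones.append((zid, geom))
            richness = float(k[r0:r1, c0:c1].sum())
            rows.append({"zone_id": zid,
                         "richness": richness * (1.0 + 0.05 * rng.standard_normal())})
    return mask, ZoneSet(zones), pd.DataFrame(rows)


@dataclass
class SyntheticDataset:
    """Bundle of all generated pipeline inputs plus their ground truth."""

    cfg: SyntheticConfig
    truth: GroundTruth
    scenes: list[ReflectanceScene]
    spei: dict[int, SPEIStack]
    vi_stack: MonthlyVIStack
    p_annual: np.ndarray
    pet_annual: np.ndarray
    coarse_grid: GridSpec
    forest_mask: ForestMask
    zones: ZoneSet
    richness: pd.DataFrame


def generate_all(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate every pipeline input from one config."""
    D = gen_diversity_field(cfg)
    p, pet, cgrid, truth = gen_climate_and_truth(cfg, D)
    spei = gen_spei(cfg, truth.ai_coarse)
    vi = gen_vi_stack(truth.sensitivity_field, spei[1], cfg)
    scenes = [gen_reflectance_scene(D, cfg, i) for i in range(cfg.n_scenes)]
    mask, zones, richness = gen_mask_and_zones(cfg, D)
    return SyntheticDataset(cfg, truth, scenes, spei, vi, p, pet, cgrid, mask, zones, richness)
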