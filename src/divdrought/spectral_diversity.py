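"""Windowed coefficient-of-variation plant-diversity index.

The spectral variation hypothesis posits that the spatial variability of
reflectance among neighboring pixels tracks plant diversity: a stand with
more species mixes more distinct spectral signatures, so a small window
around a pixel shows higher per-band dispersion.  The index computed here
is, for each forest pixel, the per-band coefficient of variation
std(rho_lambda)/mean(rho_lambda) over the valid forest pixels of a
window_size x window_size neighborhood, averaged over the bands.

Windows are clipped at image edges; non-forest and invalid pixels never
contribute.  The standard deviation uses the sample convention (n-1) by
default, switchable via ``ddof``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster_grid import ForestMask, GridSpec, MaskedRaster, block_aggregate

__all__ = ["ReflectanceScene", "DiversityMap", "window_cv", "average_diversity", "aggregate_diversity"]


@dataclass
class ReflectanceScene:
    """Multiband surface-reflectance image on one grid; values in [0, 1]."""

    grid: GridSpec
    bands: list[MaskedRaster]
    band_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.bands) < 1:
            raise ValueError("scene needs at least one band")
        for b in self.bands:
            if b.grid.shape != self.grid.shape:
                raise ValueError("all bands must share the scene grid")
        if self.band_labels is None:
            self.band_labels = [f"band{i + 1}" for i in range(len(self.bands))]

    @property
    def n_bands(self) -> int:
        return len(self.bands)


@dataclass
class DiversityMap:
    """CV diversity index map; dimensionless, >= 0 where valid."""

    grid: GridSpec
    cv: MaskedRaster
    window_size: int
    n_scenes_averaged: int = 1


def _window_sums(arr: np.ndarray, half: int) -> np.ndarray:
    """Sum of ``arr`` over the clipped (2*half+1)^2 window of every pixel,
    via a padded summed-area table (exact up to float64 rounding)."""
    n_rows, n_cols = arr.shape
    sat = np.zeros((n_rows + 1, n_cols + 1), dtype=np.float64)
    np.cumsum(arr, axis=0, out=sat[1:, 1:])
    np.cumsum(sat[1:, 1:], axis=1, out=sat[1:, 1:])
    r = np.arange(n_rows)
    c = np.arange(n_cols)
    r0 = np.clip(r - half, 0, n_rows)[:, None]
    r1 = np.clip(r + half + 1, 0, n_rows)[:, None]
    c0 = np.clip(c - half, 0, n_cols)[None, :]
    c1 = np.clip(c + half + 1, 0, n_cols)[None, :]
    return sat[r1, c1] - sat[r0, c1] - sat[r1, c0] + sat[r0, c0]


def window_cv(
    scene: ReflectanceScene,
    mask: ForestMask,
    window_size: int = 7,
    min_valid: int = 10,
    ddof: int = 1,
) -> DiversityMap:
    """Windowed CV diversity index of a reflectance scene.

    Parameters
    ----------
    scene : ReflectanceScene
        Multiband reflectance; bands are combined by averaging their CVs.
    mask : ForestMask
        Only forest pixels contribute to a window, and only forest pixels
        receive an index value.
    window_size : int
        Odd neighborhood side length (the field-standard choice is 7).
    min_valid : int
        Minimum number of contributing window pixels; windows with fewer
        become invalid, as do windows where any band has mean 0.
    ddof : int
        Delta degrees of freedom of the standard deviation (1 = sample).
    """
    if window_size % 2 == 0 or window_size < 3:
        raise ValueError("window_size must be odd and >= 3")
    if min_valid < 2:
        raise ValueError("min_valid must be >= 2")
    if mask.grid.shape != scene.grid.shape:
        raise ValueError("scene and forest mask grids differ")
    half = window_size // 2

    contrib = mask.is_forest.copy()
    for b in scene.bands:
        contrib &= b.valid
    n = _window_sums(contrib.astype(np.float64), half)
    ok = mask.is_forest & (n >= max(min_valid, ddof + 1))

    cv_sum = np.zeros(scene.grid.shape, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        for b in scene.bands:
            v = np.where(contrib, np.asarray(b.values, np.float64), 0.0)
            s1 = _window_sums(v, half)
            mean = s1 / np.maximum(n, 1)
            # center on the global mean before the variance sums: variance is
            # shift-invariant and this kills catastrophic cancellation on
            # near-constant windows
            shift = v[contrib].mean() if contrib.any() else 0.0
            vc = np.where(contrib, v - shift, 0.0)
            s1c = _window_sums(vc, half)
            s2c = _window_sums(vc * vc, half)
            var = (s2c - s1c * s1c / np.maximum(n, 1)) / np.maximum(n - ddof, 1)
            var = np.maximum(var, 0.0)  # guard tiny negative rounding
            ok &= mean != 0
            cv_sum += np.sqrt(var) / np.where(mean == 0, 1.0, mean)
    cv = np.where(ok, cv_sum / scene.n_bands, np.nan)
    return DiversityMap(scene.grid, MaskedRaster(scene.grid, cv, ok), window_size)


def average_diversity(maps: list[DiversityMap]) -> DiversityMap:
    """Cellwise mean of several CV maps (e.g. one per acquisition date).

    A cell valid in k >= 1 maps averages those k values; a cell valid
    nowhere stays invalid.
    """
    if not maps:
        raise ValueError("need at least one diversity map")
    grid = maps[0].grid
    w = maps[0].window_size
    for m in maps:
        if m.grid.shape != grid.shape or m.window_size != w:
            raise ValueError("maps must share grid and window size")
    total = np.zeros(grid.shape)
    count = np.zeros(grid.shape)
    for m in maps:
        total += np.where(m.cv.valid, m.cv.values, 0.0)
        count += m.cv.valid
    valid = count > 0
    cv = np.divide(total, count, out=np.full(grid.shape, np.nan), where=valid)
    return DiversityMap(grid, MaskedRaster(grid, cv, valid), w, n_scenes_averaged=len(maps))


def aggregate_diversity(dmap: DiversityMap, target: GridSpec) -> DiversityMap:
    """Block-mean aggregation of a fine CV map onto a coarser grid whose
    cell size is an integer multiple of the source's."""
    ratio = target.cell_size / dmap.grid.cell_size
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError("target cell size must be an integer multiple of source")
    agg = block_aggregate(dmap.cv, factor, reducer="mean")
    if agg.grid.shape != target.shape:
        raise ValueError(
            f"aggregated shape {agg.grid.shape} does not match target {target.shape}"
        )
    out = MaskedRaster(target, agg.values, agg.valid)
    return DiversityMap(target, out, dmap.window_size, dmap.n_scenes_averaged)
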