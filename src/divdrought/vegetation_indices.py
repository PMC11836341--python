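"""Monthly compositing, NDVI/EVI, and the standardized vegetation index.

The standardized vegetation index (SVI) expresses each month's vegetation
index as an anomaly against that calendar month's multi-year climatology:

    SVI[i, j] = (VI[i, j] - mu_i) / sigma_i

for calendar month i and year j, where mu_i and sigma_i are the across-year
mean and standard deviation of month i at that pixel.  Deseasonalizing this
way lets the anomaly be correlated against a standardized drought index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np

from .raster_grid import GridSpec, MaskedRaster

__all__ = [
    "EightDayReflectance",
    "MonthlyVIStack",
    "SVIStack",
    "monthly_composite",
    "ndvi",
    "evi",
    "standardize_svi",
]


@dataclass
class EightDayReflectance:
    """A stack of dated red/NIR/blue reflectance layers with a per-date
    clear-sky flag (quality masking reduced to one boolean per pixel)."""

    grid: GridSpec
    time_stamps: list[date]
    red: np.ndarray    # (n_dates, rows, cols)
    nir: np.ndarray
    blue: np.ndarray
    clear: np.ndarray  # boolean, same shape

    def __post_init__(self) -> None:
        n = len(self.time_stamps)
        shape = (n, *self.grid.shape)
        for name in ("red", "nir", "blue", "clear"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
            setattr(self, name, arr)
        self.clear = self.clear.astype(bool)


@dataclass
class MonthlyVIStack:
    """Per-pixel monthly vegetation-index series over years.

    ``vi`` is indexed (year, month, row, col) with NaN for missing slots;
    missing means absent, never zero.
    """

    grid: GridSpec
    years: list[int]
    vi: np.ndarray
    vi_kind: str = "NDVI"

    def __post_init__(self) -> None:
        self.vi = np.asarray(self.vi, dtype=float)
        expected = (len(self.years), 12, *self.grid.shape)
        if self.vi.shape != expected:
            raise ValueError(f"vi must have shape {expected}, got {self.vi.shape}")

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.vi)


@dataclass
class SVIStack:
    """Standardized vegetation-index anomalies with the per-pixel monthly
    climatology (mu_i, sigma_i) they were computed from."""

    grid: GridSpec
    years: list[int]
    svi: np.ndarray
    month_mean: np.ndarray  # (12, rows, cols)
    month_sd: np.ndarray
    vi_kind: str = "NDVI"

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.svi)


def monthly_composite(stack: EightDayReflectance, year: int, month: int):
    """Maximum-value composite of one month's clear observations.

    Returns (red, nir, blue) MaskedRasters; a pixel with no clear
    observation in the month is invalid.
    """
    sel = [k for k, d in enumerate(stack.time_stamps) if d.year == year and d.month == month]
    if not sel:
        raise ValueError(f"no acquisition dates in {year}-{month:02d}")
    out = []
    for arr in (stack.red, stack.nir, stack.blue):
        sub = np.asarray(arr[sel], dtype=float)
        clear = stack.clear[sel]
        sub = np.where(clear, sub, -np.inf)
        comp = sub.max(axis=0)
        valid = clear.any(axis=0)
        comp = np.where(valid, comp, np.nan)
        out.append(MaskedRaster(stack.grid, comp, valid))
    return tuple(out)


def ndvi(red: MaskedRaster, nir: MaskedRaster) -> MaskedRaster:
    """Normalized difference vegetation index (NIR - red)/(NIR + red)."""
    if red.grid.shape != nir.grid.shape:
        raise ValueError("red and nir grids differ")
    denom = np.asarray(nir.values, float) + np.asarray(red.values, float)
    valid = red.valid & nir.valid & (denom != 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (np.asarray(nir.values, float) - np.asarray(red.values, float)) / denom
    out[~valid] = np.nan
    return MaskedRaster(red.grid, out, valid)


def evi(red: MaskedRaster, nir: MaskedRaster, blue: MaskedRaster) -> MaskedRaster:
    """Enhanced vegetation index 2.5*(NIR - red)/(NIR + 6*red - 7.5*blue + 1)."""
    if not (red.grid.shape == nir.grid.shape == blue.grid.shape):
        raise ValueError("band grids differ")
    r = np.asarray(red.values, float)
    n = np.asarray(nir.values, float)
    b = np.asarray(blue.values, float)
    denom = n + 6.0 * r - 7.5 * b + 1.0
    valid = red.valid & nir.valid & blue.valid & (denom != 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 2.5 * (n - r) / denom
    out[~valid] = np.nan
    return MaskedRaster(red.grid, out, valid)


def standardize_svi(stack: MonthlyVIStack, min_years: int = 10, ddof: int = 1) -> SVIStack:
    """Standardize a monthly VI stack into per-calendar-month anomalies.

    Per pixel and calendar month the across-year mean and standard deviation
    (``ddof=1`` sample convention) are estimated from valid years; cells of
    months with fewer than ``min_years`` valid years, or zero spread, are
    invalid throughout.
    """
    if min_years < 2:
        raise ValueError("min_years must be >= 2")
    vi = stack.vi
    with np.errstate(invalid="ignore", divide="ignore"):
        n = np.sum(~np.isnan(vi), axis=0)
        mu = np.where(n > 0, np.nansum(vi, axis=0) / np.maximum(n, 1), np.nan)
        sd = np.full(mu.shape, np.nan)
        enough = n >= max(min_years, ddof + 1)
        # nanstd warns on all-NaN slices; compute only where defined
        sd_all = _nanstd(vi, ddof)
        sd[enough] = sd_all[enough]
        ok = enough & (sd > 0)
        svi = (vi - mu[None]) / sd[None]
    svi[:, ~ok] = np.nan
    mu = np.where(ok, mu, np.nan)
    sd = np.where(ok, sd, np.nan)
    return SVIStack(stack.grid, list(stack.years), svi, mu, sd, stack.vi_kind)


def _nanstd(vi: np.ndarray, ddof: int) -> np.ndarray:
    n = np.sum(~np.isnan(vi), axis=0).astype(float)
    mu = np.where(n > 0, np.nansum(vi, axis=0) / np.maximum(n, 1), np.nan)
    ss = np.nansum((vi - mu[None]) ** 2, axis=0)
    denom = np.maximum(n - ddof, 1)
    out = np.sqrt(ss / denom)
    out[n <= ddof] = np.nan
    return out
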