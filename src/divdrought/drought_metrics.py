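"""SPEI handling, aridity classification, and drought frequency.

The pipeline consumes standardized precipitation-evapotranspiration index
(SPEI) grids as an input product: values are standardized drought
indicators where a month below -0.5 counts as drought and below -2.0 as
exceptional drought.  Climate dryness is summarized by the aridity index

    AI = mean over years of (P_i / PET_i)

— the multi-year mean of the annual precipitation-to-potential-
evapotranspiration ratio (mean of ratios, not ratio of means) — and mapped
to the standard five aridity classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .raster_grid import GridSpec, MaskedRaster

logger = logging.getLogger(__name__)

__all__ = [
    "SPEIStack",
    "ClimateGrid",
    "DroughtFrequencyMap",
    "ClimateClass",
    "DROUGHT_THRESHOLD",
    "EXCEPTIONAL_DROUGHT_THRESHOLD",
    "aridity_index",
    "classify_climate",
    "drought_frequency",
    "label_drought_years",
    "multi_timescale_spei",
]

DROUGHT_THRESHOLD = -0.5
EXCEPTIONAL_DROUGHT_THRESHOLD = -2.0


class ClimateClass(IntEnum):
    """Aridity-index climate classes, driest to wettest."""

    HYPER_ARID = 1   # AI < 0.05
    ARID = 2         # 0.05 <= AI < 0.2
    SEMI_ARID = 3    # 0.2 <= AI < 0.5
    DRY_SUBHUMID = 4 # 0.5 <= AI < 0.65
    HUMID = 5        # AI >= 0.65


_CLASS_EDGES = np.array([0.05, 0.2, 0.5, 0.65])


@dataclass
class SPEIStack:
    """Monthly SPEI on a (typically coarse) grid, (year, month, row, col),
    NaN for missing slots; ``timescale`` is the accumulation window in
    months."""

    grid: GridSpec
    years: list[int]
    values: np.ndarray
    timescale: int = 1

    def __post_init__(self) -> None:
        if self.timescale not in (1, 3, 6, 12):
            raise ValueError("timescale must be one of 1, 3, 6, 12 months")
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.years), 12, *self.grid.shape)
        if self.values.shape != expected:
            raise ValueError(f"values must have shape {expected}")

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass
class ClimateGrid:
    """Aridity index and climate class per cell."""

    grid: GridSpec
    ai: MaskedRaster
    climate_class: np.ndarray
    n_years: int


@dataclass
class DroughtFrequencyMap:
    """Fraction of months whose SPEI falls below the drought threshold."""

    grid: GridSpec
    frequency: MaskedRaster
    threshold: float = DROUGHT_THRESHOLD
    timescale: int = 12


def classify_climate(ai):
    """Map aridity-index value(s) to :class:`ClimateClass` codes.

    Boundaries are closed on the left: 0.05 is Arid, 0.2 Semi-arid,
    0.5 Dry subhumid, 0.65 Humid.
    """
    arr = np.asarray(ai, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("aridity index must be non-negative")
    codes = 1 + np.searchsorted(_CLASS_EDGES, arr, side="right")
    if np.isscalar(ai) or arr.ndim == 0:
        return ClimateClass(int(codes))
    return codes.astype(np.int8)


def aridity_index(p_annual: np.ndarray, pet_annual: np.ndarray, grid: GridSpec,
                  valid: np.ndarray | None = None) -> ClimateGrid:
    """Aridity index from per-year precipitation and PET stacks.

    ``p_annual`` and ``pet_annual`` are (n_years, rows, cols).  Cells where
    any year has PET = 0 are invalidated with a warning rather than
    producing an infinite ratio.
    """
    p = np.asarray(p_annual, dtype=float)
    pet = np.asarray(pet_annual, dtype=float)
    if p.shape != pet.shape:
        raise ValueError("P and PET stacks must have equal year counts and shapes")
    if p.shape[1:] != grid.shape:
        raise ValueError("stack shape does not match grid")
    ok = np.ones(grid.shape, dtype=bool) if valid is None else np.asarray(valid, bool).copy()
    bad_pet = np.any(pet == 0, axis=0)
    if np.any(bad_pet & ok):
        logger.warning("invalidating %d cells with PET = 0", int(np.sum(bad_pet & ok)))
    ok &= ~bad_pet
    ok &= ~np.any(np.isnan(p) | np.isnan(pet), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ai = np.mean(p / np.where(pet == 0, np.nan, pet), axis=0)
    ai = np.where(ok, ai, np.nan)
    codes = np.where(ok, 1 + np.searchsorted(_CLASS_EDGES, np.where(ok, ai, 0.0), side="right"), 0)
    return ClimateGrid(grid, MaskedRaster(grid, ai, ok), codes.astype(np.int8), n_years=p.shape[0])


def drought_frequency(spei12: SPEIStack, threshold: float = DROUGHT_THRESHOLD) -> DroughtFrequencyMap:
    """Per-cell ratio of drought months (SPEI strictly below ``threshold``)
    to all months with a valid SPEI value."""
    if spei12.timescale != 12:
        raise ValueError("drought frequency is defined on the 12-month timescale")
    valid = spei12.valid
    n = valid.sum(axis=(0, 1))
    hits = (np.where(valid, spei12.values, np.inf) < threshold).sum(axis=(0, 1))
    ok = n > 0
    freq = np.divide(hits, n, out=np.full(spei12.grid.shape, np.nan), where=ok)
    return DroughtFrequencyMap(spei12.grid, MaskedRaster(spei12.grid, freq, ok),
                               threshold, spei12.timescale)


def label_drought_years(spei12: SPEIStack, region_mask: np.ndarray | None = None) -> dict[int, str]:
    """Label each year from the region-mean December 12-month SPEI.

    drought (< -0.5), exceptional drought (< -2.0), wet (> 0.5), otherwise
    normal; a year without a valid December is labeled unknown.
    """
    labels: dict[int, str] = {}
    for k, year in enumerate(spei12.years):
        dec = spei12.values[k, 11]
        sel = spei12.valid[k, 11]
        if region_mask is not None:
            sel = sel & region_mask
        if not sel.any():
            labels[year] = "unknown"
            continue
        v = float(dec[sel].mean())
        if v < EXCEPTIONAL_DROUGHT_THRESHOLD:
            labels[year] = "exceptional drought"
        elif v < DROUGHT_THRESHOLD:
            labels[year] = "drought"
        elif v > 0.5:
            labels[year] = "wet"
        else:
            labels[year] = "normal"
    return labels


def multi_timescale_spei(monthly: np.ndarray, grid: GridSpec, years: list[int],
                         timescale: int, min_years: int = 2) -> SPEIStack:
    """Build a k-month-timescale standardized index from a monthly series.

    The k-month trailing mean of the monthly water-balance proxy is
    re-standardized per calendar month (mean 0, sd 1 across years).  The
    first k-1 months lack history and are invalid.  This is the moving-mean
    construction used for synthetic drought indices; real multi-scale SPEI
    products are consumed as data.
    """
    monthly = np.asarray(monthly, dtype=float)
    n_years = len(years)
    flat = monthly.reshape(n_years * 12, *monthly.shape[2:])
    if flat.shape[0] < timescale:
        raise ValueError("series shorter than the requested timescale")
    c = np.cumsum(np.vstack([np.zeros((1, *flat.shape[1:])), flat]), axis=0)
    trail = np.full_like(flat, np.nan)
    trail[timescale - 1:] = (c[timescale:] - c[:-timescale]) / timescale
    trail = trail.reshape(n_years, 12, *monthly.shape[2:])
    mu = np.nanmean(trail, axis=0)
    nv = np.sum(~np.isnan(trail), axis=0)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(trail, axis=0, ddof=1)
    ok = (nv >= min_years) & (sd > 0)
    out = np.where(ok[None], (trail - mu[None]) / np.where(ok, sd, 1.0)[None], np.nan)
    return SPEIStack(grid, list(years), out, timescale)
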