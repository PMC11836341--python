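"""Pixelwise drought sensitivity: temporal correlation of SVI and SPEI.

Drought sensitivity gamma is the Pearson correlation between a pixel's
standardized vegetation-index anomaly series and its drought-index series
over a chosen set of calendar months.  High positive gamma means the
canopy's condition tracks water availability (drought-sensitive, low
resistance); gamma near zero or negative means the stand holds its state
through dry spells (drought-resistant).

Gamma maps are computed per calendar month (correlating across years,
n up to the number of years) or pooled over the dry season, where all
(year, month) pairs with month in the dry set enter one correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .raster_grid import GridSpec, MaskedRaster
from .drought_metrics import SPEIStack
from .vegetation_indices import SVIStack

__all__ = [
    "DRY_SEASON_MONTHS",
    "SensitivityMap",
    "pixel_gamma",
    "monthly_gamma_maps",
    "dry_season_gamma",
    "positive_area_proportion",
]

# study-area dry season: January-April plus November-December
DRY_SEASON_MONTHS = frozenset({1, 2, 3, 4, 11, 12})


@dataclass
class SensitivityMap:
    """Per-pixel gamma with sample counts and two-sided p-values."""

    grid: GridSpec
    gamma: MaskedRaster
    n_samples: np.ndarray
    p_value: MaskedRaster
    vi_kind: str = "NSVI"
    spei_timescale: int = 1
    month_set: frozenset = DRY_SEASON_MONTHS


def _masked_pearson(x: np.ndarray, y: np.ndarray, min_samples: int):
    """Pearson r of two (k, rows, cols) stacks along axis 0, ignoring NaNs.

    Returns (r, n, p).  Pixels with fewer than ``min_samples`` joint
    observations or zero variance in either series are NaN.
    """
    both = ~np.isnan(x) & ~np.isnan(y)
    n = both.sum(axis=0)
    xm = np.where(both, x, 0.0)
    ym = np.where(both, y, 0.0)
    nn = np.maximum(n, 1)
    mx = xm.sum(axis=0) / nn
    my = ym.sum(axis=0) / nn
    dx = np.where(both, x - mx[None], 0.0)
    dy = np.where(both, y - my[None], 0.0)
    sxy = (dx * dy).sum(axis=0)
    sxx = (dx * dx).sum(axis=0)
    syy = (dy * dy).sum(axis=0)
    # a series constant over its valid slots has no defined correlation
    x_const = np.where(both, x, -np.inf).max(axis=0) == np.where(both, x, np.inf).min(axis=0)
    y_const = np.where(both, y, -np.inf).max(axis=0) == np.where(both, y, np.inf).min(axis=0)
    ok = (n >= max(min_samples, 2)) & (sxx > 0) & (syy > 0) & ~x_const & ~y_const
    with np.errstate(invalid="ignore", divide="ignore"):
        r = sxy / np.sqrt(sxx * syy)
    r = np.clip(np.where(ok, r, np.nan), -1.0, 1.0)
    # two-sided p from the t transform: t = r sqrt((n-2)/(1-r^2))
    p = np.full(r.shape, np.nan)
    okp = ok & (n > 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        rr = np.where(okp, r, 0.0)
        df = np.maximum(n - 2, 1)
        t2 = rr * rr * df / np.maximum(1.0 - rr * rr, 1e-300)
        pv = special.betainc(df / 2.0, 0.5, df / (df + t2))
    p[okp] = pv[okp]
    p[ok & (n <= 2)] = 1.0
    return r, n, p


def pixel_gamma(
    svi: SVIStack,
    spei: SPEIStack,
    month_set,
    min_samples: int = 30,
    per_month_average: bool = False,
) -> SensitivityMap:
    """Gamma map from an SVI stack and an SPEI stack on the same grid.

    All (year, month) pairs with month in ``month_set`` and both values
    valid enter one pooled Pearson correlation per pixel.  With
    ``per_month_average`` the months are instead correlated separately
    (across years) and the per-month gammas averaged — a comparison
    variant, not the default.
    """
    months = sorted(set(int(m) for m in month_set))
    if not months:
        raise ValueError("month_set must not be empty")
    if any(m < 1 or m > 12 for m in months):
        raise ValueError("months must be in 1..12")
    if svi.grid.shape != spei.grid.shape:
        raise ValueError("SVI and SPEI stacks must share a grid (resample first)")
    if list(svi.years) != list(spei.years):
        raise ValueError("SVI and SPEI stacks must share the year layout")
    midx = [m - 1 for m in months]
    if per_month_average and len(months) > 1:
        per_month = max(2, min_samples // len(months))
        acc = np.zeros(svi.grid.shape)
        cnt = np.zeros(svi.grid.shape)
        ntot = np.zeros(svi.grid.shape, dtype=int)
        for mi in midx:
            r, n, _ = _masked_pearson(svi.svi[:, mi], spei.values[:, mi], per_month)
            good = ~np.isnan(r)
            acc += np.where(good, r, 0.0)
            cnt += good
            ntot += n
        ok = cnt == len(months)
        r = np.where(ok, acc / np.maximum(cnt, 1), np.nan)
        n, p = ntot, np.full(r.shape, np.nan)
    else:
        x = svi.svi[:, midx].reshape(-1, *svi.grid.shape)
        y = spei.values[:, midx].reshape(-1, *svi.grid.shape)
        r, n, p = _masked_pearson(x, y, min_samples)
        ok = ~np.isnan(r)
    return SensitivityMap(
        svi.grid,
        MaskedRaster(svi.grid, r, ok),
        np.asarray(n, dtype=int),
        MaskedRaster(svi.grid, p, ok & ~np.isnan(p)),
        vi_kind={"NDVI": "NSVI", "EVI": "ESVI"}.get(svi.vi_kind, svi.vi_kind),
        spei_timescale=spei.timescale,
        month_set=frozenset(months),
    )


def monthly_gamma_maps(svi: SVIStack, spei: SPEIStack, min_samples: int = 10) -> dict[int, SensitivityMap]:
    """One gamma map per calendar month, correlating across years."""
    return {m: pixel_gamma(svi, spei, {m}, min_samples) for m in range(1, 13)}


def dry_season_gamma(svi: SVIStack, spei: SPEIStack, min_samples: int = 30,
                     months=DRY_SEASON_MONTHS) -> SensitivityMap:
    """Pooled dry-season gamma (default months 1-4, 11, 12)."""
    return pixel_gamma(svi, spei, months, min_samples)


def positive_area_proportion(smap: SensitivityMap, sig_mask: float | None = None) -> float:
    """Fraction of valid pixels with strictly positive gamma.

    ``sig_mask`` optionally restricts to pixels with p-value below the
    given level before counting.
    """
    sel = smap.gamma.valid.copy()
    if sig_mask is not None:
        sel &= smap.p_value.valid & (smap.p_value.values < sig_mask)
    n = int(sel.sum())
    if n == 0:
        raise ValueError("no valid pixels in sensitivity map")
    return float(np.sum(smap.gamma.values[sel] > 0) / n)
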