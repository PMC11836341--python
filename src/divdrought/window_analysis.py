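"""Moving-window diversity-resistance analysis.

The map is partitioned into non-overlapping blocks (the window sizes of
interest are 30-60 km at 1 km resolution, 50 being the headline choice
because the climate grids are about half a degree).  Within each block the
Pearson correlation between the diversity index and the drought-sensitivity
gamma is computed over jointly valid pixels, alongside block means of
climate covariates (aridity index, drought frequency).  A negative block
correlation — higher diversity, lower drought sensitivity — is the
signature of a diversity benefit; the summary stage regresses the block
correlations on block dryness to ask where the benefit is strongest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .raster_grid import MaskedRaster, tile_blocks
from .spectral_diversity import DiversityMap
from .sensitivity import SensitivityMap

__all__ = ["BlockResult", "TrendSummary", "block_relationship", "negative_proportion",
           "trend_vs_dryness", "block_results_frame"]


@dataclass
class BlockResult:
    """Per-block diversity-sensitivity correlation and mean covariates."""

    block_id: tuple[int, int]
    n_pixels: int
    r_div_sens: float
    p_value: float
    covariate_means: dict[str, float] = field(default_factory=dict)
    partial: bool = False

    @property
    def mean_ai(self) -> float:
        return self.covariate_means.get("ai", float("nan"))

    @property
    def mean_drought_freq(self) -> float:
        return self.covariate_means.get("drought_freq", float("nan"))


@dataclass
class TrendSummary:
    """OLS and rank-correlation summary of block r against a covariate."""

    covariate: str
    slope: float
    intercept: float
    slope_se: float
    spearman_rho: float
    spearman_p: float
    n_blocks: int
    proportion_negative: float


def block_relationship(
    diversity: DiversityMap,
    sens: SensitivityMap,
    covariates: dict[str, MaskedRaster] | None = None,
    block_size: int = 50,
    min_pixels: int = 30,
    include_partial: bool = False,
) -> list[BlockResult]:
    """Correlate diversity against sensitivity in non-overlapping blocks.

    Blocks with fewer than ``min_pixels`` jointly valid pixels, or with no
    variance in either field, are dropped.  Partial edge tiles are dropped
    by default (unequal support would bias their correlations).
    """
    if min_pixels < 3:
        raise ValueError("min_pixels must be >= 3")
    grid = diversity.grid
    if sens.grid.shape != grid.shape:
        raise ValueError("diversity and sensitivity maps must share a grid")
    covariates = covariates or {}
    for name, cov in covariates.items():
        if cov.grid.shape != grid.shape:
            raise ValueError(f"covariate {name!r} grid mismatch")
    d = diversity.cv.values
    g = sens.gamma.values
    joint = diversity.cv.valid & sens.gamma.valid
    results: list[BlockResult] = []
    for tile in tile_blocks(grid, block_size):
        if tile.partial and not include_partial:
            continue
        rs, cs = tile.slices()
        sel = joint[rs, cs]
        n = int(sel.sum())
        if n < min_pixels:
            continue
        dv = np.asarray(d[rs, cs][sel], float)
        gv = np.asarray(g[rs, cs][sel], float)
        if dv.std() == 0 or gv.std() == 0:
            continue
        r, p = stats.pearsonr(dv, gv)
        means = {}
        for name, cov in covariates.items():
            csel = sel & cov.valid[rs, cs]
            means[name] = float(np.mean(cov.values[rs, cs][csel])) if csel.any() else float("nan")
        results.append(BlockResult((tile.block_row, tile.block_col), n, float(r), float(p),
                                   means, tile.partial))
    return results


def negative_proportion(results: list[BlockResult]) -> float:
    """Fraction of retained blocks with strictly negative correlation."""
    if not results:
        raise ValueError("no retained blocks")
    return float(sum(b.r_div_sens < 0 for b in results) / len(results))


def trend_vs_dryness(results: list[BlockResult], covariate: str = "ai") -> TrendSummary:
    """How the block diversity-sensitivity correlation varies with dryness.

    OLS of r on the block-mean covariate plus Spearman rank correlation.
    A positive slope on the aridity index means the benefit (negative r)
    weakens as the climate gets wetter.
    """
    rows = [(b.covariate_means.get(covariate, float("nan")), b.r_div_sens) for b in results]
    rows = [(x, y) for x, y in rows if np.isfinite(x) and np.isfinite(y)]
    if len(rows) < 3:
        raise ValueError("need at least 3 blocks with a finite covariate")
    x = np.array([r[0] for r in rows])
    y = np.array([r[1] for r in rows])
    if np.ptp(x) == 0:
        raise ValueError(f"covariate {covariate!r} is constant over blocks")
    ols = stats.linregress(x, y)
    rho, rho_p = stats.spearmanr(x, y)
    return TrendSummary(
        covariate=covariate,
        slope=float(ols.slope),
        intercept=float(ols.intercept),
        slope_se=float(ols.stderr),
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        n_blocks=len(rows),
        proportion_negative=float(np.mean(y < 0)),
    )


def block_results_frame(results: list[BlockResult]) -> pd.DataFrame:
    """Tabulate block results (the CSV contract of the windows stage)."""
    rows = []
    for b in results:
        row = {
            "block_row": b.block_id[0],
            "block_col": b.block_id[1],
            "n_pixels": b.n_pixels,
            "r": b.r_div_sens,
            "p": b.p_value,
        }
        for name, v in b.covariate_means.items():
            row[f"mean_{name}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
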