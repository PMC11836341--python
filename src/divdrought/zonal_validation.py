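"""Zonal validation of the diversity map against surveyed richness.

The CV diversity map is summarized per administrative zone (county-style
polygon): mu_CV, the mean of valid CV cells whose centers fall inside the
polygon, and tau_CV, their sum.  The zonal statistics are then correlated
against an external table of surveyed plant-species richness — the
ground-truth check that a spectral-variation index tracks real floristic
diversity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely import wkt as shapely_wkt
from shapely.geometry.base import BaseGeometry
from shapely.prepared import prep
from shapely.geometry import Point

from .spectral_diversity import DiversityMap

logger = logging.getLogger(__name__)

__all__ = ["ZoneSet", "zonal_stats", "richness_correlation", "read_zones_csv", "write_zones_csv"]


@dataclass
class ZoneSet:
    """Named polygons; zone ids unique, geometries valid."""

    zones: list[tuple[str, BaseGeometry]]

    def __post_init__(self) -> None:
        ids = [z for z, _ in self.zones]
        if len(set(ids)) != len(ids):
            raise ValueError("zone ids must be unique")
        for zid, geom in self.zones:
            if not geom.is_valid:
                raise ValueError(f"zone {zid!r} has an invalid geometry")


def read_zones_csv(path) -> ZoneSet:
    """Zones from a CSV with columns (zone_id, wkt)."""
    df = pd.read_csv(path)
    return ZoneSet([(str(r.zone_id), shapely_wkt.loads(r.wkt)) for r in df.itertuples()])


def write_zones_csv(zones: ZoneSet, path) -> None:
    pd.DataFrame(
        {"zone_id": [z for z, _ in zones.zones], "wkt": [g.wkt for _, g in zones.zones]}
    ).to_csv(path, index=False)


def zonal_stats(diversity: DiversityMap, zones: ZoneSet) -> pd.DataFrame:
    """Per-zone mean and sum of valid CV cells by cell-center containment.

    Returns a DataFrame with columns (zone_id, mu_cv, tau_cv, n_pixels);
    zones containing no valid cell get n_pixels 0 and NaN statistics.
    """
    grid = diversity.grid
    valid = diversity.cv.valid
    rows, cols = np.nonzero(valid)
    xs, _ = grid.cell_center(0, cols)
    _, ys = grid.cell_center(rows, 0)
    vals = diversity.cv.values[rows, cols]
    out = []
    for zid, geom in zones.zones:
        xmin, ymin, xmax, ymax = geom.bounds
        cand = (xs >= xmin) & (xs <= xmax) & (ys >= ymin) & (ys <= ymax)
        if cand.any():
            pg = prep(geom)
            idx = np.nonzero(cand)[0]
            inside = np.fromiter(
                (pg.contains(Point(xs[i], ys[i])) for i in idx), bool, count=len(idx)
            )
            sel = vals[idx[inside]]
        else:
            sel = np.empty(0)
        n = len(sel)
        out.append({
            "zone_id": zid,
            "mu_cv": float(sel.mean()) if n else np.nan,
            "tau_cv": float(sel.sum()) if n else np.nan,
            "n_pixels": n,
        })
    return pd.DataFrame(out)


def richness_correlation(table: pd.DataFrame, richness: pd.DataFrame):
    """Pearson correlation of zonal CV statistics with surveyed richness.

    ``richness`` has columns (zone_id, richness).  Zones present in only
    one table are excluded (with a logged count).  Returns a dict with
    r_mu, r_tau and their two-sided p-values.
    """
    merged = table.merge(richness, on="zone_id", how="inner")
    merged = merged[(merged["n_pixels"] > 0) & np.isfinite(merged["richness"])]
    dropped = len(table) + len(richness) - 2 * len(merged)
    if dropped > 0:
        logger.info("excluded %d unmatched or empty zone rows", dropped)
    if len(merged) < 3:
        raise ValueError("need at least 3 matched zones for a correlation")
    r_mu, p_mu = stats.pearsonr(merged["richness"], merged["mu_cv"])
    r_tau, p_tau = stats.pearsonr(merged["richness"], merged["tau_cv"])
    return {
        "r_mu": float(r_mu), "p_mu": float(p_mu),
        "r_tau": float(r_tau), "p_tau": float(p_tau),
        "n_zones": int(len(merged)),
    }
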