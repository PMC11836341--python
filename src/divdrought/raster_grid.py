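"""Grid bookkeeping, masked rasters, resampling and block tiling.

All rasters in the pipeline are axis-aligned regular grids with row 0 at the
north edge, 0-based pixel indexing and half-open extents.  A value array is
always paired with a boolean validity mask; invalid cells carry no
information and every statistic downstream ignores them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "MaskedRaster",
    "ForestMask",
    "BlockIndex",
    "resample_nearest",
    "block_aggregate",
    "forest_mask_from_landcover",
    "tile_blocks",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid.

    ``origin`` is the (x, y) coordinate of the outer corner of pixel (0, 0),
    i.e. the north-west corner of the extent; y decreases with increasing
    row index.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_label: str = "local"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center(self, row, col):
        """(x, y) coordinates of cell centers for index arrays."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = y0 - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the half-open grid extent."""
        x0, y0 = self.origin
        return (
            x0,
            y0 - self.n_rows * self.cell_size,
            x0 + self.n_cols * self.cell_size,
            y0,
        )

    def scaled(self, factor: int) -> "GridSpec":
        """A coarser grid covering the same origin with ``factor``-times
        larger cells; row/col counts are ceil-divided."""
        return GridSpec(
            n_rows=-(-self.n_rows // factor),
            n_cols=-(-self.n_cols // factor),
            cell_size=self.cell_size * factor,
            origin=self.origin,
            crs_label=self.crs_label,
        )


@dataclass
class MaskedRaster:
    """A 2-D value array with a same-shape boolean validity mask."""

    grid: GridSpec
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.valid.shape != self.values.shape:
            raise ValueError("valid mask shape must match values shape")

    @classmethod
    def full(cls, grid: GridSpec, values: np.ndarray) -> "MaskedRaster":
        """Raster with every cell valid."""
        values = np.asarray(values)
        return cls(grid, values, np.ones(values.shape, dtype=bool))

    @classmethod
    def from_nodata(cls, grid: GridSpec, values: np.ndarray, nodata) -> "MaskedRaster":
        values = np.asarray(values)
        if nodata is None:
            valid = ~np.isnan(values) if np.issubdtype(values.dtype, np.floating) else np.ones(values.shape, bool)
        elif isinstance(nodata, float) and np.isnan(nodata):
            valid = ~np.isnan(values)
        else:
            valid = values != nodata
            if np.issubdtype(values.dtype, np.floating):
                valid &= ~np.isnan(values)
        return cls(grid, values, valid)

    def masked_values(self) -> np.ndarray:
        """Float copy with NaN in invalid cells."""
        out = np.asarray(self.values, dtype=float).copy()
        out[~self.valid] = np.nan
        return out

    def copy(self) -> "MaskedRaster":
        return MaskedRaster(self.grid, self.values.copy(), self.valid.copy())


@dataclass
class ForestMask:
    """Boolean forest/non-forest raster derived from a land-cover map."""

    grid: GridSpec
    is_forest: np.ndarray

    def __post_init__(self) -> None:
        self.is_forest = np.asarray(self.is_forest, dtype=bool)
        if self.is_forest.shape != self.grid.shape:
            raise ValueError("is_forest shape must match grid shape")


@dataclass(frozen=True)
class BlockIndex:
    """Index ranges of one non-overlapping tile, half-open in rows/cols."""

    block_row: int
    block_col: int
    row_start: int
    row_stop: int
    col_start: int
    col_stop: int
    partial: bool = False

    @property
    def n_cells(self) -> int:
        return (self.row_stop - self.row_start) * (self.col_stop - self.col_start)

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_start, self.row_stop), slice(self.col_start, self.col_stop)


def forest_mask_from_landcover(lc: MaskedRaster, forest_code: int) -> ForestMask:
    """Mark cells whose land-cover class equals ``forest_code``.

    Invalid land-cover cells are never forest.  An absent class yields an
    all-false mask with a logged warning (a common sign of a wrong code).
    """
    is_forest = (lc.values == forest_code) & lc.valid
    if not is_forest.any():
        logger.warning("forest code %s not present in land-cover raster", forest_code)
    return ForestMask(lc.grid, is_forest)


def _source_indices(src: GridSpec, target: GridSpec):
    """Row/col indices in ``src`` of each target cell center; -1 when the
    center falls outside the source extent."""
    rows = np.arange(target.n_rows)
    cols = np.arange(target.n_cols)
    xs, _ = target.cell_center(0, cols)
    _, ys = target.cell_center(rows, 0)
    sx0, sy1 = src.origin
    src_col = np.floor((xs - sx0) / src.cell_size).astype(int)
    src_row = np.floor((sy1 - ys) / src.cell_size).astype(int)
    src_col[(src_col < 0) | (src_col >= src.n_cols)] = -1
    src_row[(src_row < 0) | (src_row >= src.n_rows)] = -1
    return src_row, src_col


def resample_nearest(src: MaskedRaster, target: GridSpec) -> MaskedRaster:
    """Nearest-neighbor resampling: each target cell takes the value of the
    source cell containing its center.  Validity propagates; target cells
    whose centers fall outside the source extent become invalid.
    """
    tx0, ty0, tx1, ty1 = target.extent()
    sx0, sy0, sx1, sy1 = src.grid.extent()
    if tx1 <= sx0 or tx0 >= sx1 or ty1 <= sy0 or ty0 >= sy1:
        raise ValueError("source and target grids do not overlap")
    src_row, src_col = _source_indices(src.grid, target)
    inside = (src_row[:, None] >= 0) & (src_col[None, :] >= 0)
    rr = np.clip(src_row, 0, None)[:, None]
    cc = np.clip(src_col, 0, None)[None, :]
    values = src.values[rr, cc]
    valid = src.valid[rr, cc] & inside
    return MaskedRaster(target, values, valid)


def block_aggregate(src: MaskedRaster, factor: int, reducer: str = "mean") -> MaskedRaster:
    """Aggregate ``factor``x``factor`` blocks of fine cells into one coarse
    cell with a mask-aware reducer (``mean`` or ``sum``); a coarse cell with
    no valid fine cell is invalid.  Edge blocks may be partial.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    grid = src.grid
    coarse = grid.scaled(factor)
    vals = np.where(src.valid, np.asarray(src.values, float), 0.0)
    cnt = src.valid.astype(float)
    # pad to a multiple of factor so edge blocks reduce correctly
    pr = coarse.n_rows * factor - grid.n_rows
    pc = coarse.n_cols * factor - grid.n_cols
    vals = np.pad(vals, ((0, pr), (0, pc)))
    cnt = np.pad(cnt, ((0, pr), (0, pc)))
    vsum = vals.reshape(coarse.n_rows, factor, coarse.n_cols, factor).sum(axis=(1, 3))
    n = cnt.reshape(coarse.n_rows, factor, coarse.n_cols, factor).sum(axis=(1, 3))
    valid = n > 0
    if reducer == "mean":
        out = np.divide(vsum, n, out=np.zeros_like(vsum), where=valid)
    elif reducer == "sum":
        out = vsum
    else:
        raise ValueError(f"unknown reducer {reducer!r}")
    out[~valid] = np.nan
    return MaskedRaster(coarse, out, valid)


def tile_blocks(grid: GridSpec, block_size: int) -> list[BlockIndex]:
    """Partition the grid into non-overlapping ``block_size`` x ``block_size``
    tiles, row-major from the origin corner.  Remainder tiles at the right
    and bottom edges are emitted flagged ``partial``.
    """
    if block_size < 2:
        raise ValueError("block_size must be >= 2")
    tiles = []
    n_br = -(-grid.n_rows // block_size)
    n_bc = -(-grid.n_cols // block_size)
    for br in range(n_br):
        r0 = br * block_size
        r1 = min(r0 + block_size, grid.n_rows)
        for bc in range(n_bc):
            c0 = bc * block_size
            c1 = min(c0 + block_size, grid.n_cols)
            partial = (r1 - r0 != block_size) or (c1 - c0 != block_size)
            tiles.append(BlockIndex(br, bc, r0, r1, c0, c1, partial))
    return tiles
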