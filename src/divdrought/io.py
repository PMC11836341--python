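"""Raster and stack I/O.

Rasters travel as TIFF files (single- or multi-band) with the grid geometry
and nodata convention stored as JSON in the ImageDescription tag, so a file
round-trips to the same grid, values and mask.  Monthly stacks travel as
NetCDF with dimensions (year, month, y, x) and explicit fill values.
"""

from __future__ import annotations

import json
import os

import numpy as np
import tifffile
import xarray as xr

from .raster_grid import GridSpec, MaskedRaster

__all__ = ["read_raster", "write_raster", "read_year_month_stack", "write_year_month_stack",
           "read_annual_stack", "write_annual_stack"]

_FLOAT_FILL = float(np.float32(-9.999e36))


def _grid_meta(grid: GridSpec) -> dict:
    return {
        "n_rows": grid.n_rows,
        "n_cols": grid.n_cols,
        "cell_size": grid.cell_size,
        "origin": list(grid.origin),
        "crs_label": grid.crs_label,
    }


def _grid_from_meta(meta: dict, shape: tuple[int, int]) -> GridSpec:
    if meta:
        return GridSpec(
            n_rows=int(meta["n_rows"]),
            n_cols=int(meta["n_cols"]),
            cell_size=float(meta["cell_size"]),
            origin=tuple(meta["origin"]),
            crs_label=meta.get("crs_label", "local"),
        )
    return GridSpec(n_rows=shape[0], n_cols=shape[1])


def write_raster(path, bands, nodata=None, tags: dict | None = None) -> None:
    """Write one or more :class:`MaskedRaster` bands to a TIFF file.

    Integer rasters require an explicit ``nodata`` code; float rasters
    default to NaN-as-nodata.  Extra ``tags`` are stored alongside the grid
    metadata and returned by :func:`read_raster`.
    """
    if isinstance(bands, MaskedRaster):
        bands = [bands]
    if not bands:
        raise ValueError("no bands to write")
    grid = bands[0].grid
    for b in bands:
        if b.grid.shape != grid.shape:
            raise ValueError("all bands must share one grid")
    dtype = np.result_type(*(b.values.dtype for b in bands))
    if np.issubdtype(dtype, np.integer):
        if nodata is None:
            raise ValueError("integer rasters need an explicit nodata code")
        fill = nodata
    else:
        fill = np.nan if nodata is None else nodata
    data = np.stack(
        [np.where(b.valid, b.values, np.array(fill, dtype=dtype)) for b in bands]
    ).astype(dtype)
    meta = {
        "grid": _grid_meta(grid),
        "nodata": None if (isinstance(fill, float) and np.isnan(fill)) else fill,
        "nodata_is_nan": bool(isinstance(fill, float) and np.isnan(fill)),
        "tags": tags or {},
    }
    tifffile.imwrite(path, data, description=json.dumps(meta), photometric="minisblack")


def read_raster(path, band_selection: list[int] | None = None):
    """Read a TIFF raster into per-band :class:`MaskedRaster` objects.

    Returns ``(bands, grid, tags)``.  ``band_selection`` is a list of
    0-based band indices; out-of-range indices raise.
    """
    if band_selection is not None and len(band_selection) == 0:
        raise ValueError("band_selection must not be empty")
    if not os.path.exists(path):
        raise IOError(f"raster file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description
    except Exception as exc:  # pragma: no cover - corrupt-file path
        raise IOError(f"could not read raster {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (ValueError, TypeError):
            meta = {}
    grid = _grid_from_meta(meta.get("grid", {}), data.shape[-2:])
    nodata = meta.get("nodata")
    if meta.get("nodata_is_nan"):
        nodata = float("nan")
    n_bands = data.shape[0]
    idx = band_selection if band_selection is not None else list(range(n_bands))
    for i in idx:
        if i < 0 or i >= n_bands:
            raise ValueError(f"band {i} out of range for a {n_bands}-band file")
    bands = [MaskedRaster.from_nodata(grid, data[i], nodata) for i in idx]
    return bands, grid, meta.get("tags", {})


def write_year_month_stack(path, grid: GridSpec, years, values, name: str = "value",
                           attrs: dict | None = None) -> None:
    """Write a (year, month, y, x) float array with NaN-as-missing to NetCDF."""
    values = np.asarray(values, dtype=np.float32)
    ds = xr.Dataset(
        {name: (("year", "month", "y", "x"), values)},
        coords={"year": np.asarray(list(years), dtype=np.int32),
                "month": np.arange(1, 13, dtype=np.int32)},
        attrs={**_grid_meta(grid), **(attrs or {})},
    )
    enc = {name: {"_FillValue": np.float32(_FLOAT_FILL)}}
    ds.to_netcdf(path, engine="scipy", encoding=enc)


def write_annual_stack(path, grid: GridSpec, years, values, name: str = "value",
                       attrs: dict | None = None) -> None:
    """Write a (year, y, x) float array to NetCDF (annual P/PET stacks)."""
    values = np.asarray(values, dtype=np.float32)
    ds = xr.Dataset(
        {name: (("year", "y", "x"), values)},
        coords={"year": np.asarray(list(years), dtype=np.int32)},
        attrs={**_grid_meta(grid), **(attrs or {})},
    )
    ds.to_netcdf(path, engine="scipy",
                 encoding={name: {"_FillValue": np.float32(_FLOAT_FILL)}})


def read_annual_stack(path, name: str = "value"):
    """Read a (year, y, x) NetCDF stack. Returns (grid, years, values, attrs)."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    attrs = dict(ds.attrs)
    grid = _grid_from_meta(
        {k: attrs.pop(k) for k in ("n_rows", "n_cols", "cell_size", "origin", "crs_label") if k in attrs},
        ds[name].shape[-2:],
    )
    years = [int(y) for y in ds["year"].values]
    return grid, years, np.asarray(ds[name].values, dtype=float), attrs


def read_year_month_stack(path, name: str = "value"):
    """Read a (year, month, y, x) NetCDF stack. Returns (grid, years, values, attrs)."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    attrs = dict(ds.attrs)
    grid = _grid_from_meta(
        {k: attrs.pop(k) for k in ("n_rows", "n_cols", "cell_size", "origin", "crs_label") if k in attrs},
        ds[name].shape[-2:],
    )
    years = [int(y) for y in ds["year"].values]
    return grid, years, np.asarray(ds[name].values, dtype=float), attrs
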