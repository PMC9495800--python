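"""Minimal georeferenced single-band raster container and TIFF I/O.

A ``Raster`` couples a 2-D numpy array with a north-up affine geotransform
(GDAL order: origin_x, pixel_width, 0, origin_y, 0, pixel_height with
pixel_height < 0), a CRS tag and a nodata marker. Files are written as
single-band TIFFs with the georeferencing serialized as JSON in the
ImageDescription tag, so rasters round-trip losslessly through tifffile.

Resampling supports nearest-neighbour (categorical grids are never
interpolated) and bilinear for continuous fields.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

__all__ = ["GridGeometry", "Raster", "read_raster", "write_raster", "resample_to"]


class GeometryError(ValueError):
    """Grid geometries do not match or do not overlap."""


@dataclass(frozen=True)
class GridGeometry:
    """Shape + affine transform + CRS of a north-up grid."""

    nrows: int
    ncols: int
    origin_x: float = 0.0
    origin_y: float = 0.0
    pixel_width: float = 1.0
    pixel_height: float = -1.0  # negative: rows run north -> south
    crs: str = "EPSG:3857"

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise GeometryError("grid must have at least one row and column")
        if self.pixel_width <= 0 or self.pixel_height >= 0:
            raise GeometryError("expect pixel_width > 0 and pixel_height < 0")

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x of each column center, y of each row center)."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.origin_x + (cols + 0.5) * self.pixel_width
        y = self.origin_y + (rows + 0.5) * self.pixel_height
        return x, y

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        xmax = self.origin_x + self.ncols * self.pixel_width
        ymin = self.origin_y + self.nrows * self.pixel_height
        return (self.origin_x, ymin, xmax, self.origin_y)

    def same_as(self, other: "GridGeometry", tol: float = 1e-9) -> bool:
        return (
            self.nrows == other.nrows
            and self.ncols == other.ncols
            and abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.pixel_width - other.pixel_width) <= tol
            and abs(self.pixel_height - other.pixel_height) <= tol
            and self.crs == other.crs
        )


@dataclass(frozen=True)
class Raster:
    """Single-band grid of values with geometry and a nodata marker."""

    data: np.ndarray
    geometry: GridGeometry
    nodata: float | int | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise GeometryError("raster data must be 2-D")
        if self.data.shape != (self.geometry.nrows, self.geometry.ncols):
            raise GeometryError(
                f"data shape {self.data.shape} does not match geometry "
                f"({self.geometry.nrows}, {self.geometry.ncols})"
            )

    def nodata_mask(self) -> np.ndarray:
        """Boolean grid, True where the pixel carries no value."""
        if self.nodata is None:
            return np.zeros(self.data.shape, dtype=bool)
        if np.issubdtype(self.data.dtype, np.floating) and np.isnan(self.nodata):
            return np.isnan(self.data)
        return self.data == self.nodata

    def valid_values(self) -> np.ndarray:
        return self.data[~self.nodata_mask()]

    def with_data(self, data: np.ndarray, nodata=None) -> "Raster":
        return Raster(data=data, geometry=self.geometry,
                      nodata=self.nodata if nodata is None else nodata)


def write_raster(r: Raster, path) -> None:
    """Write a single-band TIFF with georeferencing in the description tag."""
    meta = {
        "origin_x": r.geometry.origin_x,
        "origin_y": r.geometry.origin_y,
        "pixel_width": r.geometry.pixel_width,
        "pixel_height": r.geometry.pixel_height,
        "crs": r.geometry.crs,
        "nodata": None if r.nodata is None else float(r.nodata),
    }
    tifffile.imwrite(str(path), r.data, description=json.dumps(meta))


def read_raster(path) -> Raster:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        data = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    geom = GridGeometry(
        nrows=data.shape[0],
        ncols=data.shape[1],
        origin_x=float(meta.get("origin_x", 0.0)),
        origin_y=float(meta.get("origin_y", 0.0)),
        pixel_width=float(meta.get("pixel_width", 1.0)),
        pixel_height=float(meta.get("pixel_height", -1.0)),
        crs=str(meta.get("crs", "EPSG:3857")),
    )
    nodata = meta.get("nodata")
    if nodata is not None and np.issubdtype(data.dtype, np.integer):
        nodata = int(nodata)
    return Raster(data=data, geometry=geom, nodata=nodata)


def resample_to(reference: GridGeometry, grid: Raster, method: str) -> Raster:
    """Resample ``grid`` onto ``reference``.

    method: 'nearest' (categorical-safe) or 'bilinear' (continuous only).
    The two extents must overlap; an identity geometry returns the values
    bit-identically under either method.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling method {method!r}")
    src = grid.geometry
    if src.crs != reference.crs:
        raise GeometryError(f"CRS mismatch: {src.crs} vs {reference.crs}")
    rxmin, rymin, rxmax, rymax = reference.bounds()
    sxmin, symin, sxmax, symax = src.bounds()
    if rxmin >= sxmax or rxmax <= sxmin or rymin >= symax or rymax <= symin:
        raise GeometryError("reference and source extents do not overlap")

    x, y = reference.pixel_centers()
    # fractional source array indices of the reference pixel centers
    col_f = (x - src.origin_x) / src.pixel_width - 0.5
    row_f = (y - src.origin_y) / src.pixel_height - 0.5
    cols, rows = np.meshgrid(col_f, row_f)

    nod = grid.nodata
    if method == "nearest":
        ri = np.clip(np.round(rows).astype(int), 0, src.nrows - 1)
        ci = np.clip(np.round(cols).astype(int), 0, src.ncols - 1)
        out = grid.data[ri, ci]
    else:
        data = grid.data.astype(float)
        mask = grid.nodata_mask()
        if mask.any():
            # bilinear only between valid pixels; mark outputs touching nodata
            filled = np.where(mask, 0.0, data)
            out = ndimage.map_coordinates(
                filled, [rows, cols], order=1, mode="nearest")
            touch = ndimage.map_coordinates(
                mask.astype(float), [rows, cols], order=1, mode="nearest")
            if nod is None or (isinstance(nod, float) and not np.isnan(nod)):
                nod = np.nan
            out = np.where(touch > 0, nod, out)
        else:
            out = ndimage.map_coordinates(
                data, [rows, cols], order=1, mode="nearest")
    return Raster(data=out, geometry=reference, nodata=nod)
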