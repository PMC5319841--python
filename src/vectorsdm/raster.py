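"""Planar raster grids and TIFF + JSON-sidecar I/O.

Rasters live on a regular grid with the origin at the *upper-left* corner
(row 0 = northernmost row), matching the usual raster convention. Pixel
membership is half-open: a point on a shared pixel boundary belongs to the
pixel with the lower row/column index. Synthetic worlds use abstract planar
kilometre coordinates (one pixel = 5 km, mirroring a 5 x 5 km grid);
geographic grids carry decimal-degree coordinates and are tagged as such.

Arrays are written as plain (multi-band) TIFF with a ``.json`` sidecar that
stores the grid geometry, band names, nodata value and any provenance
metadata, so every raster on disk is self-describing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import box

__all__ = ["Grid", "write_raster", "read_raster"]


@dataclass(frozen=True)
class Grid:
    """Geometry of a regular raster grid (upper-left origin)."""

    width: int
    height: int
    pixel_size: float = 5.0
    x_min: float = 0.0
    y_max: float | None = None  # top edge; defaults to height * pixel_size
    crs_tag: str = "planar-km"

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.y_max is None:
            object.__setattr__(self, "y_max", self.height * self.pixel_size)

    # -- extent ---------------------------------------------------------
    @property
    def x_max(self) -> float:
        return self.x_min + self.width * self.pixel_size

    @property
    def y_min(self) -> float:
        return self.y_max - self.height * self.pixel_size

    @property
    def extent_polygon(self):
        return box(self.x_min, self.y_min, self.x_max, self.y_max)

    # -- point <-> pixel ------------------------------------------------
    def point_to_rowcol(self, x, y):
        """Containing pixel of (x, y); half-open, boundary -> lower index."""
        col = np.floor((np.asarray(x, float) - self.x_min) / self.pixel_size).astype(int)
        row = np.floor((self.y_max - np.asarray(y, float)) / self.pixel_size).astype(int)
        # points exactly on the bottom/right outer edge belong to the last pixel
        col = np.where(np.asarray(x, float) == self.x_max, self.width - 1, col)
        row = np.where(np.asarray(y, float) == self.y_min, self.height - 1, row)
        return row, col

    def contains(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (x >= self.x_min) & (x <= self.x_max) & (y >= self.y_min) & (y <= self.y_max)

    def pixel_centres(self):
        """(X, Y) coordinate arrays of shape (height, width)."""
        xs = self.x_min + (np.arange(self.width) + 0.5) * self.pixel_size
        ys = self.y_max - (np.arange(self.height) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def centre_of(self, row, col):
        x = self.x_min + (np.asarray(col) + 0.5) * self.pixel_size
        y = self.y_max - (np.asarray(row) + 0.5) * self.pixel_size
        return x, y

    # -- serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "pixel_size": self.pixel_size,
            "x_min": self.x_min,
            "y_max": self.y_max,
            "crs_tag": self.crs_tag,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Grid":
        return cls(**d)

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.width == other.width
            and self.height == other.height
            and math.isclose(self.pixel_size, other.pixel_size)
            and math.isclose(self.x_min, other.x_min)
            and math.isclose(self.y_max, other.y_max)
            and self.crs_tag == other.crs_tag
        )


def write_raster(
    path: str | Path,
    array: np.ndarray,
    grid: Grid,
    band_names: list[str] | None = None,
    nodata: float = float("nan"),
    metadata: dict | None = None,
) -> Path:
    """Write a (bands, H, W) or (H, W) array as TIFF + JSON sidecar."""
    path = Path(path)
    arr = np.asarray(array)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.shape[1:] != (grid.height, grid.width):
        raise ValueError(f"array shape {arr.shape} does not match grid {grid.height}x{grid.width}")
    if band_names is None:
        band_names = [f"band_{i}" for i in range(arr.shape[0])]
    if len(band_names) != arr.shape[0]:
        raise ValueError("band_names length must equal band count")
    kwargs = dict(photometric="minisblack")
    if arr.shape[0] > 1:
        kwargs["planarconfig"] = "separate"
    if arr.dtype == bool:
        tifffile.imwrite(path, arr.astype(np.uint8), **kwargs)
    else:
        tifffile.imwrite(path, arr.astype(np.float64), **kwargs)
    sidecar = {
        "grid": grid.to_dict(),
        "band_names": list(band_names),
        "nodata": None if (isinstance(nodata, float) and math.isnan(nodata)) else nodata,
        "dtype": "bool" if arr.dtype == bool else "float64",
        "metadata": metadata or {},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_raster(path: str | Path):
    """Read TIFF + sidecar; returns (array (bands,H,W), grid, band_names, metadata)."""
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    side = json.loads(path.with_suffix(".json").read_text())
    grid = Grid.from_dict(side["grid"])
    if side.get("dtype") == "bool":
        arr = arr.astype(bool)
    return arr, grid, side["band_names"], side.get("metadata", {})
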