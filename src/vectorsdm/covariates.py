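"""Annual environmental covariate stacks: temporal matching and extraction.

A :class:`CovariateStack` holds one multi-band raster per calendar year on a
shared grid (the study design uses annual 5 x 5 km layers for temperature,
temperature seasonality, wetness/greenness, elevation, land-class proportions
and population density). Occurrence records are matched to the covariate
layer of their collection year, clamped to the available year range: records
before the first year use the first year's layers, records after the last
year use the last year's layers. Extraction is containing-pixel lookup with
no interpolation, because the layers are already area summaries at the grid
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .raster import Grid, read_raster, write_raster

__all__ = ["CovariateStack", "clamp_year", "extract_at_points", "prediction_matrix", "reassemble"]


def clamp_year(year: int, years_available) -> int:
    """Clamp ``year`` into the inclusive available range.

    Idempotent and monotone non-decreasing in ``year``.
    """
    years = sorted(int(y) for y in years_available)
    if not years:
        raise ValueError("years_available is empty")
    return int(min(max(int(year), years[0]), years[-1]))


@dataclass
class CovariateStack:
    """Multi-band annual raster stack on a common grid."""

    grid: Grid
    band_names: list[str]
    arrays: dict[int, np.ndarray]  # year -> (n_bands, H, W)

    def __post_init__(self) -> None:
        if len(set(self.band_names)) != len(self.band_names):
            raise ValueError("band names must be unique")
        years = self.years_available
        if years and years != list(range(years[0], years[-1] + 1)):
            raise ValueError("years must form a contiguous range")
        nb = len(self.band_names)
        for y, a in self.arrays.items():
            if a.shape != (nb, self.grid.height, self.grid.width):
                raise ValueError(f"year {y}: array shape {a.shape} mismatches grid/bands")

    @property
    def years_available(self) -> list[int]:
        return sorted(self.arrays)

    @property
    def n_bands(self) -> int:
        return len(self.band_names)

    def year_array(self, year: int) -> np.ndarray:
        return self.arrays[clamp_year(year, self.years_available)]

    # -- I/O ------------------------------------------------------------
    def to_dir(self, out_dir: str | Path, metadata: dict | None = None) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for year in self.years_available:
            write_raster(
                out_dir / f"covariates_{year}.tif",
                self.arrays[year],
                self.grid,
                band_names=self.band_names,
                metadata=metadata,
            )

    @classmethod
    def from_dir(cls, in_dir: str | Path) -> "CovariateStack":
        in_dir = Path(in_dir)
        paths = sorted(in_dir.glob("covariates_*.tif"))
        if not paths:
            raise FileNotFoundError(f"no covariates_<year>.tif under {in_dir}")
        arrays: dict[int, np.ndarray] = {}
        grid = None
        band_names: list[str] | None = None
        for p in paths:
            year = int(p.stem.split("_")[-1])
            arr, g, names, _ = read_raster(p)
            if grid is None:
                grid, band_names = g, names
            elif not grid.same_geometry(g) or names != band_names:
                raise ValueError(f"{p}: grid/band mismatch across years")
            arrays[year] = arr
        return cls(grid=grid, band_names=band_names, arrays=arrays)


def extract_at_points(stack: CovariateStack, x, y, year_per_point):
    """Covariate matrix at points, matched to per-point (clamped) years.

    Returns ``(matrix, valid_mask)`` where ``matrix`` has one row per point
    and one column per band. Rows whose pixel holds nodata (NaN) in any band
    are flagged False in ``valid_mask`` (and should be excluded from model
    input); callers log the count.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    years = np.asarray(year_per_point, int)
    if not np.all(stack.grid.contains(x, y)):
        bad = np.flatnonzero(~stack.grid.contains(x, y))
        raise ValueError(f"{bad.size} point(s) outside grid extent, first index {bad[0]}")
    rows, cols = stack.grid.point_to_rowcol(x, y)
    out = np.empty((x.size, stack.n_bands), float)
    for year in np.unique(years):
        sel = years == year
        arr = stack.year_array(int(year))
        out[sel] = arr[:, rows[sel], cols[sel]].T
    valid = ~np.isnan(out).any(axis=1)
    return out, valid


def prediction_matrix(stack: CovariateStack, year: int | None = None):
    """All-pixel covariate matrix for one (clamped) year.

    Returns ``(matrix, valid_index)``: one row per non-nodata pixel and the
    flat pixel indices needed to reassemble rasters. Default year is the most
    contemporary layer available.
    """
    if year is None:
        year = stack.years_available[-1]
    arr = stack.year_array(int(year))
    flat = arr.reshape(stack.n_bands, -1).T  # (H*W, bands)
    valid_index = np.flatnonzero(~np.isnan(flat).any(axis=1))
    return flat[valid_index], valid_index


def reassemble(values, valid_index, grid: Grid) -> np.ndarray:
    """Scatter per-valid-pixel values back onto the grid (NaN elsewhere)."""
    out = np.full(grid.height * grid.width, np.nan)
    out[np.asarray(valid_index, int)] = np.asarray(values, float)
    return out.reshape(grid.height, grid.width)
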