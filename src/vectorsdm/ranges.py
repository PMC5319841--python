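"""Species range geometry: buffering, extension, composites, desert sampling.

Expert range polygons bound the extent of each species' predicted map. A
fixed-distance buffer (300 km by default) is added to each range to reflect
uncertainty in the exact range limits, and model outputs are masked to the
buffered range. Where molecularly confirmed records fall outside the prior
range, the range is extended to encompass them. Complex- and group-level
ranges are unions of their member species' ranges plus pooled presences.

Deserts host no anopheline surveys but the species are known absent there,
so pseudo-absence points (210 by default) are sampled uniformly from the
desert biome mask to anchor the models.

Planar ("planar-km") worlds buffer with Euclidean distance; geographic
ranges are buffered through a per-geometry azimuthal-equidistant projection
so the buffer distance is honest in kilometres at any latitude.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.ops import transform, unary_union

from .occurrence import LabelledPoint
from .raster import Grid

__all__ = [
    "SpeciesRange",
    "buffer_range",
    "extend_range",
    "composite_range",
    "sample_pseudo_absences",
    "mask_to_range",
    "read_range_geojson",
    "write_range_geojson",
]

_EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class SpeciesRange:
    species: str
    geometry: shapely.Geometry
    crs_tag: str = "planar-km"  # or "geographic"

    def __post_init__(self):
        geom = self.geometry
        if geom is None or geom.is_empty:
            raise ValueError("range geometry must be non-empty")
        if not geom.is_valid:
            geom = shapely.make_valid(geom)
            if not geom.is_valid or geom.is_empty:
                raise ValueError("range geometry invalid and unrepairable")
            object.__setattr__(self, "geometry", geom)


# ---------------------------------------------------------------------------
# azimuthal-equidistant projection (spherical) for geographic buffering
# ---------------------------------------------------------------------------

def _aeqd_forward(lon0: float, lat0: float):
    lon0r, lat0r = math.radians(lon0), math.radians(lat0)

    def fwd(lon, lat):
        lon = np.radians(np.asarray(lon, float))
        lat = np.radians(np.asarray(lat, float))
        c = np.arccos(
            np.clip(
                np.sin(lat0r) * np.sin(lat)
                + np.cos(lat0r) * np.cos(lat) * np.cos(lon - lon0r),
                -1.0, 1.0,
            )
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c == 0, 1.0, c / np.sin(c))
        x = _EARTH_RADIUS_KM * k * np.cos(lat) * np.sin(lon - lon0r)
        y = _EARTH_RADIUS_KM * k * (
            np.cos(lat0r) * np.sin(lat)
            - np.sin(lat0r) * np.cos(lat) * np.cos(lon - lon0r)
        )
        return x, y

    return fwd


def _aeqd_inverse(lon0: float, lat0: float):
    lon0r, lat0r = math.radians(lon0), math.radians(lat0)

    def inv(x, y):
        x = np.asarray(x, float) / _EARTH_RADIUS_KM
        y = np.asarray(y, float) / _EARTH_RADIUS_KM
        c = np.sqrt(x**2 + y**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            lat = np.where(
                c == 0,
                lat0r,
                np.arcsin(np.cos(c) * np.sin(lat0r) + y * np.sin(c) * np.cos(lat0r) / np.where(c == 0, 1, c)),
            )
            lon = lon0r + np.arctan2(
                x * np.sin(c),
                c * np.cos(lat0r) * np.cos(c) - y * np.sin(lat0r) * np.sin(c),
            )
        return np.degrees(lon), np.degrees(lat)

    return inv


def _buffer_geometry(geom, distance: float, crs_tag: str):
    if crs_tag == "planar-km":
        return geom.buffer(distance)
    # geographic: project each part around its own centroid, buffer, unproject
    parts = getattr(geom, "geoms", [geom])
    buffered = []
    for part in parts:
        lon0, lat0 = part.centroid.x, part.centroid.y
        proj = transform(_aeqd_forward(lon0, lat0), part)
        buf = proj.buffer(distance)
        buffered.append(transform(_aeqd_inverse(lon0, lat0), buf))
    return unary_union(buffered)


def buffer_range(rng: SpeciesRange, distance_km: float = 300.0) -> SpeciesRange:
    """Enlarge a range by a fixed distance (km); distance 0 is the identity."""
    if distance_km < 0:
        raise ValueError("buffer distance must be non-negative")
    if distance_km == 0:
        return rng
    geom = _buffer_geometry(rng.geometry, distance_km, rng.crs_tag)
    if not geom.is_valid:
        geom = shapely.make_valid(geom)
    return replace(rng, geometry=geom)


def extend_range(
    rng: SpeciesRange,
    presences: Sequence[LabelledPoint],
    disc_radius_km: float = 25.0,
) -> SpeciesRange:
    """Extend a range to encompass confirmed records found outside it.

    Each outside point is unioned in as a disc of ``disc_radius_km`` — enough
    to encompass the new location without inflating the range. Points
    already inside leave the range unchanged; output always contains input.
    """
    geom = rng.geometry
    outside = [
        p for p in presences
        if not shapely.intersects(geom, shapely.points(p.x, p.y))
    ]
    if not outside:
        return rng
    if rng.crs_tag == "planar-km":
        discs = [shapely.points(p.x, p.y).buffer(disc_radius_km) for p in outside]
    else:
        discs = []
        for p in outside:
            proj_disc = shapely.points(0.0, 0.0).buffer(disc_radius_km)
            discs.append(transform(_aeqd_inverse(p.x, p.y), proj_disc))
    return replace(rng, geometry=unary_union([geom, *discs]))


def composite_range(
    ranges: Sequence[SpeciesRange],
    presences: Sequence[LabelledPoint] = (),
    species: str = "composite",
    disc_radius_km: float = 25.0,
) -> SpeciesRange:
    """Complex/group range: union of member ranges, extended by pooled points."""
    if not ranges:
        raise ValueError("composite_range requires at least one member range")
    tags = {r.crs_tag for r in ranges}
    if len(tags) > 1:
        raise ValueError("member ranges mix coordinate systems")
    merged = SpeciesRange(
        species=species,
        geometry=unary_union([r.geometry for r in ranges]),
        crs_tag=ranges[0].crs_tag,
    )
    return extend_range(merged, presences, disc_radius_km)


# ---------------------------------------------------------------------------
# desert pseudo-absences
# ---------------------------------------------------------------------------

def sample_pseudo_absences(
    desert_mask: np.ndarray,
    grid: Grid,
    n: int = 210,
    seed: int = 0,
    background_class: int = 2,
) -> list[LabelledPoint]:
    """Uniform pseudo-absence points from the desert biome mask.

    Samples ``n`` distinct desert pixels (without replacement) and places a
    point at each pixel centre, labelled 0. Pseudo-absences come from no
    survey, so the capable-method upweighting cannot apply: they are class-2
    background. Deterministic given ``seed``.
    """
    if n == 0:
        return []
    desert_idx = np.flatnonzero(np.asarray(desert_mask, bool).ravel())
    if desert_idx.size < n:
        raise ValueError(
            f"desert mask has {desert_idx.size} pixels but {n} pseudo-absences requested"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(desert_idx, size=n, replace=False)
    rows, cols = np.unravel_index(chosen, (grid.height, grid.width))
    xs, ys = grid.centre_of(rows, cols)
    return [
        LabelledPoint(
            x=float(x), y=float(y), label=0,
            background_class=background_class, weight=1.0,
            record_id=f"pseudo_absence_{i}",
        )
        for i, (x, y) in enumerate(zip(xs, ys))
    ]


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

def mask_to_range(prediction: np.ndarray, grid: Grid, buffered_range: SpeciesRange) -> np.ndarray:
    """Set pixels outside the buffered range to nodata (NaN).

    Pixel membership is pixel-centre-in-polygon. Inside pixels are carried
    over bit-exactly; the input array is not modified.
    """
    if buffered_range.crs_tag != grid.crs_tag:
        raise ValueError(
            f"CRS mismatch: range is {buffered_range.crs_tag!r}, grid is {grid.crs_tag!r}"
        )
    pred = np.asarray(prediction, float)
    if pred.shape != (grid.height, grid.width):
        raise ValueError("prediction shape does not match grid")
    X, Y = grid.pixel_centres()
    inside = shapely.intersects_xy(buffered_range.geometry, X.ravel(), Y.ravel()).reshape(pred.shape)
    out = pred.copy()
    out[~inside] = np.nan
    return out


# ---------------------------------------------------------------------------
# GeoJSON I/O
# ---------------------------------------------------------------------------

def write_range_geojson(rng: SpeciesRange, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "type": "Feature",
        "properties": {"species": rng.species, "crs_tag": rng.crs_tag},
        "geometry": mapping(rng.geometry),
    }
    path.write_text(json.dumps(doc))
    return path


def read_range_geojson(path: str | Path) -> SpeciesRange:
    doc = json.loads(Path(path).read_text())
    props = doc.get("properties", {})
    return SpeciesRange(
        species=props.get("species", Path(path).stem),
        geometry=shape(doc["geometry"]),
        crs_tag=props.get("crs_tag", "planar-km"),
    )
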