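"""Occurrence records: validation, year handling, and presence/background prep.

Species occurrence surveys of the Gambiae complex and Funestus subgroup carry
a species label, coordinates, collection dates and the identification methods
used. Sibling species are morphologically identical, so only records whose
methods include a molecular assay capable of detecting the focal species
count as confirmed presences. All surveys (of any anopheline) form the
background set, which carries the same spatial sampling bias as the
presences; background records are split into

* class 1 — surveys whose methods *would have* detected the focal species
  had it been present (these receive twice the weight of class 2), and
* class 2 — all other surveys.

Records labelled ``gambiae_old`` (molecularly confirmed An. gambiae sensu
lato before the An. coluzzii / An. gambiae split) are reassigned to
An. gambiae when they fall outside the buffered An. coluzzii range, and
discarded inside it, where the two current species cannot be told apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely

from .raster import Grid

__all__ = [
    "OccurrenceRecord",
    "DetectionCapability",
    "LabelledPoint",
    "validate_records",
    "impute_collection_year",
    "extract_presence",
    "classify_background",
    "assign_weights",
    "resolve_gambiae_old",
    "location_id",
    "records_from_dataframe",
    "records_to_dataframe",
    "read_occurrence_csv",
]

GAMBIAE_OLD = "gambiae_old"


def location_id(x: float, y: float) -> str:
    """Shared id for co-located records: coordinates rounded to 6 decimals.

    The validation split withholds whole *locations*, so every record at the
    same point must map to the same id.
    """
    return f"{round(float(x), 6):.6f}_{round(float(y), 6):.6f}"


@dataclass(frozen=True)
class OccurrenceRecord:
    """One survey result for one species at one place and time."""

    record_id: str
    species_label: str
    x: float  # longitude (geographic) or planar-km easting (synthetic)
    y: float
    year_start: int | None = None
    year_end: int | None = None
    publication_year: int | None = None
    id_methods: frozenset[str] = field(default_factory=frozenset)
    is_molecular: bool = False
    source_id: str = ""

    @property
    def loc_id(self) -> str:
        return location_id(self.x, self.y)


@dataclass(frozen=True)
class DetectionCapability:
    """Which species each identification-method code can detect.

    Method codes absent from the mapping are treated as non-molecular
    (conservative: an unverifiable identification never upgrades a record).
    """

    methods: dict[str, frozenset[str]]

    def detects(self, method: str, species: str) -> bool:
        return species in self.methods.get(method, frozenset())

    def any_detects(self, methods: Iterable[str], species: str) -> bool:
        return any(self.detects(m, species) for m in methods)


@dataclass(frozen=True)
class LabelledPoint:
    """Model-ready point: label, background class, weight, covariates."""

    x: float
    y: float
    label: int  # 1 presence, 0 background / pseudo-absence
    background_class: int | None = None  # 1 | 2 | None (presences)
    weight: float = 1.0
    year_used: int | None = None
    covariates: np.ndarray | None = None
    loc_id: str = ""
    record_id: str = ""

    def __post_init__(self):
        if self.label == 1 and self.background_class is not None:
            raise ValueError("presence points carry no background class")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if not self.loc_id:
            object.__setattr__(self, "loc_id", location_id(self.x, self.y))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _in_extent(rec: OccurrenceRecord, extent) -> bool:
    if isinstance(extent, Grid):
        return bool(extent.contains(rec.x, rec.y))
    return bool(shapely.intersects(extent, shapely.points(rec.x, rec.y)))


def validate_records(records: Sequence[OccurrenceRecord], extent):
    """Screen records against the study extent and field invariants.

    ``extent`` is a :class:`Grid` or a shapely polygon. Returns
    ``(valid_records, report)`` where ``report`` is a DataFrame of rejected
    record ids with reason codes; rejections are data, not exceptions. This
    is the automated surrogate for the manual checks that source coordinates
    matched the described sampling design and fell on land in the right
    country.
    """
    valid: list[OccurrenceRecord] = []
    rows: list[dict] = []
    geographic = not isinstance(extent, Grid)
    for rec in records:
        reasons: list[str] = []
        if geographic and not (-180 <= rec.x <= 180 and -90 <= rec.y <= 90):
            reasons.append("coordinate_out_of_range")
        elif not _in_extent(rec, extent):
            reasons.append("coordinate_out_of_range")
        if rec.year_start is not None and rec.year_end is not None and rec.year_start > rec.year_end:
            reasons.append("year_order_invalid")
        if rec.year_start is None and rec.publication_year is None:
            reasons.append("no_dating_information")
        if reasons:
            rows.append({"record_id": rec.record_id, "reasons": ";".join(reasons)})
        else:
            valid.append(rec)
    report = pd.DataFrame(rows, columns=["record_id", "reasons"])
    return valid, report


# ---------------------------------------------------------------------------
# collection year
# ---------------------------------------------------------------------------

def impute_collection_year(record: OccurrenceRecord) -> int:
    """Single representative collection year for covariate matching.

    Records with collection dates use them (floor of the midpoint for
    multi-year collections). Records lacking a collection date are assumed
    collected two years before the article publication year, following the
    trend seen in data with known collection dates.
    """
    if record.year_start is not None:
        end = record.year_end if record.year_end is not None else record.year_start
        return int((int(record.year_start) + int(end)) // 2)
    if record.publication_year is None:
        raise ValueError(f"record {record.record_id}: no collection or publication year")
    return int(record.publication_year) - 2


# ---------------------------------------------------------------------------
# presence / background
# ---------------------------------------------------------------------------

def extract_presence(
    records: Sequence[OccurrenceRecord],
    focal_species: str,
    capability: DetectionCapability,
) -> list[LabelledPoint]:
    """Molecularly confirmed presences of the focal species (label 1, weight 1).

    Morphology-only records are excluded: sibling species are morphologically
    identical, so such identifications are potentially wrong.
    """
    out = []
    for rec in records:
        if rec.species_label != focal_species:
            continue
        if not (rec.is_molecular and capability.any_detects(rec.id_methods, focal_species)):
            continue
        out.append(
            LabelledPoint(
                x=rec.x, y=rec.y, label=1, weight=1.0,
                year_used=impute_collection_year(rec), record_id=rec.record_id,
            )
        )
    return out


def classify_background(
    records: Sequence[OccurrenceRecord],
    focal_species: str,
    capability: DetectionCapability,
) -> list[LabelledPoint]:
    """Label background surveys class 1 or class 2 for the focal species.

    Class 1 (any identification method could have detected the focal
    species) gets weight 2, class 2 gets weight 1 — the exact 2:1 ratio the
    weighting scheme requires; :func:`assign_weights` rescales both while
    preserving the ratio. Callers must already have excluded survey records
    that appear in the presence dataset.
    """
    if not focal_species:
        raise ValueError("focal species label required")
    out = []
    for rec in records:
        capable = capability.any_detects(rec.id_methods, focal_species)
        cls = 1 if capable else 2
        out.append(
            LabelledPoint(
                x=rec.x, y=rec.y, label=0, background_class=cls,
                weight=2.0 if cls == 1 else 1.0,
                year_used=impute_collection_year(rec), record_id=rec.record_id,
            )
        )
    return out


def assign_weights(
    presences: Sequence[LabelledPoint],
    background: Sequence[LabelledPoint],
    mode: str = "balanced",
):
    """Final model weights for presence and background points.

    ``mode='balanced'`` (default): presences keep weight 1; class-2
    background gets weight w and class-1 gets 2w, with w chosen so the total
    background weight equals the total presence weight. ``mode='plain'``
    keeps the raw (1, 2, 1) weights. Either way the class-1 : class-2 ratio
    is exactly 2.
    """
    if mode not in ("balanced", "plain"):
        raise ValueError(f"unknown weight mode {mode!r}")
    pres = [replace(p, weight=1.0) for p in presences]
    n1 = sum(1 for b in background if b.background_class == 1)
    n2 = sum(1 for b in background if b.background_class == 2)
    if mode == "plain" or (2 * n1 + n2) == 0:
        w2 = 1.0
    else:
        w2 = len(pres) / (2 * n1 + n2)
    bg = [
        replace(b, weight=2.0 * w2 if b.background_class == 1 else w2)
        for b in background
    ]
    return pres, bg


# ---------------------------------------------------------------------------
# the "An. gambiae (old)" rule
# ---------------------------------------------------------------------------

def resolve_gambiae_old(
    records: Sequence[OccurrenceRecord],
    coluzzii_range_buffered,
    gambiae_range_buffered,
    assigned_label: str = "gambiae",
):
    """Resolve pre-split An. gambiae s.l. records against current ranges.

    Records outside the buffered An. coluzzii range are designated
    An. gambiae (only An. gambiae occurs there). Records inside the buffered
    coluzzii range are discarded: within the gambiae/coluzzii overlap the
    old label cannot distinguish the two species, and inside coluzzii-only
    territory the record is equally unresolvable (these are discarded too,
    and counted). Non-``gambiae_old`` records pass through unchanged.
    Returns ``(assigned_or_passthrough, discarded)``.
    """
    if coluzzii_range_buffered is None or gambiae_range_buffered is None:
        raise ValueError("both buffered ranges are required")
    col = getattr(coluzzii_range_buffered, "geometry", coluzzii_range_buffered)
    assigned: list[OccurrenceRecord] = []
    discarded: list[OccurrenceRecord] = []
    for rec in records:
        if rec.species_label != GAMBIAE_OLD:
            assigned.append(rec)
            continue
        pt = shapely.points(rec.x, rec.y)
        if shapely.intersects(col, pt):
            discarded.append(rec)
        else:
            assigned.append(replace(rec, species_label=assigned_label))
    return assigned, discarded


# ---------------------------------------------------------------------------
# CSV schema
# ---------------------------------------------------------------------------

_COLUMNS = [
    "record_id", "species", "x", "y", "year_start", "year_end",
    "publication_year", "id_methods", "is_molecular", "source_id",
]


def records_to_dataframe(records: Sequence[OccurrenceRecord]) -> pd.DataFrame:
    rows = [
        {
            "record_id": r.record_id,
            "species": r.species_label,
            "x": r.x,
            "y": r.y,
            "year_start": r.year_start,
            "year_end": r.year_end,
            "publication_year": r.publication_year,
            "id_methods": ";".join(sorted(r.id_methods)),
            "is_molecular": r.is_molecular,
            "source_id": r.source_id,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def _opt_int(v):
    return None if pd.isna(v) else int(v)


def records_from_dataframe(df: pd.DataFrame) -> list[OccurrenceRecord]:
    out = []
    for row in df.itertuples(index=False):
        methods = frozenset(m for m in str(row.id_methods).split(";") if m and m != "nan")
        out.append(
            OccurrenceRecord(
                record_id=str(row.record_id),
                species_label=str(row.species),
                x=float(row.x),
                y=float(row.y),
                year_start=_opt_int(row.year_start),
                year_end=_opt_int(row.year_end),
                publication_year=_opt_int(row.publication_year),
                id_methods=methods,
                is_molecular=bool(row.is_molecular),
                source_id=str(row.source_id),
            )
        )
    return out


def read_occurrence_csv(path: str | Path) -> list[OccurrenceRecord]:
    return records_from_dataframe(pd.read_csv(path))
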