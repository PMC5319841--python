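"""Insecticide-resistance bioassay curation and summary tables.

Susceptibility bioassays expose field-collected mosquitoes (up to the F1
generation) to one of the four major neurotoxic insecticide classes —
carbamates, organochlorines, organophosphates and pyrethroids — and report
percent mortality; low mortality indicates resistance. Because sibling
species can differ in resistance, only samples identified with molecular
methods in which more than 95% of mosquitoes belong to a single species are
attributed to that species. Mixed samples are kept as a separate "mixed"
stratum rather than deleted, since their tally is itself reported.

Summaries give, per species x insecticide class x period, the number of
records with the min, max and (unweighted) mean mortality and the sorted
list of countries sampled. Periods are five-year bins ("<=2000",
"2001-2005", "2006-2010", "2011-2015", ...); a species x class group with
fewer than 10 records is aggregated into a single all-years bin.

A record is one mortality value for a single mosquito population sampled at
a specified time and place by a unique study.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "INSECTICIDE_CLASSES",
    "BioassayRecord",
    "parse_composition",
    "format_composition",
    "filter_single_species",
    "bin_periods",
    "summarise_resistance",
    "read_bioassay_csv",
]

INSECTICIDE_CLASSES = ("carbamate", "organochlorine", "organophosphate", "pyrethroid")

PERIOD_AGGREGATED = "all years"


@dataclass(frozen=True)
class BioassayRecord:
    """One susceptibility-bioassay result."""

    record_id: str
    composition: dict[str, float]  # species -> proportion, sums to 1
    insecticide: str
    insecticide_class: str
    year: int
    country: str
    mortality_pct: float
    molecular_id: bool = True
    generation_ok: bool = True  # field-collected up to F1
    protocol: str = ""
    deviations: str = ""  # annotation only, never a filter

    def __post_init__(self):
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition sums to {total}, expected 1")
        if any(not (0 <= v <= 1) for v in self.composition.values()):
            raise ValueError("composition proportions must lie in [0, 1]")
        if not (0 <= self.mortality_pct <= 100):
            raise ValueError("mortality must lie in [0, 100]")
        if self.insecticide_class not in INSECTICIDE_CLASSES:
            raise ValueError(f"unknown insecticide class {self.insecticide_class!r}")


# ---------------------------------------------------------------------------
# composition string codec (CSV-friendly: "speciesA:0.96;speciesB:0.04")
# ---------------------------------------------------------------------------

def parse_composition(text: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for part in str(text).split(";"):
        if not part:
            continue
        name, _, frac = part.rpartition(":")
        out[name] = float(frac)
    return out


def format_composition(comp: dict[str, float]) -> str:
    return ";".join(f"{k}:{v!r}" for k, v in sorted(comp.items()))


def _as_dataframe(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "composition" in df.columns and df["composition"].map(lambda c: isinstance(c, str)).any():
            df["composition"] = df["composition"].map(
                lambda c: parse_composition(c) if isinstance(c, str) else c
            )
        return df
    rows = [
        {
            "record_id": r.record_id,
            "composition": dict(r.composition),
            "insecticide": r.insecticide,
            "insecticide_class": r.insecticide_class,
            "year": r.year,
            "country": r.country,
            "mortality_pct": r.mortality_pct,
            "molecular_id": r.molecular_id,
            "generation_ok": r.generation_ok,
            "protocol": r.protocol,
            "deviations": r.deviations,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def read_bioassay_csv(path: str | Path) -> pd.DataFrame:
    return _as_dataframe(pd.read_csv(path))


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_single_species(records, threshold: float = 0.95):
    """Purity filter: keep molecularly identified, near-pure samples.

    A record is kept iff its species were identified molecularly and the
    largest composition proportion strictly exceeds ``threshold`` (a sample
    at exactly 95% of one species is *not* attributed to it). Kept records
    gain a ``species`` column naming the majority species. Rejected records
    carry ``reject_reason``: ``"not_molecular"`` or ``"mixed_sample"`` (the
    mixed stratum is reported separately, not discarded).

    Returns ``(kept, rejected)`` DataFrames partitioning the input.
    """
    df = _as_dataframe(records)
    if df.empty:
        empty = df.assign(species=pd.Series(dtype=str))
        return empty, df.assign(reject_reason=pd.Series(dtype=str))
    majority = df["composition"].map(lambda c: max(c, key=c.get))
    max_prop = df["composition"].map(lambda c: max(c.values()))
    molecular = df["molecular_id"].astype(bool)
    keep = molecular & (max_prop > threshold)
    kept = df[keep].assign(species=majority[keep])
    reason = np.where(~molecular, "not_molecular", "mixed_sample")
    rejected = df[~keep].assign(reject_reason=reason[~keep.to_numpy()])
    return kept.reset_index(drop=True), rejected.reset_index(drop=True)


# ---------------------------------------------------------------------------
# period binning
# ---------------------------------------------------------------------------

def _period_of(year: int) -> str:
    year = int(year)
    if year <= 2000:
        return "≤2000"
    start = 2001 + 5 * ((year - 2001) // 5)
    return f"{start}–{start + 4}"


def bin_periods(records, min_records_for_binning: int = 10) -> pd.DataFrame:
    """Attach period labels, aggregating small species x class groups.

    Records are binned into "≤2000" and subsequent five-year ranges. When a
    species x insecticide-class group holds fewer than
    ``min_records_for_binning`` records, all its records collapse into a
    single all-years bin. Requires a ``species`` column (run
    :func:`filter_single_species` first) and a year on every record.
    """
    df = _as_dataframe(records)
    if df.empty:
        return df.assign(period=pd.Series(dtype=str))
    if df["year"].isna().any():
        raise ValueError("every record needs a year before period binning")
    if "species" not in df.columns:
        raise ValueError("records need a 'species' attribution before binning")
    df = df.copy()
    df["period"] = df["year"].map(_period_of)
    sizes = df.groupby(["species", "insecticide_class"])["record_id"].transform("size")
    df.loc[sizes < min_records_for_binning, "period"] = PERIOD_AGGREGATED
    return df


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

def summarise_resistance(records) -> pd.DataFrame:
    """Species x class x period summary of bioassay mortality.

    One row per group with ``n_records``, min/max/mean mortality (mean
    rounded to 1 d.p.) and the sorted unique country list. Empty input
    yields an empty table. Row order is deterministic (sorted keys), so the
    summary is invariant to input row order.
    """
    df = _as_dataframe(records)
    cols = ["species", "insecticide_class", "period", "n_records",
            "mortality_min", "mortality_max", "mortality_mean", "countries"]
    if df.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    for (species, iclass, period), grp in df.groupby(
        ["species", "insecticide_class", "period"], sort=True
    ):
        m = grp["mortality_pct"].astype(float)
        rows.append({
            "species": species,
            "insecticide_class": iclass,
            "period": period,
            "n_records": len(grp),
            "mortality_min": float(m.min()),
            "mortality_max": float(m.max()),
            "mortality_mean": round(float(m.mean()), 1),
            "countries": ", ".join(sorted(set(grp["country"]))),
        })
    return pd.DataFrame(rows, columns=cols)
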