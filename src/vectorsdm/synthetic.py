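"""Seeded synthetic worlds with known ground truth.

The real mapping exercise runs on a compiled continental occurrence
database and 5 x 5 km environmental raster layers that cannot be bundled
with a test suite. This module generates small worlds with the same
statistical structure so every pipeline stage is testable end to end:

* smooth multi-band covariate rasters (low-pass-filtered noise) that drift
  slowly across years — emulating annual layers for temperature,
  seasonality, wetness/greenness, elevation, land classes and population;
* a desert strip with no surveys, for pseudo-absence sampling;
* a known true suitability surface: the inverse logit of a linear
  predictor over a subset of "active" covariate bands;
* a spatially *biased* survey process (clustered survey locations), where
  each survey yields a presence record with probability equal to the true
  suitability at its pixel if its identification method can detect the
  focal species, and a background record otherwise;
* bioassay tables with species-composition proportions, insecticide class,
  year, country and percent mortality, including mixed-species and
  non-molecular records to exercise the purity filter.

Coordinates are abstract planar kilometres, one pixel = 5 km. Everything
is deterministic given the config seed: the same seed reproduces the same
world bit for bit, and each record stores the uniform draw and true
suitability that decided its label, so labels can be regenerated exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit
from shapely.geometry import box

from .covariates import CovariateStack, clamp_year
from .raster import Grid, write_raster
from .ranges import SpeciesRange, write_range_geojson
from .resistance import INSECTICIDE_CLASSES, format_composition

__all__ = ["SyntheticWorldConfig", "SyntheticWorld", "generate_world", "generate_bioassay_table"]

PIXEL_KM = 5.0

_BAND_NAMES_8 = [
    "temperature", "temperature_seasonality", "wetness_index", "greenness_index",
    "elevation", "land_class_cropland", "land_class_forest", "population_density",
]

_INSECTICIDES = {
    "carbamate": ["bendiocarb", "propoxur"],
    "organochlorine": ["DDT", "dieldrin"],
    "organophosphate": ["malathion", "fenitrothion"],
    "pyrethroid": ["deltamethrin", "permethrin", "lambda-cyhalothrin"],
}

_COUNTRIES = [
    "Country_A", "Country_B", "Country_C", "Country_D", "Country_E",
    "Country_F", "Country_G", "Country_H",
]


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Ground-truth parameters of a synthetic world.

    Defaults describe the standard test world: a 64 x 64 grid of 8 annual
    covariate bands (2001-2012), two active bands with strong opposite
    effects and a negative intercept (so surveyed habitat is mostly
    unsuitable and presences are the minority, ~350 of ~900 clustered
    survey locations), 85% of surveys using a molecular method capable of
    detecting the focal species, and a desert strip covering 15% of the
    grid.
    """

    grid_width: int = 64
    grid_height: int = 64
    n_bands: int = 8
    years: tuple[int, int] = (2001, 2012)
    n_survey_locations: int = 900
    cluster_count: int = 20
    cluster_spread: float = 45.0  # km
    true_coefficients: tuple[float, ...] | None = None  # per band; built from active_bands if None
    active_bands: tuple[int, ...] = (0, 2)
    effect_size: float = 5.0  # |coefficient| on active bands when building defaults
    suitability_intercept: float = -1.5  # keeps surveyed habitat mostly unsuitable
    desert_fraction: float = 0.15
    detection_capability_fraction: float = 0.85
    band_correlation: float = 0.0  # shared-field mixing; 0 = independent fields
    annual_drift_sd: float = 0.02  # small: drift perturbs year-matching, never dominates
    duplicate_visit_fraction: float = 0.10
    missing_year_fraction: float = 0.15
    survey_year_range: tuple[int, int] = (1995, 2015)
    focal_species: str = "species_a"
    background_species: tuple[str, ...] = ("species_b", "species_c", "species_d")
    seed: int = 0

    def __post_init__(self):
        if self.grid_width < 8 or self.grid_height < 8:
            raise ValueError("grid dimensions must be >= 8")
        if not (0 < self.desert_fraction < 0.5):
            raise ValueError("desert_fraction must be in (0, 0.5)")
        if any(b < 0 or b >= self.n_bands for b in self.active_bands):
            raise ValueError("active_bands must be a subset of the band indices")
        if not (0 <= self.band_correlation < 1):
            raise ValueError("band_correlation must be in [0, 1)")
        if self.years[0] > self.years[1]:
            raise ValueError("years range inverted")
        if self.true_coefficients is not None:
            coefs = np.asarray(self.true_coefficients, float)
            if coefs.size != self.n_bands:
                raise ValueError("true_coefficients must have one entry per band")
            nonzero = set(np.flatnonzero(coefs != 0).tolist())
            if not nonzero <= set(self.active_bands):
                raise ValueError("nonzero coefficients outside active_bands")

    def coefficients(self) -> np.ndarray:
        if self.true_coefficients is not None:
            return np.asarray(self.true_coefficients, float)
        coefs = np.zeros(self.n_bands)
        for i, b in enumerate(self.active_bands):
            coefs[b] = self.effect_size * (1 if i % 2 == 0 else -1)
        return coefs

    def band_names(self) -> list[str]:
        if self.n_bands == 8:
            return list(_BAND_NAMES_8)
        return [f"band_{i}" for i in range(self.n_bands)]


@dataclass
class SyntheticWorld:
    config: SyntheticWorldConfig
    stack: CovariateStack
    desert_mask: np.ndarray  # bool (H, W)
    suitability: dict[int, np.ndarray]  # year -> (H, W) in [0, 1]
    species_range: SpeciesRange
    occurrence: pd.DataFrame
    bioassay: pd.DataFrame
    ground_truth: dict

    @property
    def true_suitability(self) -> np.ndarray:
        """Suitability surface of the most contemporary year."""
        return self.suitability[max(self.suitability)]

    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta = {"seed": self.config.seed}
        self.stack.to_dir(out_dir, metadata=meta)
        write_raster(out_dir / "desert_mask.tif", self.desert_mask, self.stack.grid,
                     band_names=["desert"], metadata=meta)
        write_raster(out_dir / "true_suitability.tif", self.true_suitability,
                     self.stack.grid, band_names=["suitability"], metadata=meta)
        write_range_geojson(self.species_range, out_dir / f"range_{self.species_range.species}.geojson")
        self.occurrence.to_csv(out_dir / "occurrence.csv", index=False)
        self.bioassay.to_csv(out_dir / "bioassay.csv", index=False)
        (out_dir / "truth.json").write_text(json.dumps(self.ground_truth, indent=1, sort_keys=True))
        return out_dir


# ---------------------------------------------------------------------------
# covariate fields
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Standardised low-pass-filtered white noise (mean 0, sd 1)."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def _make_stack(config: SyntheticWorldConfig, rng: np.random.Generator, grid: Grid) -> CovariateStack:
    shape = (config.grid_height, config.grid_width)
    sigma = config.grid_width / 8.0
    shared = _smooth_field(rng, shape, sigma)
    rho = config.band_correlation
    base = np.empty((config.n_bands, *shape))
    for b in range(config.n_bands):
        own = _smooth_field(rng, shape, sigma)
        base[b] = np.sqrt(1 - rho**2) * own + rho * shared
    years = range(config.years[0], config.years[1] + 1)
    arrays: dict[int, np.ndarray] = {}
    current = base.copy()
    for year in years:
        if year != config.years[0]:
            # slow annual drift: cumulative small smooth perturbations
            for b in range(config.n_bands):
                current[b] = current[b] + config.annual_drift_sd * _smooth_field(rng, shape, sigma)
        arrays[year] = current.copy()
    return CovariateStack(grid=grid, band_names=config.band_names(), arrays=arrays)


# ---------------------------------------------------------------------------
# survey process
# ---------------------------------------------------------------------------

def _survey_locations(config: SyntheticWorldConfig, rng: np.random.Generator,
                      grid: Grid, desert_rows: int) -> np.ndarray:
    """Clustered survey coordinates, outside the desert strip: (n, 2)."""
    y_top = grid.y_max - desert_rows * grid.pixel_size  # below this lies habitable land
    centres = np.column_stack([
        rng.uniform(grid.x_min, grid.x_max, config.cluster_count),
        rng.uniform(grid.y_min, y_top, config.cluster_count),
    ])
    pts = np.empty((config.n_survey_locations, 2))
    filled = 0
    while filled < config.n_survey_locations:
        k = config.n_survey_locations - filled
        which = rng.integers(0, config.cluster_count, k)
        cand = centres[which] + rng.normal(0, config.cluster_spread, (k, 2))
        ok = (
            (cand[:, 0] > grid.x_min) & (cand[:, 0] < grid.x_max)
            & (cand[:, 1] > grid.y_min) & (cand[:, 1] < y_top)
        )
        take = cand[ok]
        pts[filled:filled + len(take)] = take
        filled += len(take)
    return np.round(pts, 6)


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Build a complete synthetic world from its config (seed-deterministic)."""
    rng = np.random.default_rng(config.seed)
    grid = Grid(width=config.grid_width, height=config.grid_height,
                pixel_size=PIXEL_KM, crs_tag="planar-km")
    stack = _make_stack(config, rng, grid)

    desert_rows = max(1, int(round(config.desert_fraction * config.grid_height)))
    desert_mask = np.zeros((config.grid_height, config.grid_width), bool)
    desert_mask[:desert_rows, :] = True

    coefs = config.coefficients()
    suitability = {
        year: expit(config.suitability_intercept + np.tensordot(coefs, arr, axes=(0, 0)))
        for year, arr in stack.arrays.items()
    }

    # species range: the non-desert block (deserts lie outside all ranges)
    y_top = grid.y_max - desert_rows * grid.pixel_size
    species_range = SpeciesRange(
        species=config.focal_species,
        geometry=box(grid.x_min, grid.y_min, grid.x_max, y_top),
        crs_tag="planar-km",
    )

    # surveys -> occurrence records
    locs = _survey_locations(config, rng, grid, desert_rows)
    n_dup = int(round(config.duplicate_visit_fraction * len(locs)))
    dup_of = rng.choice(len(locs), size=n_dup, replace=False) if n_dup else np.array([], int)
    xy = np.vstack([locs, locs[dup_of]])
    n_rec = len(xy)

    years_lo, years_hi = config.survey_year_range
    true_years = rng.integers(years_lo, years_hi + 1, n_rec)
    method_draw = rng.uniform(size=n_rec)
    label_draw = rng.uniform(size=n_rec)
    missing_year = rng.uniform(size=n_rec) < config.missing_year_fraction
    bg_species = rng.choice(config.background_species, size=n_rec)

    rows, cols = grid.point_to_rowcol(xy[:, 0], xy[:, 1])
    capable_frac = config.detection_capability_fraction
    records = []
    for i in range(n_rec):
        year = int(true_years[i])
        suit = float(suitability[clamp_year(year, stack.years_available)][rows[i], cols[i]])
        if method_draw[i] < capable_frac:
            methods, molecular = "PCR_ALL", True
        elif method_draw[i] < capable_frac + (1 - capable_frac) / 2:
            methods, molecular = "PCR_OTHER", True
        else:
            methods, molecular = "MORPH", False
        capable = methods == "PCR_ALL"
        is_presence = capable and (label_draw[i] < suit)
        records.append({
            "record_id": f"rec_{i:05d}",
            "species": config.focal_species if is_presence else bg_species[i],
            "x": xy[i, 0],
            "y": xy[i, 1],
            "year_start": pd.NA if missing_year[i] else year,
            "year_end": pd.NA if missing_year[i] else year,
            "publication_year": year + 2,
            "id_methods": methods,
            "is_molecular": molecular,
            "source_id": f"study_{i % 37:03d}",
            # ground-truth bookkeeping (not part of the real-data schema)
            "true_year": year,
            "true_suitability": suit,
            "label_draw": label_draw[i],
            "is_presence_truth": is_presence,
        })
    occurrence = pd.DataFrame(records)

    bioassay = generate_bioassay_table(
        n_records=400,
        species_pool=(config.focal_species, *config.background_species),
        seed=int(rng.integers(0, 2**31)),
    )

    ground_truth = {
        "coefficients": coefs.tolist(),
        "intercept": config.suitability_intercept,
        "active_bands": list(config.active_bands),
        "band_names": config.band_names(),
        "desert_rows": desert_rows,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
    }
    return SyntheticWorld(
        config=config,
        stack=stack,
        desert_mask=desert_mask,
        suitability=suitability,
        species_range=species_range,
        occurrence=occurrence,
        bioassay=bioassay,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# bioassay generator
# ---------------------------------------------------------------------------

def generate_bioassay_table(
    n_records: int,
    species_pool,
    seed: int = 0,
    mixed_fraction: float = 0.3,
    nonmolecular_fraction: float = 0.1,
    year_range: tuple[int, int] = (1995, 2015),
) -> pd.DataFrame:
    """Synthetic susceptibility-bioassay records.

    Compositions sum to 1; ``mixed_fraction`` of records are mixed-species
    samples (majority proportion <= 0.95) and ``nonmolecular_fraction``
    lack molecular identification, so both purity-filter paths are
    exercised. Pyrethroid mortality declines over calendar time (emulating
    spreading resistance); other classes stay near-susceptible.
    """
    species_pool = list(species_pool)
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    if not species_pool:
        raise ValueError("species pool must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_records):
        major = species_pool[rng.integers(0, len(species_pool))]
        mixed = len(species_pool) > 1 and rng.uniform() < mixed_fraction
        if mixed:
            others = [s for s in species_pool if s != major]
            minor = others[rng.integers(0, len(others))]
            p_major = rng.uniform(0.5, 0.95)
            comp = {major: p_major, minor: 1.0 - p_major}
        else:
            comp = {major: 1.0}
        iclass = INSECTICIDE_CLASSES[rng.integers(0, len(INSECTICIDE_CLASSES))]
        insecticide = _INSECTICIDES[iclass][rng.integers(0, len(_INSECTICIDES[iclass]))]
        year = int(rng.integers(year_range[0], year_range[1] + 1))
        if iclass == "pyrethroid":
            base = 98.0 - 2.2 * (year - year_range[0])
        else:
            base = 96.0
        mortality = float(np.clip(base + rng.normal(0, 8), 0, 100))
        rows.append({
            "record_id": f"bio_{i:05d}",
            "composition": format_composition(comp),
            "insecticide": insecticide,
            "insecticide_class": iclass,
            "year": year,
            "country": _COUNTRIES[rng.integers(0, len(_COUNTRIES))],
            "mortality_pct": round(mortality, 1),
            "molecular_id": bool(rng.uniform() >= nonmolecular_fraction),
            "generation_ok": True,
            "protocol": "WHO_tube",
            "deviations": "",
        })
    return pd.DataFrame(rows)
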