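"""End-to-end orchestration: occurrence table to validated prediction maps.

``run_species`` executes the full mapping procedure for one focal species:

1. validate occurrence records against the study extent,
2. impute collection years (publication year minus two where missing),
3. resolve pre-split "gambiae (old)" labels against buffered ranges
   (when the two ranges are supplied),
4. extract molecularly confirmed presences,
5. classify the remaining surveys into background classes 1 and 2
   (class 1 gets twice the class-2 weight) and rebalance weights,
6. extend the species range to cover outside presences, buffer it
   (300 km default),
7. sample desert pseudo-absences (210 default, class-2 weight),
8. attach covariate values for each record's collection year, clamped to
   the available span (2001-2012 in the synthetic default),
9. withhold a random 10% of locations for validation,
10. fit the bootstrap BRT ensemble (200 submodels at full scale) and
    summarise to mean/median/quantile rasters masked to the buffered
    range, and
11. score the mean map by AUC on the withheld points.

Every stage logs record counts in and out, outputs carry the config hash
and master seed, and the whole run is reproducible from config + seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

from . import occurrence as occ
from .covariates import CovariateStack, clamp_year, extract_at_points
from .ensemble import EnsembleConfig, EnsembleSummary, fit_ensemble, summarise_ensemble
from .occurrence import DetectionCapability, LabelledPoint
from .ranges import (
    buffer_range,
    extend_range,
    read_range_geojson,
    sample_pseudo_absences,
)
from .raster import read_raster, write_raster
from .resistance import bin_periods, filter_single_species, read_bioassay_csv, summarise_resistance
from .validation import split_by_location, validate_map

__all__ = ["RunConfig", "run_species", "default_capability", "resistance_summary_run",
           "build_labelled_points"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved inputs and constants for one species run.

    Defaults mirror the mapping procedure's constants: 300 km range
    buffer, 210 desert pseudo-absences, a 10% location-withheld test set,
    200 bootstrap submodels summarised at the 0.025/0.975 quantiles, and
    presence/background weighting with class-1 background at double
    weight.
    """

    occurrence_csv: str
    covariate_dir: str
    range_path: str
    out_dir: str
    focal_species: str
    desert_mask_path: str | None = None
    coluzzii_range_path: str | None = None
    gambiae_range_path: str | None = None
    buffer_km: float = 300.0
    extension_disc_km: float = 25.0
    n_pseudo_absences: int = 210
    split_fraction: float = 0.10
    weight_mode: str = "balanced"
    prediction_year: int | None = None
    capability: dict[str, list[str]] | None = None  # method -> detectable species
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    master_seed: int = 0

    def frozen_json(self) -> str:
        doc = asdict(self)
        return json.dumps(doc, indent=1, sort_keys=True, default=str)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (excludes the output path)."""
        doc = asdict(self)
        doc.pop("out_dir", None)
        payload = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_capability(records: Sequence[occ.OccurrenceRecord],
                       focal_species: str) -> DetectionCapability:
    """Synthetic-world method semantics, derived from the data.

    ``PCR_ALL`` detects every species seen in the table; ``PCR_OTHER`` is
    molecular but cannot detect the focal species; all other codes detect
    nothing (and hence class as non-molecular background).
    """
    species = frozenset(r.species_label for r in records) | {focal_species}
    return DetectionCapability(methods={
        "PCR_ALL": species,
        "PCR_OTHER": species - {focal_species},
    })


def build_labelled_points(
    records: Sequence[occ.OccurrenceRecord],
    stack: CovariateStack,
    focal_species: str,
    capability: DetectionCapability | None = None,
    pseudo_absences: Sequence[LabelledPoint] = (),
    weight_mode: str = "balanced",
) -> list[LabelledPoint]:
    """In-memory presence/background preparation for a validated record set.

    Extracts molecular presences, classes the remaining surveys as
    background (class 1 at double weight), folds in pseudo-absences as
    class-2 background, rebalances weights, and attaches clamped-year
    covariate vectors. The file-based pipeline in :func:`run_species` adds
    staging, logging and persistence around the same operations.
    """
    cap = capability or default_capability(records, focal_species)
    presences = occ.extract_presence(records, focal_species, cap)
    presence_ids = {p.record_id for p in presences}
    background = occ.classify_background(
        [r for r in records if r.record_id not in presence_ids], focal_species, cap
    )
    presences, background = occ.assign_weights(
        presences, background + list(pseudo_absences), mode=weight_mode
    )
    pts = presences + background
    last_year = stack.years_available[-1]
    years = [clamp_year(p.year_used if p.year_used is not None else last_year,
                        stack.years_available) for p in pts]
    mat, valid = extract_at_points(stack, [p.x for p in pts], [p.y for p in pts], years)
    return [replace(p, covariates=mat[i], year_used=years[i])
            for i, p in enumerate(pts) if valid[i]]


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_species(config: RunConfig) -> Path:
    """Run the full mapping procedure; returns the populated run directory."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    report: dict = {"focal_species": config.focal_species,
                    "config_hash": config.config_hash(),
                    "master_seed": config.master_seed,
                    "stages": {}}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except StageError:
                raise
            except Exception as exc:
                (out_dir / "FAILED_STAGE.txt").write_text(name)
                raise StageError(name, exc) from exc
        return deco

    # -- load inputs ----------------------------------------------------
    @stage("load_inputs")
    def loaded():
        records = occ.read_occurrence_csv(config.occurrence_csv)
        stack = CovariateStack.from_dir(config.covariate_dir)
        rng_range = read_range_geojson(config.range_path)
        return records, stack, rng_range

    records, stack, species_range = loaded

    cap = (
        DetectionCapability({k: frozenset(v) for k, v in config.capability.items()})
        if config.capability is not None
        else default_capability(records, config.focal_species)
    )

    # -- validate -------------------------------------------------------
    @stage("validate_records")
    def validated():
        valid, rejections = occ.validate_records(records, stack.grid)
        rejections.to_csv(out_dir / "rejected_records.csv", index=False)
        return valid, rejections

    valid_records, rejections = validated
    log.append(f"validate_records: {len(records)} in, {len(valid_records)} valid, "
               f"{len(rejections)} rejected")
    report["stages"]["validate_records"] = {"in": len(records), "valid": len(valid_records),
                                            "rejected": len(rejections)}

    # -- gambiae_old ----------------------------------------------------
    if config.coluzzii_range_path and config.gambiae_range_path:
        @stage("resolve_gambiae_old")
        def resolved():
            col = buffer_range(read_range_geojson(config.coluzzii_range_path), config.buffer_km)
            gam = buffer_range(read_range_geojson(config.gambiae_range_path), config.buffer_km)
            return occ.resolve_gambiae_old(valid_records, col, gam)

        valid_records, discarded_old = resolved
        log.append(f"resolve_gambiae_old: {len(discarded_old)} discarded")
        report["stages"]["resolve_gambiae_old"] = {"discarded": len(discarded_old)}

    # -- presence / background -----------------------------------------
    @stage("extract_presence")
    def presences_raw():
        return occ.extract_presence(valid_records, config.focal_species, cap)

    presence_ids = {p.record_id for p in presences_raw}

    @stage("classify_background")
    def background_raw():
        # the full survey set minus records already in the presence dataset
        bg_records = [r for r in valid_records if r.record_id not in presence_ids]
        return occ.classify_background(bg_records, config.focal_species, cap)

    n_c1 = sum(1 for b in background_raw if b.background_class == 1)
    log.append(f"extract_presence: {len(presences_raw)} presences; "
               f"classify_background: {len(background_raw)} background "
               f"({n_c1} class-1, {len(background_raw) - n_c1} class-2)")
    report["stages"]["presence_background"] = {
        "n_presence": len(presences_raw), "n_background": len(background_raw),
        "n_class1": n_c1, "n_class2": len(background_raw) - n_c1,
    }

    # -- ranges ---------------------------------------------------------
    @stage("extend_and_buffer_range")
    def buffered():
        extended = extend_range(species_range, presences_raw, config.extension_disc_km)
        return extended, buffer_range(extended, config.buffer_km)

    extended_range, buffered_rng = buffered

    # -- pseudo-absences ------------------------------------------------
    pseudo: list[LabelledPoint] = []
    if config.desert_mask_path and config.n_pseudo_absences > 0:
        @stage("sample_pseudo_absences")
        def sampled():
            mask, mgrid, _, _ = read_raster(config.desert_mask_path)
            if not mgrid.same_geometry(stack.grid):
                raise ValueError("desert mask grid differs from covariate grid")
            return sample_pseudo_absences(
                mask[0], mgrid, n=config.n_pseudo_absences,
                seed=_derive_seed(config.master_seed, "pseudo_absences"),
            )

        pseudo = sampled
        log.append(f"sample_pseudo_absences: {len(pseudo)} points")

    # -- weights --------------------------------------------------------
    presences, background = occ.assign_weights(
        presences_raw, background_raw + pseudo, mode=config.weight_mode
    )

    # -- covariates -----------------------------------------------------
    @stage("extract_covariates")
    def with_covariates():
        pts = presences + background
        last_year = stack.years_available[-1]
        years = [clamp_year(p.year_used if p.year_used is not None else last_year,
                            stack.years_available) for p in pts]
        xs = [p.x for p in pts]
        ys = [p.y for p in pts]
        mat, valid = extract_at_points(stack, xs, ys, years)
        kept = [replace(p, covariates=mat[i], year_used=years[i])
                for i, p in enumerate(pts) if valid[i]]
        return kept, int((~valid).sum())

    points, n_nodata = with_covariates
    log.append(f"extract_covariates: {len(points)} points with covariates, "
               f"{n_nodata} dropped on nodata")
    report["stages"]["extract_covariates"] = {"kept": len(points), "dropped_nodata": n_nodata}

    # -- split ----------------------------------------------------------
    @stage("split_by_location")
    def split():
        return split_by_location(points, fraction=config.split_fraction,
                                 seed=_derive_seed(config.master_seed, "split"))

    log.append(f"split_by_location: {len(split.train)} train / {len(split.test)} test records, "
               f"{len(split.withheld_locations)} locations withheld")
    report["stages"]["split_by_location"] = {
        "n_train": len(split.train), "n_test": len(split.test),
        "n_withheld_locations": len(split.withheld_locations),
    }

    # -- ensemble -------------------------------------------------------
    @stage("fit_ensemble")
    def models():
        econf = replace(config.ensemble,
                        master_seed=_derive_seed(config.master_seed, "ensemble"))
        return fit_ensemble(split.train, econf, band_names=stack.band_names)

    log.append(f"fit_ensemble: {len(models)} submodels")

    @stage("summarise_ensemble")
    def summary():
        return summarise_ensemble(
            models, stack, year=config.prediction_year, buffered_range=buffered_rng,
            quantiles=config.ensemble.quantiles,
            provenance={"config_hash": config.config_hash(),
                        "master_seed": config.master_seed,
                        "n_submodels": len(models)},
        )

    # -- validation -----------------------------------------------------
    @stage("validate_map")
    def auc_report():
        # score the *unmasked* mean map so test background outside the
        # buffered range still validates the ranking
        unmasked = summarise_ensemble(models, stack, year=config.prediction_year,
                                      quantiles=config.ensemble.quantiles)
        return validate_map(unmasked, split.test)

    log.append(f"validate_map: AUC {auc_report['auc']:.3f} on "
               f"{auc_report['n_test_presence']}+{auc_report['n_test_background']} test points")
    report["validation"] = auc_report

    # -- outputs --------------------------------------------------------
    @stage("write_outputs")
    def _written():
        meta = summary.provenance
        for name, arr in (("mean", summary.mean), ("median", summary.median),
                          ("q025", summary.q_low), ("q975", summary.q_high)):
            write_raster(out_dir / f"{config.focal_species}_{name}.tif",
                         arr, summary.grid, band_names=[name], metadata=meta)
        _quicklook(summary, out_dir / f"{config.focal_species}_mean.png")
        (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        (out_dir / "log.txt").write_text("\n".join(log) + "\n")
        (out_dir / "config_frozen.json").write_text(config.frozen_json())
        return True

    return out_dir


def _derive_seed(master_seed: int, tag: str) -> int:
    h = hashlib.sha256(f"{master_seed}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _quicklook(summary: EnsembleSummary, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(summary.mean, vmin=0, vmax=1, cmap="viridis")
    fig.colorbar(im, ax=ax, label="relative probability of occurrence")
    ax.set_title("ensemble mean")
    fig.savefig(path, dpi=100)
    plt.close(fig)


def resistance_summary_run(bioassay_csv: str | Path, out_csv: str | Path,
                           threshold: float = 0.95) -> dict:
    """Bioassay CSV in, curated summary CSV out; returns tallies."""
    df = read_bioassay_csv(bioassay_csv)
    kept, rejected = filter_single_species(df, threshold=threshold)
    binned = bin_periods(kept)
    table = summarise_resistance(binned)
    table.to_csv(out_csv, index=False)
    reasons = rejected["reject_reason"].value_counts().to_dict() if len(rejected) else {}
    return {
        "n_in": len(df),
        "n_single_species": len(kept),
        "n_mixed": int(reasons.get("mixed_sample", 0)),
        "n_not_molecular": int(reasons.get("not_molecular", 0)),
        "n_summary_rows": len(table),
    }
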