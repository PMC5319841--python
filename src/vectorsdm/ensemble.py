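"""Bootstrap BRT ensembles and per-pixel prediction summaries.

The mapping procedure fits 200 submodels, each to an independent bootstrap
of the presence/background dataset, predicts the relative probability of
occurrence at every pixel with each submodel, and summarises the resulting
per-pixel distribution by its mean, median and 0.025/0.975 quantiles. The
quantile maps express the Monte-Carlo + sampling uncertainty of the map.

Bootstraps are stratified by label (presences resampled among presences,
background among background, class sizes preserved) so every resample is
fittable. Submodel seeds are derived deterministically from the master
seed and the submodel index, so results do not depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .brt import BRTConfig, BRTModel, fit_brt, predict_brt
from .covariates import CovariateStack, prediction_matrix, reassemble
from .occurrence import LabelledPoint
from .ranges import SpeciesRange, mask_to_range
from .raster import Grid

__all__ = [
    "EnsembleConfig",
    "EnsembleSummary",
    "bootstrap_dataset",
    "fit_ensemble",
    "summarise_ensemble",
    "points_to_arrays",
]


@dataclass(frozen=True)
class EnsembleConfig:
    n_submodels: int = 200
    quantiles: tuple[float, float] = (0.025, 0.975)
    brt: BRTConfig = field(default_factory=BRTConfig)
    master_seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if self.n_submodels < 1:
            raise ValueError("n_submodels must be >= 1")
        lo, hi = self.quantiles
        if not (0 < lo < hi < 1):
            raise ValueError("quantiles must satisfy 0 < low < high < 1")


@dataclass
class EnsembleSummary:
    """Per-pixel summary rasters of the submodel prediction distribution."""

    grid: Grid
    mean: np.ndarray
    median: np.ndarray
    q_low: np.ndarray
    q_high: np.ndarray
    n_submodels: int
    quantiles: tuple[float, float]
    provenance: dict = field(default_factory=dict)


def submodel_seed(master_seed: int, index: int) -> int:
    """Deterministic per-submodel seed (independent of execution order)."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def bootstrap_dataset(
    points: Sequence[LabelledPoint],
    seed: int,
    stratified: bool = True,
) -> list[LabelledPoint]:
    """Resample points with replacement, carrying weights with records.

    Stratified (default): presences are resampled among presences and
    background among background with the original class sizes preserved.
    Pooled mode resamples the whole dataset at once.
    """
    labels = np.array([p.label for p in points])
    if len(np.unique(labels)) < 2:
        raise ValueError("bootstrap needs both presence and background points")
    rng = np.random.default_rng(seed)
    out: list[LabelledPoint] = []
    if stratified:
        for lab in (1, 0):
            idx = np.flatnonzero(labels == lab)
            take = rng.integers(0, len(idx), size=len(idx))
            out.extend(points[i] for i in idx[take])
    else:
        take = rng.integers(0, len(points), size=len(points))
        out.extend(points[i] for i in take)
    return out


def points_to_arrays(points: Sequence[LabelledPoint]):
    """(X, y, w) arrays from labelled points carrying covariate vectors."""
    missing = [p.record_id for p in points if p.covariates is None]
    if missing:
        raise ValueError(f"{len(missing)} point(s) lack covariates, e.g. {missing[0]!r}")
    X = np.vstack([np.asarray(p.covariates, float) for p in points])
    y = np.array([p.label for p in points], float)
    w = np.array([p.weight for p in points], float)
    return X, y, w


def fit_ensemble(
    points: Sequence[LabelledPoint],
    econfig: EnsembleConfig,
    band_names: list[str] | None = None,
) -> list[BRTModel]:
    """Fit ``n_submodels`` BRTs, each on its own seeded bootstrap."""
    points = list(points)
    models: list[BRTModel] = []
    for i in range(econfig.n_submodels):
        seed_i = submodel_seed(econfig.master_seed, i)
        boot = bootstrap_dataset(points, seed=seed_i, stratified=econfig.stratified)
        X, y, w = points_to_arrays(boot)
        cfg = replace(econfig.brt, seed=seed_i)
        try:
            models.append(fit_brt(X, y, w, cfg, band_names=band_names))
        except Exception as exc:  # annotate which submodel failed
            raise RuntimeError(f"submodel {i} (seed {seed_i}) failed: {exc}") from exc
    return models


def predict_ensemble_matrix(models: Sequence[BRTModel], X: np.ndarray) -> np.ndarray:
    """(n_models, n_rows) prediction matrix."""
    return np.vstack([predict_brt(m, X) for m in models])


def summarise_ensemble(
    models: Sequence[BRTModel],
    stack: CovariateStack,
    year: int | None = None,
    buffered_range: SpeciesRange | None = None,
    quantiles: tuple[float, float] = (0.025, 0.975),
    provenance: dict | None = None,
) -> EnsembleSummary:
    """Mean / median / quantile rasters of the per-pixel prediction spread.

    Quantiles use linear interpolation of order statistics (type 7, the
    numpy default). Predictions default to the most contemporary covariate
    year; the summaries are then masked to the buffered species range.
    """
    if len(models) < 2:
        raise ValueError("ensemble summaries need at least 2 submodels")
    X, valid_index = prediction_matrix(stack, year)
    preds = predict_ensemble_matrix(models, X)
    mean = preds.mean(axis=0)
    q_low, median, q_high = np.quantile(
        preds, [quantiles[0], 0.5, quantiles[1]], axis=0, method="linear"
    )
    grid = stack.grid
    rasters = [reassemble(v, valid_index, grid) for v in (mean, median, q_low, q_high)]
    if buffered_range is not None:
        rasters = [mask_to_range(r, grid, buffered_range) for r in rasters]
    return EnsembleSummary(
        grid=grid,
        mean=rasters[0],
        median=rasters[1],
        q_low=rasters[2],
        q_high=rasters[3],
        n_submodels=len(models),
        quantiles=quantiles,
        provenance=provenance or {},
    )
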