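"""Location-withheld validation split and AUC against background points.

A random 10% of *locations* from both the presence and the background
datasets are withheld before fitting; all records at a withheld location go
to the test set, so co-located records never straddle the split. The mean
prediction map is then scored by the area under the receiver operating
characteristic curve (AUC): the probability that a randomly chosen presence
point receives a higher map value than a randomly chosen background point,
ties counted half (the Mann-Whitney statistic). AUC 1 is a perfect
ranking, 0.5 is no better than random, 0 is a perfectly inverted ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .ensemble import EnsembleSummary
from .occurrence import LabelledPoint

__all__ = ["SplitResult", "split_by_location", "compute_auc", "validate_map"]


@dataclass
class SplitResult:
    train: list[LabelledPoint]
    test: list[LabelledPoint]
    withheld_locations: set[str]
    fraction: float
    seed: int


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_by_location(
    points: Sequence[LabelledPoint],
    fraction: float = 0.10,
    seed: int = 0,
    mode: str = "within-each",
) -> SplitResult:
    """Withhold a fraction of unique locations for testing.

    ``within-each`` (default) samples the fraction independently within the
    presence-location set and the background-location set; ``pooled``
    samples from all locations at once. The withheld count per set is
    ``fraction * n`` rounded half-up, with a minimum of 1 for non-empty
    sets. Every record at a withheld location lands in the test set.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    if mode not in ("within-each", "pooled"):
        raise ValueError(f"unknown split mode {mode!r}")
    points = list(points)
    pres_locs = sorted({p.loc_id for p in points if p.label == 1})
    bg_locs = sorted({p.loc_id for p in points if p.label == 0})
    for name, locs in (("presence", pres_locs), ("background", bg_locs)):
        if len(locs) < 2:
            raise ValueError(f"need at least 2 {name} locations to split")
    rng = np.random.default_rng(seed)
    withheld: set[str] = set()
    if mode == "within-each":
        for locs in (pres_locs, bg_locs):
            k = max(1, _round_half_up(fraction * len(locs)))
            withheld.update(rng.choice(locs, size=k, replace=False).tolist())
    else:
        locs = sorted(set(pres_locs) | set(bg_locs))
        k = max(1, _round_half_up(fraction * len(locs)))
        withheld.update(rng.choice(locs, size=k, replace=False).tolist())
    train = [p for p in points if p.loc_id not in withheld]
    test = [p for p in points if p.loc_id in withheld]
    return SplitResult(train=train, test=test, withheld_locations=withheld,
                       fraction=fraction, seed=seed)


def compute_auc(scores_presence, scores_background) -> float:
    """Rank-based (Mann-Whitney) AUC, ties counted half per pair.

    Equals the fraction of presence-background pairs in which the presence
    point scores higher, plus half the tied pairs. Invariant under any
    strictly monotone transform of the scores.
    """
    sp = np.asarray(scores_presence, float)
    sb = np.asarray(scores_background, float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([sp, sb]), method="average")
    rank_sum_presence = ranks[: sp.size].sum()
    u = rank_sum_presence - sp.size * (sp.size + 1) / 2.0
    return float(u / (sp.size * sb.size))


def validate_map(summary: EnsembleSummary, test_points: Sequence[LabelledPoint]) -> dict:
    """AUC of the mean map on withheld presence vs background points.

    Scores are read from the mean raster at each test point's containing
    pixel; points landing on nodata pixels are dropped (counted in the
    report).
    """
    test_points = list(test_points)
    xs = np.array([p.x for p in test_points])
    ys = np.array([p.y for p in test_points])
    labels = np.array([p.label for p in test_points])
    rows, cols = summary.grid.point_to_rowcol(xs, ys)
    inside = summary.grid.contains(xs, ys)
    if not inside.all():
        raise ValueError("test points outside the prediction grid")
    scores = summary.mean[rows, cols]
    ok = ~np.isnan(scores)
    if not ok.any() or len(np.unique(labels[ok])) < 2:
        raise ValueError("test points have no scored presence/background pair "
                         "(all on nodata pixels?)")
    auc = compute_auc(scores[ok & (labels == 1)], scores[ok & (labels == 0)])
    return {
        "auc": auc,
        "n_test_presence": int((ok & (labels == 1)).sum()),
        "n_test_background": int((ok & (labels == 0)).sum()),
        "n_dropped_nodata": int((~ok).sum()),
        "n_withheld_locations": len({p.loc_id for p in test_points}),
    }
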