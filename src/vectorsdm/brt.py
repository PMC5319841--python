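"""Weighted boosted regression trees for presence/background modelling.

Stagewise gradient boosting of small least-squares regression trees on the
Bernoulli deviance, the standard BRT formulation used in species
distribution modelling. The model is additive on the log-odds scale:

    F(x) = F0 + shrinkage * sum_m T_m(x),        p(x) = 1 / (1 + exp(-F(x)))

with F0 the log-odds of the weighted prevalence. At each stage the
pseudo-residuals r_i = y_i - p_i are computed, a bag of observations is
drawn (weight-proportional, without replacement), and a regression tree is
grown on (X, r, w) over the bag by greedy binary splits that maximise the
weighted sum-of-squares reduction, up to a maximum number of terminal
nodes. Each leaf then takes the Newton step for the Bernoulli loss,

    leaf value = sum_leaf w*r / sum_leaf w*p*(1-p),

and the additive score is updated with shrinkage. Observation weights enter
every ingredient (prevalence, split gains, leaf values, bagging and the
deviance trace), so class-1 background points at twice class-2 weight and
presence/background rebalancing are honoured exactly; rescaling all weights
by a constant leaves the fit unchanged.

Everything here is deterministic given the config seed, and models
round-trip through JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit, logit

__all__ = ["BRTConfig", "BRTModel", "fit_brt", "predict_brt", "variable_importance"]

_EPS_HESSIAN = 1e-12  # leaf-value denominator floor (pure leaves)
_EPS_PROB = 1e-15     # deviance log guard


@dataclass(frozen=True)
class BRTConfig:
    """Boosting hyperparameters.

    Defaults follow the conventions of BRT-based species distribution
    models: many small trees (up to 5 terminal nodes, i.e. at most 4
    splits), slow learning, and a 0.75 bag fraction.
    """

    n_trees: int = 1000
    shrinkage: float = 0.005
    tree_complexity: int = 5  # max terminal nodes per tree
    bag_fraction: float = 0.75
    min_obs_leaf: int = 5
    seed: int = 0
    early_stopping: bool = False
    holdout_fraction: float = 0.2
    patience: int = 50

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (0 < self.shrinkage <= 1):
            raise ValueError("shrinkage must be in (0, 1]")
        if self.tree_complexity < 2:
            raise ValueError("tree_complexity must allow at least one split")
        if not (0 < self.bag_fraction <= 1):
            raise ValueError("bag_fraction must be in (0, 1]")
        if self.min_obs_leaf < 1:
            raise ValueError("min_obs_leaf must be >= 1")


@dataclass
class BRTModel:
    """Fitted boosted-tree model: intercept, trees, and provenance."""

    intercept: float
    trees: list[dict]
    shrinkage: float
    band_names: list[str]
    config: BRTConfig
    train_deviance: list[float] = field(default_factory=list)
    holdout_deviance: list[float] | None = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    # -- JSON serialisation (bit-stable given a seed) -------------------
    def to_json(self) -> str:
        doc = {
            "intercept": self.intercept,
            "trees": self.trees,
            "shrinkage": self.shrinkage,
            "band_names": self.band_names,
            "config": asdict(self.config),
            "train_deviance": self.train_deviance,
            "holdout_deviance": self.holdout_deviance,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "BRTModel":
        doc = json.loads(text)
        return cls(
            intercept=doc["intercept"],
            trees=doc["trees"],
            shrinkage=doc["shrinkage"],
            band_names=doc["band_names"],
            config=BRTConfig(**doc["config"]),
            train_deviance=doc["train_deviance"],
            holdout_deviance=doc.get("holdout_deviance"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "BRTModel":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# regression tree on pseudo-residuals
# ---------------------------------------------------------------------------

def _best_split(x_node: np.ndarray, r: np.ndarray, w: np.ndarray, min_obs: int):
    """Best (gain, feature, threshold) for one node; None if unsplittable.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted values of each feature. Gain is the weighted SSE reduction
    (equivalently the increase in sum(w*r)^2/sum(w) over the children).
    Ties break to the lowest feature index, then the lowest threshold.
    """
    n, n_feat = x_node.shape
    if n < 2 * min_obs:
        return None
    best = None  # (-gain, feature, threshold) lexicographic minimum
    w_total = w.sum()
    wr_total = (w * r).sum()
    parent = wr_total**2 / max(w_total, _EPS_HESSIAN)
    for j in range(n_feat):
        order = np.argsort(x_node[:, j], kind="stable")
        xs = x_node[order, j]
        ws = w[order]
        wrs = (w * r)[order]
        cw = np.cumsum(ws)[:-1]
        cwr = np.cumsum(wrs)[:-1]
        pos = np.arange(1, n)  # left-child sizes
        ok = (xs[1:] > xs[:-1]) & (pos >= min_obs) & (n - pos >= min_obs)
        if not ok.any():
            continue
        gain = (
            cwr**2 / np.maximum(cw, _EPS_HESSIAN)
            + (wr_total - cwr) ** 2 / np.maximum(w_total - cw, _EPS_HESSIAN)
            - parent
        )
        gain = np.where(ok, gain, -np.inf)
        k = int(np.argmax(gain))  # first max -> lowest threshold
        if gain[k] <= 0:
            continue
        cand = (-float(gain[k]), j, float(0.5 * (xs[k] + xs[k + 1])))
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    neg_gain, j, thr = best
    return -neg_gain, j, thr


def _fit_tree(
    X: np.ndarray,
    r: np.ndarray,
    w: np.ndarray,
    hess_w: np.ndarray,
    max_leaves: int,
    min_obs: int,
) -> dict:
    """Grow one regression tree best-first; returns a nested-dict tree.

    Internal nodes: {feature, threshold, gain, left, right}. Leaves:
    {value}. Leaf values are the Bernoulli Newton step over the node's bag
    observations.
    """

    def leaf_value(idx) -> float:
        return float((w[idx] * r[idx]).sum() / max(hess_w[idx].sum(), _EPS_HESSIAN))

    root_idx = np.arange(len(r))
    root: dict = {"value": leaf_value(root_idx)}
    # frontier: (node dict, member indices, cached best split), split best-gain-first
    frontier = [(root, root_idx, _best_split(X[root_idx], r[root_idx], w[root_idx], min_obs))]
    n_leaves = 1
    while n_leaves < max_leaves:
        splittable = [(f[2][0], i) for i, f in enumerate(frontier) if f[2] is not None]
        if not splittable:
            break
        # highest gain; ties -> earliest-created leaf
        _, pick = max(splittable, key=lambda t: (t[0], -t[1]))
        node, idx, (gain, feat, thr) = frontier.pop(pick)
        left_idx = idx[X[idx, feat] <= thr]
        right_idx = idx[X[idx, feat] > thr]
        left: dict = {"value": leaf_value(left_idx)}
        right: dict = {"value": leaf_value(right_idx)}
        node.clear()
        node.update(
            {"feature": int(feat), "threshold": float(thr), "gain": float(gain),
             "left": left, "right": right}
        )
        frontier.append((left, left_idx, _best_split(X[left_idx], r[left_idx], w[left_idx], min_obs)))
        frontier.append((right, right_idx, _best_split(X[right_idx], r[right_idx], w[right_idx], min_obs)))
        n_leaves += 1
    return root


def _predict_tree(tree: dict, X: np.ndarray) -> np.ndarray:
    out = np.empty(len(X))
    stack = [(tree, np.arange(len(X)))]
    while stack:
        node, idx = stack.pop()
        if "value" in node:
            out[idx] = node["value"]
            continue
        go_left = X[idx, node["feature"]] <= node["threshold"]
        stack.append((node["left"], idx[go_left]))
        stack.append((node["right"], idx[~go_left]))
    return out


def _weighted_deviance(y: np.ndarray, p: np.ndarray, w: np.ndarray) -> float:
    p = np.clip(p, _EPS_PROB, 1 - _EPS_PROB)
    return float(-2.0 * (w * (y * np.log(p) + (1 - y) * np.log(1 - p))).sum() / w.sum())


# ---------------------------------------------------------------------------
# fitting / prediction
# ---------------------------------------------------------------------------

def fit_brt(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray | None = None,
    config: BRTConfig = BRTConfig(),
    band_names: list[str] | None = None,
) -> BRTModel:
    """Fit a weighted BRT to binary labels.

    With ``config.early_stopping`` a random 20% internal holdout monitors
    deviance and boosting stops once it fails to improve for ``patience``
    stages (the tree list is trimmed to the best stage); otherwise exactly
    ``n_trees`` trees are fitted.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per label")
    if not np.isfinite(X).all():
        raise ValueError("covariates must be finite")
    if w is None:
        w = np.ones(len(y))
    w = np.asarray(w, float)
    if len(w) != len(y) or (w <= 0).any():
        raise ValueError("weights must be positive, one per observation")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError("y must contain both classes 0 and 1")
    if band_names is None:
        band_names = [f"band_{i}" for i in range(X.shape[1])]

    rng = np.random.default_rng(config.seed)

    hold_idx = np.array([], int)
    fit_idx = np.arange(len(y))
    if config.early_stopping:
        perm = rng.permutation(len(y))
        n_hold = max(1, int(round(config.holdout_fraction * len(y))))
        hold_idx, fit_idx = perm[:n_hold], np.sort(perm[n_hold:])
        if len(np.unique(y[fit_idx])) < 2:
            raise ValueError("internal holdout left a single-class training set")

    Xf, yf, wf = X[fit_idx], y[fit_idx], w[fit_idx]
    n = len(yf)
    prevalence = float((wf * yf).sum() / wf.sum())
    F0 = float(logit(np.clip(prevalence, _EPS_PROB, 1 - _EPS_PROB)))
    F = np.full(n, F0)
    F_hold = np.full(len(hold_idx), F0)

    bag_size = max(1, int(round(config.bag_fraction * n)))
    prob = wf / wf.sum()

    trees: list[dict] = []
    train_dev: list[float] = []
    hold_dev: list[float] = []
    best_stage, best_hold = 0, np.inf

    for stage in range(config.n_trees):
        p = expit(F)
        r = yf - p
        if config.bag_fraction < 1.0:
            bag = rng.choice(n, size=bag_size, replace=False, p=prob)
            bag = np.sort(bag)
        else:
            bag = np.arange(n)
        tree = _fit_tree(
            Xf[bag], r[bag], wf[bag], (wf * p * (1 - p))[bag],
            config.tree_complexity, config.min_obs_leaf,
        )
        F = F + config.shrinkage * _predict_tree(tree, Xf)
        trees.append(tree)
        train_dev.append(_weighted_deviance(yf, expit(F), wf))
        if config.early_stopping:
            F_hold = F_hold + config.shrinkage * _predict_tree(tree, X[hold_idx])
            d = _weighted_deviance(y[hold_idx], expit(F_hold), w[hold_idx])
            hold_dev.append(d)
            if d < best_hold - 1e-12:
                best_hold, best_stage = d, stage + 1
            elif stage + 1 - best_stage >= config.patience:
                trees = trees[:best_stage]
                train_dev = train_dev[:best_stage]
                hold_dev = hold_dev[:best_stage]
                break

    return BRTModel(
        intercept=F0,
        trees=trees,
        shrinkage=config.shrinkage,
        band_names=list(band_names),
        config=config,
        train_deviance=train_dev,
        holdout_deviance=hold_dev if config.early_stopping else None,
    )


def predict_brt(model: BRTModel, X: np.ndarray, band_names: list[str] | None = None) -> np.ndarray:
    """Predicted relative probability of occurrence, in (0, 1)."""
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[1] != len(model.band_names):
        raise ValueError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} columns, model expects {len(model.band_names)}"
        )
    if band_names is not None and list(band_names) != list(model.band_names):
        raise ValueError("band names do not match the fitted model")
    F = np.full(len(X), model.intercept)
    for tree in model.trees:
        F += model.shrinkage * _predict_tree(tree, X)
    return expit(F)


def variable_importance(model: BRTModel) -> dict[str, float]:
    """Relative influence per band: split-gain share, normalised to 100."""
    if model.n_trees == 0:
        raise ValueError("variable importance needs a model with >= 1 tree")
    gains = np.zeros(len(model.band_names))

    def walk(node: dict):
        if "value" in node:
            return
        gains[node["feature"]] += node["gain"]
        walk(node["left"])
        walk(node["right"])

    for tree in model.trees:
        walk(tree)
    total = gains.sum()
    if total <= 0:
        rel = np.full_like(gains, 100.0 / len(gains))
    else:
        rel = 100.0 * gains / total
    return dict(zip(model.band_names, rel.tolist()))
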