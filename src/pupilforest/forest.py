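"""Regression trees and forests for 2-D pupil displacement.

A tree maps a flattened gray-scale eye-patch feature vector (intensities in
[0, 1]) to a displacement ``(dx, dy)`` toward the pupil center, expressed in
eye-corner-distance units.  Split quality at a node holding sample set ``S``
is the variance-reduction gain

    F = SSE(S) - sum_{c in {L, R}} (|S_c| / |S|) * SSE(S_c)

where ``SSE`` pools squared deviations of both displacement components from
the node mean.  Both components are regressed jointly: every node stores a
single 2-D mean displacement and each leaf stores a small predictive model
(constant mean by default, optionally an affine fit on a leaf-local PCA
basis).  A forest predicts the unweighted mean of its trees.

All randomness flows through :class:`numpy.random.SeedSequence`, so identical
inputs and seeds reproduce bit-identical serialized models.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "EyeSample",
    "TreeConfig",
    "LeafModel",
    "SplitNode",
    "Leaf",
    "RegressionTree",
    "Forest",
    "split_gain",
    "candidate_thresholds",
    "find_best_split",
    "fit_leaf_model",
    "grow_tree",
    "predict_tree",
    "train_forest",
    "predict_forest",
    "tree_to_dict",
    "tree_from_dict",
    "forest_to_dict",
    "forest_from_dict",
]


@dataclass
class EyeSample:
    """One training unit: patch features, target displacement, weight."""

    features: np.ndarray
    target: np.ndarray
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if self.features.ndim != 1:
            raise ValueError("features must be a 1-D vector")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")
        if np.any(self.features < -1e-9) or np.any(self.features > 1 + 1e-9):
            raise ValueError("features must lie in [0, 1]")
        if self.target.shape != (2,) or not np.all(np.isfinite(self.target)):
            raise ValueError("target must be a finite (dx, dy) pair")
        if self.weight < 0:
            raise ValueError("weight must be nonnegative")


@dataclass
class TreeConfig:
    """Growth and leaf-model settings for a single regression tree.

    ``n_candidate_features=None`` means ``ceil(sqrt(D))`` features are drawn
    (without replacement, seeded) at every split node.  ``leaf_model`` is
    ``"constant"`` (node-mean displacement) or ``"linear"`` (affine fit on a
    leaf-local PCA basis of at most ``leaf_pca_components`` directions, with
    ridge damping ``leaf_ridge``; falls back to constant when the leaf holds
    too few samples for a stable fit).
    """

    max_depth: int = 6
    min_samples_leaf: int = 5
    n_candidate_features: Optional[int] = None
    n_thresholds: int = 16
    leaf_model: str = "constant"
    leaf_pca_components: int = 8
    leaf_ridge: float = 1e-6
    rng_seed: int = 0


@dataclass
class LeafModel:
    """Leaf predictor: constant mean or affine map on a reduced basis."""

    kind: str  # "constant" | "linear"
    value: np.ndarray  # (2,) mean displacement; intercept for "linear"
    feature_mean: Optional[np.ndarray] = None  # (D,)
    components: Optional[np.ndarray] = None  # (k, D) PCA directions
    coefficients: Optional[np.ndarray] = None  # (k, 2)

    def predict(self, features: np.ndarray) -> np.ndarray:
        if self.kind == "constant":
            return self.value.copy()
        z = (features - self.feature_mean) @ self.components.T
        return self.value + z @ self.coefficients


@dataclass
class Leaf:
    mean_displacement: np.ndarray
    model: LeafModel
    n_samples: int


@dataclass
class SplitNode:
    feature_index: int
    threshold: float
    mean_displacement: np.ndarray
    left: Union["SplitNode", Leaf]
    right: Union["SplitNode", Leaf]


@dataclass
class RegressionTree:
    root: Union[SplitNode, Leaf]
    n_features: int
    max_depth: int
    min_samples_leaf: int
    tree_id: int = 0


@dataclass
class Forest:
    """Nonempty ordered tree ensemble; prediction averages the trees."""

    trees: List[RegressionTree]
    forest_id: int = 0

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("a forest needs at least one tree")


# ---------------------------------------------------------------------------
# split search


def _as_arrays(samples: Sequence[EyeSample]) -> Tuple[np.ndarray, np.ndarray]:
    if len(samples) == 0:
        raise ValueError("empty sample list")
    X = np.stack([s.features for s in samples])
    Y = np.stack([s.target for s in samples])
    return X, Y


def _sse(Y: np.ndarray) -> float:
    if Y.shape[0] == 0:
        return 0.0
    mu = Y.mean(axis=0)
    return float(((Y - mu) ** 2).sum())


def _gain(Y: np.ndarray, mask: np.ndarray) -> float:
    n = Y.shape[0]
    n_left = int(mask.sum())
    n_right = n - n_left
    if n_left == 0 or n_right == 0:
        return 0.0
    # the child term is a commutative sum, so mirrored partitions (same
    # membership reached from different features) score bit-identically
    child = (n_left / n) * _sse(Y[mask]) + (n_right / n) * _sse(Y[~mask])
    return max(_sse(Y) - child, 0.0)


def split_gain(samples: Sequence[EyeSample], feature_index: int, threshold: float) -> float:
    """Variance-reduction gain of splitting on ``feature <= threshold``.

    Returns 0 for a split that leaves a child empty (rejected) and for
    degenerate nodes whose targets are all identical.
    """
    X, Y = _as_arrays(samples)
    if not 0 <= feature_index < X.shape[1]:
        raise IndexError(f"feature_index {feature_index} out of range")
    return _gain(Y, X[:, feature_index] <= threshold)


def candidate_thresholds(values: np.ndarray, n_thresholds: int) -> np.ndarray:
    """Distinct empirical quantiles of ``values`` (nearest-rank, ascending)."""
    xs = np.sort(np.asarray(values, dtype=float))
    if xs.size == 0:
        return xs
    q = np.linspace(0.0, 1.0, n_thresholds + 2)[1:-1]
    idx = np.clip(np.round(q * (xs.size - 1)).astype(int), 0, xs.size - 1)
    return np.unique(xs[idx])


def _best_split_arrays(
    X: np.ndarray,
    Y: np.ndarray,
    feature_indices: np.ndarray,
    n_thresholds: int,
) -> Optional[Tuple[int, float, float]]:
    """Best (feature, threshold, gain) over the candidate grid, or None.

    A vectorized pass scores every candidate; candidates within rounding
    distance of the best score are then re-scored with the scalar
    :func:`split_gain` arithmetic, and ties resolve to the lowest feature
    index and then the lowest threshold, so the result matches an exhaustive
    scalar enumeration exactly.
    """
    n = X.shape[0]
    sq = (Y**2).sum(axis=1)
    total = Y.sum(axis=0)
    total_sq = float(sq.sum())
    sse_parent = _sse(Y)

    per_feature = []  # (feature, thresholds, gains)
    best_gain = 0.0
    for f in feature_indices:
        col = X[:, f]
        thresholds = candidate_thresholds(col, n_thresholds)
        if thresholds.size == 0:
            continue
        mask = col[:, None] <= thresholds[None, :]  # (n, T)
        n_left = mask.sum(axis=0)
        n_right = n - n_left
        valid = (n_left > 0) & (n_right > 0)
        if not valid.any():
            continue
        sum_left = Y.T @ mask  # (2, T)
        sq_left = sq @ mask
        sum_right = total[:, None] - sum_left
        sq_right = total_sq - sq_left
        with np.errstate(divide="ignore", invalid="ignore"):
            sse_left = sq_left - (sum_left**2).sum(axis=0) / n_left
            sse_right = sq_right - (sum_right**2).sum(axis=0) / n_right
        sse_left = np.clip(sse_left, 0.0, None)
        sse_right = np.clip(sse_right, 0.0, None)
        gains = sse_parent - ((n_left / n) * sse_left + (n_right / n) * sse_right)
        gains = np.where(valid, np.clip(gains, 0.0, None), 0.0)
        per_feature.append((int(f), thresholds, gains))
        best_gain = max(best_gain, float(gains.max()))
    if best_gain <= 0.0:
        return None

    # exact re-scoring of near-ties with the canonical scalar arithmetic
    cutoff = best_gain - 1e-9 * max(1.0, best_gain)
    best: Optional[Tuple[int, float, float]] = None
    for f, thresholds, gains in per_feature:
        for j in np.flatnonzero(gains >= cutoff):
            exact = _gain(Y, X[:, f] <= thresholds[j])
            if exact > 0.0 and (best is None or exact > best[2]):
                best = (f, float(thresholds[j]), exact)
    return best


def find_best_split(
    samples: Sequence[EyeSample],
    candidate_feature_indices: Optional[Sequence[int]] = None,
    thresholds_per_feature: int = 16,
) -> Optional[Tuple[int, float, float]]:
    """Search the quantile-threshold grid for the maximum-gain split.

    Returns ``(feature_index, threshold, gain)`` or ``None`` when no split
    attains positive gain (the "make leaf" sentinel).
    """
    X, Y = _as_arrays(samples)
    if candidate_feature_indices is None:
        feats = np.arange(X.shape[1])
    else:
        feats = np.unique(np.asarray(candidate_feature_indices, dtype=int))
        if feats.size and (feats[0] < 0 or feats[-1] >= X.shape[1]):
            raise IndexError("candidate feature index out of range")
    return _best_split_arrays(X, Y, feats, thresholds_per_feature)


# ---------------------------------------------------------------------------
# leaf models


def fit_leaf_model(
    samples: Sequence[EyeSample],
    kind: str = "constant",
    n_components: int = 8,
    ridge: float = 1e-6,
) -> LeafModel:
    """Fit a leaf predictor on the samples reaching a leaf.

    ``"linear"`` performs an affine least-squares fit of the displacement on a
    leaf-local PCA reduction of the features (at most ``n_components``
    directions surviving a rank check), with ridge damping on the normal
    equations.  When the leaf holds no more than twice the reduced
    dimensionality, or the features are degenerate, it falls back to the
    constant sample-mean model.
    """
    X, Y = _as_arrays(samples)
    mean = Y.mean(axis=0)
    if kind == "constant":
        return LeafModel(kind="constant", value=mean)
    if kind != "linear":
        raise ValueError(f"unknown leaf model kind {kind!r}")
    n, d = X.shape
    mu = X.mean(axis=0)
    Xc = X - mu
    if n < 3:
        return LeafModel(kind="constant", value=mean)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s[0] * max(n, d) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    k = min(n_components, rank)
    if k < 1 or n <= 2 * k:
        return LeafModel(kind="constant", value=mean)
    V = Vt[:k]
    Z = Xc @ V.T
    A = Z.T @ Z + ridge * np.eye(k)
    B = np.linalg.solve(A, Z.T @ (Y - mean))
    return LeafModel(
        kind="linear", value=mean, feature_mean=mu, components=V, coefficients=B
    )


# ---------------------------------------------------------------------------
# tree growth and prediction


def grow_tree(
    samples: Sequence[EyeSample],
    config: Optional[TreeConfig] = None,
    tree_id: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> RegressionTree:
    """Recursively grow a regression tree with the variance-reduction gain.

    Splitting stops at ``max_depth``, when a node holds fewer than
    ``2 * min_samples_leaf`` samples, or when no candidate split has positive
    gain.  Candidate features are re-drawn at every node in preorder, so a
    fixed seed reproduces the tree exactly.
    """
    config = config or TreeConfig()
    X, Y = _as_arrays(samples)
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    n, d = X.shape
    k = config.n_candidate_features or max(1, math.ceil(math.sqrt(d)))
    k = min(k, d)

    def make_leaf(idx: np.ndarray) -> Leaf:
        sub = [samples[i] for i in idx]
        model = fit_leaf_model(
            sub,
            kind=config.leaf_model,
            n_components=config.leaf_pca_components,
            ridge=config.leaf_ridge,
        )
        return Leaf(
            mean_displacement=Y[idx].mean(axis=0), model=model, n_samples=len(idx)
        )

    def build(idx: np.ndarray, depth: int) -> Union[SplitNode, Leaf]:
        if depth >= config.max_depth or idx.size < 2 * config.min_samples_leaf:
            return make_leaf(idx)
        feats = np.sort(rng.choice(d, size=k, replace=False))
        found = _best_split_arrays(X[idx], Y[idx], feats, config.n_thresholds)
        if found is None:
            return make_leaf(idx)
        f, t, _ = found
        mask = X[idx, f] <= t
        left_idx, right_idx = idx[mask], idx[~mask]
        return SplitNode(
            feature_index=f,
            threshold=t,
            mean_displacement=Y[idx].mean(axis=0),
            left=build(left_idx, depth + 1),
            right=build(right_idx, depth + 1),
        )

    root = build(np.arange(n), 0)
    return RegressionTree(
        root=root,
        n_features=d,
        max_depth=config.max_depth,
        min_samples_leaf=config.min_samples_leaf,
        tree_id=tree_id,
    )


def predict_tree(tree: RegressionTree, features: np.ndarray) -> np.ndarray:
    """Route ``features`` (``<=`` goes left) to its unique leaf and predict."""
    features = np.asarray(features, dtype=float)
    if features.shape != (tree.n_features,):
        raise ValueError(
            f"expected {tree.n_features} features, got shape {features.shape}"
        )
    node = tree.root
    while isinstance(node, SplitNode):
        node = node.left if features[node.feature_index] <= node.threshold else node.right
    return node.model.predict(features)


# ---------------------------------------------------------------------------
# forests


def train_forest(
    samples: Sequence[EyeSample],
    n_trees: int = 10,
    bagging_fraction: float = 1.0,
    rng_seed: Union[int, np.random.SeedSequence] = 0,
    tree_config: Optional[TreeConfig] = None,
    forest_id: int = 0,
) -> Forest:
    """Train ``n_trees`` trees on bootstrap resamples and bundle them.

    Each tree gets an independent child seed spawned from ``rng_seed`` and a
    bootstrap sample (with replacement) of ``round(bagging_fraction * n)``
    rows, so the forest is fully reproducible.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if not 0 < bagging_fraction <= 1:
        raise ValueError("bagging_fraction must lie in (0, 1]")
    tree_config = tree_config or TreeConfig()
    n = len(samples)
    if n == 0:
        raise ValueError("empty sample list")
    ss = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    trees = []
    for i, child in enumerate(ss.spawn(n_trees)):
        rng = np.random.default_rng(child)
        m = max(1, int(round(bagging_fraction * n)))
        idx = rng.integers(0, n, size=m)
        boot = [samples[j] for j in idx]
        trees.append(grow_tree(boot, tree_config, tree_id=i, rng=rng))
    return Forest(trees=trees, forest_id=forest_id)


def predict_forest(forest: Forest, features: np.ndarray) -> np.ndarray:
    preds = np.stack([predict_tree(t, features) for t in forest.trees])
    return preds.mean(axis=0)


# ---------------------------------------------------------------------------
# serialization (structured JSON; re-serialization is byte-exact)


def _leaf_model_to_dict(m: LeafModel) -> dict:
    out: dict = {"kind": m.kind, "value": [float(v) for v in m.value]}
    if m.kind == "linear":
        out["feature_mean"] = [float(v) for v in m.feature_mean]
        out["components"] = [[float(v) for v in row] for row in m.components]
        out["coefficients"] = [[float(v) for v in row] for row in m.coefficients]
    return out


def _leaf_model_from_dict(d: dict) -> LeafModel:
    if d["kind"] == "constant":
        return LeafModel(kind="constant", value=np.array(d["value"], dtype=float))
    return LeafModel(
        kind="linear",
        value=np.array(d["value"], dtype=float),
        feature_mean=np.array(d["feature_mean"], dtype=float),
        components=np.array(d["components"], dtype=float),
        coefficients=np.array(d["coefficients"], dtype=float),
    )


def _node_to_dict(node: Union[SplitNode, Leaf]) -> dict:
    if isinstance(node, Leaf):
        return {
            "leaf": True,
            "mean_dx": float(node.mean_displacement[0]),
            "mean_dy": float(node.mean_displacement[1]),
            "n_samples": int(node.n_samples),
            "model": _leaf_model_to_dict(node.model),
        }
    return {
        "leaf": False,
        "feature": int(node.feature_index),
        "threshold": float(node.threshold),
        "mean_dx": float(node.mean_displacement[0]),
        "mean_dy": float(node.mean_displacement[1]),
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
    }


def _node_from_dict(d: dict) -> Union[SplitNode, Leaf]:
    mean = np.array([d["mean_dx"], d["mean_dy"]], dtype=float)
    if d["leaf"]:
        return Leaf(
            mean_displacement=mean,
            model=_leaf_model_from_dict(d["model"]),
            n_samples=int(d["n_samples"]),
        )
    return SplitNode(
        feature_index=int(d["feature"]),
        threshold=float(d["threshold"]),
        mean_displacement=mean,
        left=_node_from_dict(d["left"]),
        right=_node_from_dict(d["right"]),
    )


def tree_to_dict(tree: RegressionTree) -> dict:
    return {
        "tree_id": int(tree.tree_id),
        "n_features": int(tree.n_features),
        "max_depth": int(tree.max_depth),
        "min_samples_leaf": int(tree.min_samples_leaf),
        "root": _node_to_dict(tree.root),
    }


def tree_from_dict(d: dict) -> RegressionTree:
    return RegressionTree(
        root=_node_from_dict(d["root"]),
        n_features=int(d["n_features"]),
        max_depth=int(d["max_depth"]),
        min_samples_leaf=int(d["min_samples_leaf"]),
        tree_id=int(d["tree_id"]),
    )


def forest_to_dict(forest: Forest) -> dict:
    return {
        "forest_id": int(forest.forest_id),
        "trees": [tree_to_dict(t) for t in forest.trees],
    }


def forest_from_dict(d: dict) -> Forest:
    return Forest(
        trees=[tree_from_dict(t) for t in d["trees"]],
        forest_id=int(d["forest_id"]),
    )
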