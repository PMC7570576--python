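"""Coarse-to-fine cascade of regression-forest layers for pupil localization.

The pupil estimate starts at the midpoint of the two eye corners and is
refined layer by layer:

    Z_l = Z_{l-1} + RF_l(I, Z_{l-1}),   l = 1..L

where ``RF_l`` extracts a gray-scale patch around the current estimate (the
crop window shrinks with depth, so late layers see finer detail), predicts a
corner-distance-normalized displacement as the average over the layer's
forests, and the estimate moves by that displacement in pixels.  Training
follows the same schedule: at each layer the targets are the residuals
``(gt - Z_{l-1}) / corner_distance`` and patches are re-extracted at the
updated positions before the next layer is fitted.

Left and right eyes are pooled into one model: right-eye patches are mirrored
horizontally (and ``dx`` negated) so displacement statistics align across
eyes.  Coordinates are 0-based pixels, origin top-left, x rightward, y
downward; patches are flattened row-major.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.ndimage import map_coordinates

from .forest import (
    EyeSample,
    Forest,
    TreeConfig,
    forest_from_dict,
    forest_to_dict,
    predict_forest,
    train_forest,
)

__all__ = [
    "LayerConfig",
    "CascadeModel",
    "EyeObservation",
    "EyeAnnotation",
    "DEFAULT_SCHEDULE",
    "initial_position",
    "extract_patch",
    "patch_features",
    "to_normalized",
    "from_normalized",
    "train_cascade",
    "predict_cascade",
    "predict_eyes",
    "cascade_to_json",
    "cascade_from_json",
]


@dataclass
class LayerConfig:
    """Geometry and ensemble size of one cascade layer.

    ``crop_scale`` is the square crop window as a fraction of the eye-corner
    distance; ``patch_side`` is the resampled patch resolution in pixels.
    """

    n_forests: int = 5
    n_trees_per_forest: int = 10
    crop_scale: float = 1.0
    patch_side: int = 24

    def __post_init__(self) -> None:
        if self.n_forests < 1:
            raise ValueError("n_forests must be >= 1")
        if self.n_trees_per_forest < 1:
            raise ValueError("n_trees_per_forest must be >= 1")
        if not 0 < self.crop_scale <= 1:
            raise ValueError("crop_scale must lie in (0, 1]")
        if self.patch_side < 2:
            raise ValueError("patch_side must be >= 2")


#: Three layers, each deeper layer with more forests/trees and a tighter crop.
DEFAULT_SCHEDULE: List[LayerConfig] = [
    LayerConfig(n_forests=5, n_trees_per_forest=10, crop_scale=1.0),
    LayerConfig(n_forests=10, n_trees_per_forest=20, crop_scale=0.6),
    LayerConfig(n_forests=15, n_trees_per_forest=30, crop_scale=0.35),
]


@dataclass
class EyeObservation:
    """Per-eye annotation: the two corners, optional 6 landmarks, GT pupil.

    ``landmarks`` rows are ordered [corner0, corner1, upper0, upper1,
    lower0, lower1]; the lid points pair up vertically for the eye-aspect
    ratio.
    """

    lm0: np.ndarray
    lm1: np.ndarray
    gt: np.ndarray
    landmarks: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.lm0 = np.asarray(self.lm0, dtype=float)
        self.lm1 = np.asarray(self.lm1, dtype=float)
        self.gt = np.asarray(self.gt, dtype=float)
        if self.landmarks is not None:
            self.landmarks = np.asarray(self.landmarks, dtype=float)

    @property
    def corner_distance(self) -> float:
        return float(np.linalg.norm(self.lm1 - self.lm0))


@dataclass
class EyeAnnotation:
    """Both eyes of one image: corners, landmarks, ground-truth pupils."""

    image_path: str
    left: EyeObservation
    right: EyeObservation


@dataclass
class CascadeModel:
    layers: List[LayerConfig]
    forests: List[List[Forest]]  # [layer][forest]
    tree_config: TreeConfig
    mirrored_right: bool = True
    training_residuals: List[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= len(self.layers) <= 5:
            raise ValueError("a cascade has between 1 and 5 layers")
        if len(self.layers) != len(self.forests):
            raise ValueError("layer configs and forest lists must align")


# ---------------------------------------------------------------------------
# geometry primitives


def initial_position(lm0: np.ndarray, lm1: np.ndarray) -> np.ndarray:
    """Starting pupil estimate: the midpoint of the two eye corners."""
    lm0 = np.asarray(lm0, dtype=float)
    lm1 = np.asarray(lm1, dtype=float)
    if np.linalg.norm(lm1 - lm0) < 1e-9:
        raise ValueError("eye corners must be distinct")
    return (lm0 + lm1) / 2.0


def _as_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = img / 255.0
    if img.ndim == 3:
        img = img[..., :3] @ np.array([0.299, 0.587, 0.114])
    return np.asarray(img, dtype=float)


def extract_patch(
    image: np.ndarray, center: np.ndarray, window: float, patch_side: int
) -> np.ndarray:
    """Crop, resample, and flatten a square gray-scale patch.

    A ``window``-pixel square centered at ``center`` (x, y) is sampled on a
    ``patch_side x patch_side`` grid with bilinear interpolation
    (out-of-bounds pixels mirrored), intensities clipped to [0, 1], and
    flattened row-major.
    """
    if window < 2:
        raise ValueError("crop window must be at least 2 pixels")
    img = _as_gray(image)
    center = np.asarray(center, dtype=float)
    offsets = (np.arange(patch_side) + 0.5) * (window / patch_side) - window / 2.0
    cols = center[0] + offsets
    rows = center[1] + offsets
    cc, rr = np.meshgrid(cols, rows)
    patch = map_coordinates(img, [rr, cc], order=1, mode="mirror")
    return np.clip(patch, 0.0, 1.0).ravel()


def patch_features(
    image: np.ndarray,
    center: np.ndarray,
    window: float,
    patch_side: int,
    mirror: bool = False,
) -> np.ndarray:
    """Patch features, optionally mirrored about the patch's vertical axis."""
    feats = extract_patch(image, center, window, patch_side)
    if mirror:
        feats = feats.reshape(patch_side, patch_side)[:, ::-1].ravel()
    return feats


def to_normalized(displacement_pixels: np.ndarray, corner_distance: float) -> np.ndarray:
    """Pixel displacement -> eye-corner-distance units."""
    if corner_distance <= 0:
        raise ValueError("corner distance must be positive")
    return np.asarray(displacement_pixels, dtype=float) / corner_distance


def from_normalized(displacement: np.ndarray, corner_distance: float) -> np.ndarray:
    """Eye-corner-distance units -> pixel displacement."""
    if corner_distance <= 0:
        raise ValueError("corner distance must be positive")
    return np.asarray(displacement, dtype=float) * corner_distance


# ---------------------------------------------------------------------------
# training


@dataclass
class _SampleState:
    image_index: int
    obs: EyeObservation
    mirror: bool
    estimate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.estimate = initial_position(self.obs.lm0, self.obs.lm1)


def train_cascade(
    images: Sequence[np.ndarray],
    annotations: Sequence[EyeAnnotation],
    schedule: Optional[Sequence[LayerConfig]] = None,
    seed: int = 0,
    tree_config: Optional[TreeConfig] = None,
    bagging_fraction: float = 1.0,
    mirror_right: bool = True,
) -> CascadeModel:
    """Fit the layered displacement regressors on annotated eye images.

    Every annotated eye contributes one sample per layer; right eyes are
    mirrored into the left-eye frame when ``mirror_right`` (the default).
    Per-layer mean training residuals (pixels, after the layer's update) are
    stored on the returned model, preceded by the residual of the corner-
    midpoint initialization.
    """
    if schedule is None:
        schedule = DEFAULT_SCHEDULE
    schedule = list(schedule)
    if not schedule:
        raise ValueError("layer schedule must be nonempty")
    if not annotations:
        raise ValueError("no annotations given")
    tree_config = tree_config or TreeConfig()

    states: List[_SampleState] = []
    for i, ann in enumerate(annotations):
        states.append(_SampleState(i, ann.left, mirror=False))
        states.append(_SampleState(i, ann.right, mirror=mirror_right))

    def mean_residual() -> float:
        return float(
            np.mean([np.linalg.norm(s.obs.gt - s.estimate) for s in states])
        )

    residuals = [mean_residual()]
    root_ss = np.random.SeedSequence(seed)
    layer_seeds = root_ss.spawn(len(schedule))
    layer_forests: List[List[Forest]] = []

    for layer, layer_ss in zip(schedule, layer_seeds):
        samples = []
        for s in states:
            cd = s.obs.corner_distance
            feats = patch_features(
                images[s.image_index],
                s.estimate,
                layer.crop_scale * cd,
                layer.patch_side,
                mirror=s.mirror,
            )
            target = to_normalized(s.obs.gt - s.estimate, cd)
            if s.mirror:
                target = np.array([-target[0], target[1]])
            samples.append(EyeSample(features=feats, target=target))

        forests = [
            train_forest(
                samples,
                n_trees=layer.n_trees_per_forest,
                bagging_fraction=bagging_fraction,
                rng_seed=child,
                tree_config=tree_config,
                forest_id=fi,
            )
            for fi, child in enumerate(layer_ss.spawn(layer.n_forests))
        ]
        layer_forests.append(forests)

        for s, sample in zip(states, samples):
            preds = np.stack(
                [predict_forest(f, sample.features) for f in forests]
            )
            pred = preds.mean(axis=0)
            if s.mirror:
                pred = np.array([-pred[0], pred[1]])
            s.estimate = s.estimate + from_normalized(pred, s.obs.corner_distance)
        residuals.append(mean_residual())

    return CascadeModel(
        layers=schedule,
        forests=layer_forests,
        tree_config=tree_config,
        mirrored_right=mirror_right,
        training_residuals=residuals,
    )


# ---------------------------------------------------------------------------
# inference


def predict_cascade(
    model: CascadeModel,
    image: np.ndarray,
    lm0: np.ndarray,
    lm1: np.ndarray,
    mirror: bool = False,
) -> np.ndarray:
    """Run the trained cascade from the corner midpoint to the pupil center."""
    if not model.forests or not model.forests[0]:
        raise ValueError("model has no trained forests")
    estimate = initial_position(lm0, lm1)
    cd = float(np.linalg.norm(np.asarray(lm1, float) - np.asarray(lm0, float)))
    for layer, forests in zip(model.layers, model.forests):
        feats = patch_features(
            image, estimate, layer.crop_scale * cd, layer.patch_side, mirror=mirror
        )
        preds = np.stack([predict_forest(f, feats) for f in forests])
        pred = preds.mean(axis=0)
        if mirror:
            pred = np.array([-pred[0], pred[1]])
        estimate = estimate + from_normalized(pred, cd)
    return estimate


def predict_eyes(
    model: CascadeModel, image: np.ndarray, annotation: EyeAnnotation
) -> Tuple[np.ndarray, np.ndarray]:
    """Predict (left, right) pupil centers for one annotated image."""
    left = predict_cascade(
        model, image, annotation.left.lm0, annotation.left.lm1, mirror=False
    )
    right = predict_cascade(
        model,
        image,
        annotation.right.lm0,
        annotation.right.lm1,
        mirror=model.mirrored_right,
    )
    return left, right


# ---------------------------------------------------------------------------
# serialization


def _tree_config_to_dict(c: TreeConfig) -> dict:
    return {
        "max_depth": c.max_depth,
        "min_samples_leaf": c.min_samples_leaf,
        "n_candidate_features": c.n_candidate_features,
        "n_thresholds": c.n_thresholds,
        "leaf_model": c.leaf_model,
        "leaf_pca_components": c.leaf_pca_components,
        "leaf_ridge": c.leaf_ridge,
        "rng_seed": c.rng_seed,
    }


def _layer_to_dict(layer: LayerConfig) -> dict:
    return {
        "n_forests": layer.n_forests,
        "n_trees_per_forest": layer.n_trees_per_forest,
        "crop_scale": layer.crop_scale,
        "patch_side": layer.patch_side,
    }


def cascade_to_json(model: CascadeModel) -> str:
    doc = {
        "format": "pupilforest-cascade-v1",
        "mirrored_right": model.mirrored_right,
        "tree_config": _tree_config_to_dict(model.tree_config),
        "layers": [_layer_to_dict(l) for l in model.layers],
        "training_residuals": [float(r) for r in model.training_residuals],
        "forests": [[forest_to_dict(f) for f in layer] for layer in model.forests],
    }
    return json.dumps(doc)


def cascade_from_json(text: str) -> CascadeModel:
    doc = json.loads(text)
    if doc.get("format") != "pupilforest-cascade-v1":
        raise ValueError("not a pupilforest cascade model file")
    return CascadeModel(
        layers=[LayerConfig(**l) for l in doc["layers"]],
        forests=[[forest_from_dict(f) for f in layer] for layer in doc["forests"]],
        tree_config=TreeConfig(**doc["tree_config"]),
        mirrored_right=bool(doc["mirrored_right"]),
        training_residuals=[float(r) for r in doc["training_residuals"]],
    )
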