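"""Maximum-normalized-error metric, accuracy reports, and cross-validation.

The per-image error is

    e_d = max(d_L, d_R) / d_LR

where ``d_L`` and ``d_R`` are the Euclidean distances between predicted and
true pupil centers of the left and right eye and ``d_LR`` is the distance
between the two true centers.  Accuracy at a threshold t is the percentage
of images with ``e_d <= t``; the conventional thresholds are 0.025, 0.05
(within the pupil), and 0.1 (within the iris).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .cascade import CascadeModel, EyeAnnotation, predict_eyes
from .rules import ModelStats, RuleSet, predict_eyes_ruleset

__all__ = [
    "DEFAULT_THRESHOLDS",
    "EvalReport",
    "normalized_error",
    "accuracy_report",
    "kfold_split",
    "evaluate_model",
]

DEFAULT_THRESHOLDS: Tuple[float, ...] = (0.025, 0.05, 0.1)


@dataclass
class EvalReport:
    n_images: int
    accuracy_at: Dict[float, float]  # threshold -> percentage
    errors: List[float]
    stats: Optional[ModelStats] = None

    def to_json(self) -> str:
        doc = {
            "n_images": self.n_images,
            "accuracy_at": {repr(k): v for k, v in self.accuracy_at.items()},
            "errors": self.errors,
        }
        if self.stats is not None:
            doc["stats"] = {
                "n_rules": self.stats.n_rules,
                "n_parameters": self.stats.n_parameters,
                "n_operations_per_inference": self.stats.n_operations_per_inference,
            }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        doc = json.loads(text)
        stats = None
        if "stats" in doc:
            stats = ModelStats(**doc["stats"])
        return cls(
            n_images=int(doc["n_images"]),
            accuracy_at={float(k): float(v) for k, v in doc["accuracy_at"].items()},
            errors=[float(e) for e in doc["errors"]],
            stats=stats,
        )

    def to_text(self) -> str:
        lines = [f"images: {self.n_images}"]
        for t in sorted(self.accuracy_at):
            lines.append(f"accuracy @ e_d <= {t:g}: {self.accuracy_at[t]:6.2f} %")
        if self.stats is not None:
            lines.append(
                f"rules: {self.stats.n_rules}  parameters: {self.stats.n_parameters}"
                f"  ops/inference: {self.stats.n_operations_per_inference}"
            )
        return "\n".join(lines) + "\n"


def normalized_error(
    pred_left: np.ndarray,
    pred_right: np.ndarray,
    gt_left: np.ndarray,
    gt_right: np.ndarray,
) -> float:
    """Worst per-eye error normalized by the true inter-pupil distance."""
    gt_left = np.asarray(gt_left, dtype=float)
    gt_right = np.asarray(gt_right, dtype=float)
    d_lr = float(np.linalg.norm(gt_left - gt_right))
    if d_lr < 1e-9:
        raise ValueError("ground-truth pupil centers coincide")
    d_l = float(np.linalg.norm(np.asarray(pred_left, float) - gt_left))
    d_r = float(np.linalg.norm(np.asarray(pred_right, float) - gt_right))
    return max(d_l, d_r) / d_lr


def accuracy_report(
    errors: Sequence[float],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    stats: Optional[ModelStats] = None,
) -> EvalReport:
    """Percentage of images at or below each threshold (``<=`` at the edge)."""
    errors = [float(e) for e in errors]
    if not errors:
        raise ValueError("no errors given")
    arr = np.asarray(errors)
    acc = {
        float(t): float(100.0 * np.mean(arr <= t)) for t in thresholds
    }
    return EvalReport(
        n_images=len(errors), accuracy_at=acc, errors=errors, stats=stats
    )


def kfold_split(
    n_or_items: Union[int, Sequence], k: int, seed: int = 0
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Seeded shuffled k-fold: disjoint covering test folds, sizes differ <= 1."""
    n = n_or_items if isinstance(n_or_items, int) else len(n_or_items)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("k cannot exceed the number of items")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    folds, start = [], 0
    for size in sizes:
        test = np.sort(order[start : start + size])
        train = np.sort(np.concatenate([order[:start], order[start + size :]]))
        folds.append((train, test))
        start += size
    return folds


def evaluate_model(
    model: Union[CascadeModel, RuleSet],
    images: Sequence[np.ndarray],
    annotations: Sequence[EyeAnnotation],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    stats: Optional[ModelStats] = None,
) -> EvalReport:
    """Predict every annotated image and summarize e_d accuracies."""
    predict = (
        predict_eyes_ruleset if isinstance(model, RuleSet) else predict_eyes
    )
    errors = []
    for img, ann in zip(images, annotations):
        pred_l, pred_r = predict(model, img, ann)
        errors.append(
            normalized_error(pred_l, pred_r, ann.left.gt, ann.right.gt)
        )
    return accuracy_report(errors, thresholds, stats=stats)
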