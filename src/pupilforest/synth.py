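"""Seedable synthetic two-eye image renderer with exact ground truth.

The renderer emulates what matters for intensity-patch displacement
regression: an almond-shaped brighter sclera on a skin background, an iris
disk with a darker concentric pupil, an upper eyelid that can occlude the eye
partially or fully, a horizontal illumination gradient, and additive Gaussian
pixel noise.  Both eyes are drawn in one frame with conjugate gaze (the same
normalized pupil offset), and the inter-pupil distance is about 2.3x the
eye-corner distance, following adult facial proportions, so the maximum
normalized error metric is computable per image.

Per eye it emits the two corners, four eyelid landmarks, and the exact pupil
center.  All geometry is deterministic in the scene parameters; the only
stochastic element is the pixel noise, driven by the scene seed.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .cascade import EyeAnnotation, EyeObservation

__all__ = [
    "SceneParams",
    "DEFAULT_RANGES",
    "render_eye",
    "generate_dataset",
    "generate_sequence",
]


@dataclass
class SceneParams:
    """Parameters of one rendered scene (both eyes share the gaze offset).

    ``pupil_offset`` is normalized to the eye half-box: (±1, ±1) puts the
    pupil at the corner of the open-eye bounding box.  ``pupil_radius_fraction``
    scales the eye-corner distance.  ``lid_closure`` runs from 0 (open) to 1
    (fully closed).
    """

    image_size: Tuple[int, int] = (256, 96)  # (width, height)
    eye_width: float = 56.0
    pupil_radius_fraction: float = 0.11
    pupil_offset: Tuple[float, float] = (0.0, 0.0)
    sclera_intensity: float = 0.85
    iris_intensity: float = 0.45
    pupil_intensity: float = 0.12
    illumination_gradient: float = 0.0
    lid_closure: float = 0.0
    noise_std: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pupil_intensity < self.iris_intensity < self.sclera_intensity:
            raise ValueError(
                "intensities must satisfy pupil < iris < sclera"
            )
        if not 0 <= self.lid_closure <= 1:
            raise ValueError("lid_closure must lie in [0, 1]")
        if self.noise_std < 0:
            raise ValueError("noise_std must be nonnegative")


#: Sampling ranges used by :func:`generate_dataset`.
DEFAULT_RANGES: Dict[str, object] = {
    "pupil_offset": (-0.3, 0.3),
    "pupil_radius_fraction": (0.08, 0.15),
    "noise_std": (0.0, 0.05),
    "illumination_gradient": (-0.2, 0.2),
    "lid_closure_prob": 0.1,
}

_SKIN = 0.62
_HALF_HEIGHT_FRACTION = 0.25  # open-eye half height as a fraction of eye width


def _eye_centers(params: SceneParams) -> List[np.ndarray]:
    w, h = params.image_size
    return [
        np.array([0.25 * w, 0.5 * h]),
        np.array([0.75 * w, 0.5 * h]),
    ]


def _render_one_eye(
    canvas: np.ndarray, center: np.ndarray, params: SceneParams
) -> EyeObservation:
    half_w = params.eye_width / 2.0
    half_h = _HALF_HEIGHT_FRACTION * params.eye_width
    h, w = canvas.shape
    yy, xx = np.mgrid[0:h, 0:w]
    t = (xx - center[0]) / half_w
    inside_x = np.abs(t) <= 1.0
    arch = half_h * np.clip(1.0 - t**2, 0.0, None)
    lower = center[1] + arch
    upper = center[1] - arch * (1.0 - 2.0 * params.lid_closure)
    open_region = inside_x & (yy >= upper) & (yy <= lower)

    canvas[open_region] = params.sclera_intensity

    pupil_center = center + np.array(
        [params.pupil_offset[0] * half_w, params.pupil_offset[1] * half_h]
    )
    r_pupil = params.pupil_radius_fraction * params.eye_width
    r_iris = 2.2 * r_pupil
    dist2 = (xx - pupil_center[0]) ** 2 + (yy - pupil_center[1]) ** 2
    canvas[open_region & (dist2 <= r_iris**2)] = params.iris_intensity
    canvas[open_region & (dist2 <= r_pupil**2)] = params.pupil_intensity

    def lid_point(tq: float, top: bool) -> np.ndarray:
        x = center[0] + tq * half_w
        a = half_h * (1.0 - tq**2)
        y = center[1] - a * (1.0 - 2.0 * params.lid_closure) if top else center[1] + a
        return np.array([x, y])

    landmarks = np.stack(
        [
            center + np.array([-half_w, 0.0]),
            center + np.array([half_w, 0.0]),
            lid_point(-0.5, top=True),
            lid_point(0.5, top=True),
            lid_point(-0.5, top=False),
            lid_point(0.5, top=False),
        ]
    )
    return EyeObservation(
        lm0=landmarks[0],
        lm1=landmarks[1],
        gt=pupil_center,
        landmarks=landmarks,
    )


def render_eye(params: SceneParams) -> Tuple[np.ndarray, EyeAnnotation]:
    """Render one two-eye frame and its exact annotation.

    Returns a float image in [0, 1] (height x width) and an
    :class:`~pupilforest.cascade.EyeAnnotation` whose ``image_path`` is empty
    (callers writing files fill it in).
    """
    w, h = params.image_size
    canvas = np.full((h, w), _SKIN, dtype=float)
    left_c, right_c = _eye_centers(params)
    left = _render_one_eye(canvas, left_c, params)
    right = _render_one_eye(canvas, right_c, params)

    canvas = gaussian_filter(canvas, sigma=0.8)
    if params.illumination_gradient != 0.0:
        xnorm = np.linspace(-0.5, 0.5, w)[None, :]
        canvas = canvas + params.illumination_gradient * xnorm
    if params.noise_std > 0:
        rng = np.random.default_rng(params.seed)
        canvas = canvas + rng.normal(0.0, params.noise_std, size=canvas.shape)
    canvas = np.clip(canvas, 0.0, 1.0)
    return canvas, EyeAnnotation(image_path="", left=left, right=right)


def _sample_params(rng: np.random.Generator, ranges: Dict[str, object], base: SceneParams) -> SceneParams:
    lo, hi = ranges["pupil_offset"]
    dx = rng.uniform(lo, hi)
    dy = rng.uniform(lo, hi)
    r = rng.uniform(*ranges["pupil_radius_fraction"])
    noise = rng.uniform(*ranges["noise_std"])
    illum = rng.uniform(*ranges["illumination_gradient"])
    blink = rng.uniform() < ranges["lid_closure_prob"]
    seed = int(rng.integers(0, 2**31 - 1))
    return replace(
        base,
        pupil_offset=(dx, dy),
        pupil_radius_fraction=r,
        noise_std=noise,
        illumination_gradient=illum,
        lid_closure=1.0 if blink else 0.0,
        seed=seed,
    )


def generate_dataset(
    n: int,
    seed: int = 0,
    ranges: Optional[Dict[str, object]] = None,
    base: Optional[SceneParams] = None,
    out_dir: Optional[str] = None,
) -> Tuple[List[np.ndarray], List[EyeAnnotation], List[SceneParams]]:
    """Sample ``n`` scenes with parameters drawn uniformly from ``ranges``.

    With ``out_dir`` the images are written as PNG and the annotations as a
    TSV manifest (``annotations.tsv``); otherwise everything stays in memory.
    Returns (images, annotations, scene parameters).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    merged = dict(DEFAULT_RANGES)
    if ranges:
        merged.update(ranges)
    for key in ("pupil_offset", "pupil_radius_fraction", "noise_std", "illumination_gradient"):
        lo, hi = merged[key]
        if hi < lo:
            raise ValueError(f"empty range for {key}")
    base = base or SceneParams()
    rng = np.random.default_rng(seed)
    images, annotations, scene_params = [], [], []
    for i in range(n):
        p = _sample_params(rng, merged, base)
        img, ann = render_eye(p)
        ann.image_path = f"eye_{i:05d}.png"
        images.append(img)
        annotations.append(ann)
        scene_params.append(p)
    if out_dir is not None:
        _write_dataset(out_dir, images, annotations)
    return images, annotations, scene_params


def generate_sequence(
    n_frames: int,
    step_sigma: float = 0.03,
    blink_prob: float = 0.05,
    seed: int = 0,
    base: Optional[SceneParams] = None,
    bound: float = 0.3,
    noise_std: Optional[float] = None,
    pupil_radius: Optional[float] = None,
) -> Tuple[List[np.ndarray], List[EyeAnnotation], List[dict]]:
    """Render a gaze sequence: reflective random-walk offset plus blinks.

    The pupil offset performs a Gaussian random walk (per-axis standard
    deviation ``step_sigma``) reflected at ``±bound``; blink frames set
    ``lid_closure`` to 1 while the ground-truth pupil keeps moving under the
    lid.  Returns (frames, annotations, per-frame metadata) where metadata
    rows carry ``frame``, ``lid_closure``, and the raw offset.
    """
    if n_frames < 2:
        raise ValueError("a sequence needs at least 2 frames")
    base = base or SceneParams()
    rng = np.random.default_rng(seed)
    radius = float(rng.uniform(0.09, 0.13)) if pupil_radius is None else pupil_radius
    noise = float(rng.uniform(0.0, 0.03)) if noise_std is None else noise_std
    offset = np.array([rng.uniform(-bound, bound), rng.uniform(-bound, bound)])
    images, annotations, meta = [], [], []
    for i in range(n_frames):
        if i > 0:
            offset = offset + rng.normal(0.0, step_sigma, size=2)
            offset = _reflect(offset, bound)
        blink = bool(rng.uniform() < blink_prob) if i > 0 else False
        p = replace(
            base,
            pupil_offset=(float(offset[0]), float(offset[1])),
            pupil_radius_fraction=radius,
            noise_std=noise,
            lid_closure=1.0 if blink else 0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        img, ann = render_eye(p)
        ann.image_path = f"frame_{i:05d}.png"
        images.append(img)
        annotations.append(ann)
        meta.append(
            {
                "frame": i,
                "lid_closure": p.lid_closure,
                "offset_x": float(offset[0]),
                "offset_y": float(offset[1]),
            }
        )
    return images, annotations, meta


def _reflect(offset: np.ndarray, bound: float) -> np.ndarray:
    out = offset.copy()
    for k in range(2):
        # fold the walk back into [-bound, bound]
        period = 4.0 * bound
        x = (out[k] + bound) % period
        if x > 2.0 * bound:
            x = period - x
        out[k] = x - bound
    return out


def _write_dataset(out_dir, images, annotations) -> None:
    import imageio.v3 as iio

    from .io import write_annotations

    os.makedirs(out_dir, exist_ok=True)
    for img, ann in zip(images, annotations):
        iio.imwrite(
            os.path.join(out_dir, ann.image_path),
            (np.clip(img, 0, 1) * 255).round().astype(np.uint8),
        )
    write_annotations(os.path.join(out_dir, "annotations.tsv"), annotations)
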