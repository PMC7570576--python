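"""Temporal pupil tracking with a particle-based consistency check.

Per frame and per eye, the cascade (or distilled rule set) proposes a pupil
position.  To suppress spurious jumps, a small set of candidate particles is
spread between the new prediction and the previous pupil position —
interpolation weights evenly spaced in [0.5, 1], plus white Gaussian noise —
and the particle closest (L2) to the previous position becomes the frame's
output.  The check is skipped when the eye is closed (eye-aspect ratio below
threshold), in which case the previous position is carried forward, and on
the first frame, which bootstraps from the raw prediction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .cascade import CascadeModel, EyeAnnotation, predict_cascade
from .rules import RuleSet, predict_ruleset

__all__ = [
    "TrackState",
    "FrameResult",
    "propagate_particles",
    "consistency_select",
    "eye_open",
    "make_predictor",
    "track_frame",
    "track_sequence",
    "write_track_csv",
]


@dataclass
class TrackState:
    """Per-eye tracker state: previous position, particle settings, RNG."""

    particle_count: int = 3
    noise_sigma: float = 2.0  # pixels
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))
    prev_position: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.particle_count < 1:
            raise ValueError("particle_count must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


@dataclass
class FrameResult:
    position: np.ndarray
    particles: List[np.ndarray]
    selected_index: int
    eye_open: bool


def propagate_particles(
    prediction: np.ndarray, prev: Optional[np.ndarray], state: TrackState
) -> List[np.ndarray]:
    """Spread particles between prediction and previous position, plus noise.

    Particle k sits at ``a_k * prediction + (1 - a_k) * prev`` with weights
    ``a`` evenly spaced in [0.5, 1], perturbed by isotropic Gaussian noise of
    ``state.noise_sigma`` pixels.  Without a previous position every particle
    collapses onto the prediction.
    """
    prediction = np.asarray(prediction, dtype=float)
    if prev is None:
        return [prediction.copy() for _ in range(state.particle_count)]
    prev = np.asarray(prev, dtype=float)
    if state.particle_count == 1:
        alphas = np.array([1.0])
    else:
        alphas = np.linspace(0.5, 1.0, state.particle_count)
    noise = state.rng.normal(0.0, state.noise_sigma, size=(state.particle_count, 2))
    return [
        a * prediction + (1.0 - a) * prev + noise[k]
        for k, a in enumerate(alphas)
    ]


def consistency_select(
    particles: Sequence[np.ndarray], prev: np.ndarray
) -> Tuple[np.ndarray, int]:
    """Pick the particle nearest (Euclidean) to the previous position."""
    if len(particles) == 0:
        raise ValueError("no particles")
    prev = np.asarray(prev, dtype=float)
    dists = [float(np.linalg.norm(np.asarray(p, float) - prev)) for p in particles]
    idx = int(np.argmin(dists))  # ties resolve to the lowest index
    return np.asarray(particles[idx], dtype=float), idx


def eye_open(landmarks: np.ndarray, threshold: float = 0.12) -> bool:
    """Eye-aspect-ratio openness test on the 6-point eye landmarks.

    EAR = (|u0 - l0| + |u1 - l1|) / (2 |c0 - c1|); the eye counts as open
    when EAR >= threshold.
    """
    lm = np.asarray(landmarks, dtype=float)
    if lm.shape != (6, 2):
        raise ValueError("expected 6 landmarks of 2 coordinates")
    corner = float(np.linalg.norm(lm[1] - lm[0]))
    if corner < 1e-9:
        raise ValueError("degenerate corner distance")
    gap = float(np.linalg.norm(lm[2] - lm[4]) + np.linalg.norm(lm[3] - lm[5]))
    return gap / (2.0 * corner) >= threshold


def make_predictor(
    model: Union[CascadeModel, RuleSet, Callable]
) -> Callable[[np.ndarray, np.ndarray, np.ndarray, bool], np.ndarray]:
    """Uniform per-eye prediction callable over cascade, rule set, or function."""
    if isinstance(model, CascadeModel):
        return lambda image, lm0, lm1, mirror: predict_cascade(
            model, image, lm0, lm1, mirror=mirror
        )
    if isinstance(model, RuleSet):
        return lambda image, lm0, lm1, mirror: predict_ruleset(
            model, image, lm0, lm1, mirror=mirror
        )
    if callable(model):
        return model
    raise TypeError(f"cannot build a predictor from {type(model)!r}")


def track_frame(
    model: Union[CascadeModel, RuleSet, Callable],
    image: np.ndarray,
    annotation: EyeAnnotation,
    states: Dict[str, TrackState],
) -> Dict[str, FrameResult]:
    """Advance both per-eye trackers by one frame.

    ``states`` maps ``"left"``/``"right"`` to their :class:`TrackState`; the
    previous positions inside are updated in place.
    """
    predictor = make_predictor(model)
    mirrored = getattr(model, "mirrored_right", False)
    results: Dict[str, FrameResult] = {}
    for name, obs, mirror in (
        ("left", annotation.left, False),
        ("right", annotation.right, mirrored),
    ):
        state = states[name]
        is_open = eye_open(obs.landmarks) if obs.landmarks is not None else True
        if state.prev_position is not None and not is_open:
            pos = state.prev_position.copy()
            results[name] = FrameResult(
                position=pos, particles=[pos], selected_index=0, eye_open=False
            )
            continue
        prediction = predictor(image, obs.lm0, obs.lm1, mirror)
        if state.prev_position is None:
            pos, idx = np.asarray(prediction, float), 0
            particles = [pos]
        else:
            particles = propagate_particles(prediction, state.prev_position, state)
            pos, idx = consistency_select(particles, state.prev_position)
        state.prev_position = pos.copy()
        results[name] = FrameResult(
            position=pos, particles=particles, selected_index=idx, eye_open=is_open
        )
    return results


def track_sequence(
    model: Union[CascadeModel, RuleSet, Callable],
    images: Sequence[np.ndarray],
    annotations: Sequence[EyeAnnotation],
    particle_count: int = 3,
    noise_sigma: float = 2.0,
    seed: int = 0,
) -> List[Dict[str, FrameResult]]:
    """Track both eyes across an ordered frame sequence."""
    ss = np.random.SeedSequence(seed)
    left_ss, right_ss = ss.spawn(2)
    states = {
        "left": TrackState(particle_count, noise_sigma, np.random.default_rng(left_ss)),
        "right": TrackState(particle_count, noise_sigma, np.random.default_rng(right_ss)),
    }
    return [
        track_frame(model, img, ann, states)
        for img, ann in zip(images, annotations)
    ]


def write_track_csv(path: str, results: Sequence[Dict[str, FrameResult]]) -> None:
    """Per-frame CSV: frame, eye, x, y, eye_open, selected_index."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "eye", "x", "y", "eye_open", "selected_index"])
        for i, frame in enumerate(results):
            for eye in ("left", "right"):
                r = frame[eye]
                writer.writerow(
                    [i, eye, repr(float(r.position[0])), repr(float(r.position[1])),
                     int(r.eye_open), r.selected_index]
                )
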