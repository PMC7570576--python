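"""Annotation-table I/O.

The manifest is a UTF-8 TSV with one row per image.  Core columns:

    image_path,
    lm0x_L lm0y_L lm1x_L lm1y_L gtx_L gty_L,
    lm0x_R lm0y_R lm1x_R lm1y_R gtx_R gty_R

Optionally followed by the four non-corner eyelid landmarks per eye (eight
extra coordinate columns per eye), which the tracker's eye-openness test
needs.  Lines starting with ``#`` are comments; the writer emits one naming
the columns.  Floats are written with ``repr`` so a rewrite round-trips
byte-identically.
"""

from __future__ import annotations

import os
from typing import List, Optional, Sequence

import numpy as np

from .cascade import EyeAnnotation, EyeObservation

__all__ = ["write_annotations", "read_annotations", "load_images"]

_CORE = [
    "lm0x", "lm0y", "lm1x", "lm1y", "gtx", "gty",
]
_LIDS = ["u0x", "u0y", "u1x", "u1y", "l0x", "l0y", "l1x", "l1y"]


def _eye_fields(obs: EyeObservation, with_landmarks: bool) -> List[float]:
    vals = [*obs.lm0, *obs.lm1, *obs.gt]
    if with_landmarks:
        if obs.landmarks is None:
            raise ValueError("annotation lacks the 6-point landmarks")
        vals.extend(obs.landmarks[2:].ravel())
    return [float(v) for v in vals]


def write_annotations(
    path: str, annotations: Sequence[EyeAnnotation], with_landmarks: bool = True
) -> None:
    names = ["image_path"]
    cols = _CORE + (_LIDS if with_landmarks else [])
    for eye in ("L", "R"):
        names.extend(f"{c}_{eye}" for c in cols)
    lines = ["# " + "\t".join(names)]
    for ann in annotations:
        row = [ann.image_path]
        row.extend(repr(v) for v in _eye_fields(ann.left, with_landmarks))
        row.extend(repr(v) for v in _eye_fields(ann.right, with_landmarks))
        lines.append("\t".join(row))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_eye(fields: List[float], with_landmarks: bool) -> EyeObservation:
    lm0 = np.array(fields[0:2])
    lm1 = np.array(fields[2:4])
    gt = np.array(fields[4:6])
    landmarks = None
    if with_landmarks:
        lids = np.array(fields[6:14]).reshape(4, 2)
        landmarks = np.vstack([lm0, lm1, lids])
    return EyeObservation(lm0=lm0, lm1=lm1, gt=gt, landmarks=landmarks)


def read_annotations(path: str) -> List[EyeAnnotation]:
    annotations = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            values = [float(v) for v in parts[1:]]
            per_eye = len(values) // 2
            if per_eye not in (6, 14):
                raise ValueError(
                    f"unexpected column count {len(parts)} in {path!r}"
                )
            with_landmarks = per_eye == 14
            annotations.append(
                EyeAnnotation(
                    image_path=parts[0],
                    left=_parse_eye(values[:per_eye], with_landmarks),
                    right=_parse_eye(values[per_eye:], with_landmarks),
                )
            )
    return annotations


def load_images(annotations: Sequence[EyeAnnotation], root: str) -> List[np.ndarray]:
    """Load each annotation's image (gray float in [0, 1]) relative to root."""
    import imageio.v3 as iio

    images = []
    for ann in annotations:
        img = iio.imread(os.path.join(root, ann.image_path))
        img = np.asarray(img)
        if img.dtype == np.uint8:
            img = img / 255.0
        if img.ndim == 3:
            img = img[..., :3] @ np.array([0.299, 0.587, 0.114])
        images.append(np.asarray(img, dtype=float))
    return images
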