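"""Layered scene components consumed by every analysis stage.

A stimulus is represented not by a single image but by a set of aligned
layers produced by a renderer (or by :mod:`glossim.synthetic`):

``full``
    the composite linear-light RGB rendering,
``diffuse1``
    a diffuse-only rendering whose facing (along-normal) reflectivity is
    matched to that of the purely specular rendering — the reference used to
    split specular reflections into highlights and lowlights,
``diffuse2``
    the diffuse component of ``full`` itself, so that ``full - diffuse2``
    isolates the specular contribution,
``specular``
    the purely specular rendering,
``normals``
    camera-space unit surface normals (undefined off the object),
``mask``
    the binary object silhouette.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["SceneComponents", "luminance"]


def luminance(rgb: np.ndarray) -> np.ndarray:
    """Scalar luminance of a linear RGB image as the unweighted channel mean.

    The cue definitions operate on plain RGB images without a colorimetric
    weighting, and the stimuli include strongly coloured single channels, so
    an equal-weight mean is used throughout.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim == 2:
        return rgb
    return rgb.mean(axis=-1)


@dataclass
class SceneComponents:
    """Aligned linear-light image layers of one stimulus.

    On the object mask ``full == diffuse2 + specular`` (exactly for
    synthesized scenes, within a tolerance for layers read from files) and
    normals have unit length.
    """

    full: np.ndarray
    diffuse1: np.ndarray
    diffuse2: np.ndarray
    specular: np.ndarray
    normals: np.ndarray
    mask: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.full = np.asarray(self.full, dtype=float)
        self.diffuse1 = np.asarray(self.diffuse1, dtype=float)
        self.diffuse2 = np.asarray(self.diffuse2, dtype=float)
        self.specular = np.asarray(self.specular, dtype=float)
        self.normals = np.asarray(self.normals, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        self.validate()

    @property
    def shape(self) -> tuple[int, int]:
        return self.full.shape[:2]

    def validate(self, normal_tol: float = 1e-3) -> None:
        """Check layer shapes, image non-negativity and unit normals."""
        h, w = self.full.shape[:2]
        for name in ("full", "diffuse1", "diffuse2", "specular"):
            img = getattr(self, name)
            if img.ndim != 3 or img.shape[:2] != (h, w) or img.shape[2] != 3:
                raise ValueError(
                    f"layer {name!r} must be an H×W×3 image matching 'full' "
                    f"({h}×{w}), got shape {img.shape}"
                )
            if np.any(img < 0) or not np.all(np.isfinite(img)):
                raise ValueError(f"layer {name!r} must be finite and non-negative")
        if self.normals.shape != (h, w, 3):
            raise ValueError(
                f"layer 'normals' must have shape ({h}, {w}, 3), got {self.normals.shape}"
            )
        if self.mask.shape != (h, w):
            raise ValueError(
                f"layer 'mask' must have shape ({h}, {w}), got {self.mask.shape}"
            )
        if self.mask.any():
            norms = np.linalg.norm(self.normals[self.mask], axis=-1)
            if np.any(np.abs(norms - 1.0) > normal_tol):
                raise ValueError(
                    "layer 'normals' must be unit length on the object mask "
                    f"(max deviation {np.abs(norms - 1.0).max():.2e})"
                )

    def additivity_error(self) -> float:
        """Max abs deviation of ``full - (diffuse2 + specular)`` on the mask."""
        diff = self.full - (self.diffuse2 + self.specular)
        if not self.mask.any():
            return 0.0
        return float(np.abs(diff[self.mask]).max())
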