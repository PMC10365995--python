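"""Appearance-transfer filters: compositing manipulations of render layers.

A manipulated stimulus is produced from layered components by a fixed
pipeline: the specular component is isolated by subtracting the diffuse
component from the full rendering; its sharpness is reduced with a
cross-bilateral blur guided by surface normals; an optional velvet filter
non-monotonically remaps specular luminance; each component is optionally
multiplied by a colour; intensity and saturation of each component are
adjusted in HSV space; and the components are re-added.

The normal-guided blur weights each neighbour inside a box kernel by
``clamp(n·n0, 0, 1)**s`` — a Phong-like angular falloff — with the kernel
renormalized to unit weight over contributing object pixels.  The blur
parameter ``b`` in [0, 1] is remapped to the shininess exponent by
``s = 1 + 1/((b/5)**4 * 100 + eps)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage import color as skcolor

from .scene import SceneComponents, luminance

__all__ = [
    "ManipulationRecipe",
    "shininess_from_blur",
    "normal_blur",
    "colorize",
    "adjust_hsv",
    "smoothstep",
    "velvet_filter",
    "apply_recipe",
    "default_kernel_extent",
    "builtin_recipe",
    "load_recipe",
    "save_recipe",
]

#: Box-kernel side (pixels) of the normal-guided blur at a 1080-px frame;
#: scaled proportionally for other frame widths.
KERNEL_EXTENT_AT_1080 = 160


def default_kernel_extent(width: int) -> int:
    """Blur kernel side for a frame of the given width (odd, >= 3)."""
    extent = max(3, round(KERNEL_EXTENT_AT_1080 * width / 1080))
    return extent | 1


@dataclass(frozen=True)
class ManipulationRecipe:
    """Parameters of one material manipulation.

    ``s_col`` / ``d_col`` multiply the specular / diffuse component
    (``d_col=(0,0,0)`` discards the diffuse layer, as for bare metals);
    ``*_gamma`` and ``*_boost`` shape the HSV value channel via
    ``boost * v**gamma``; ``*_sat`` multiplies HSV saturation.  ``velvet``
    enables the highlight-core darkening filter with scene highlight
    direction ``nm``.
    """

    b: float = 0.0
    epsilon: float = 1e-6
    s_col: tuple[float, float, float] | None = None
    d_col: tuple[float, float, float] | None = None
    s_gamma: float = 1.0
    d_gamma: float = 1.0
    s_boost: float = 1.0
    d_boost: float = 1.0
    s_sat: float = 1.0
    d_sat: float = 1.0
    velvet: bool = False
    nm: tuple[float, float, float] = (0.0, 0.0, 1.0)
    kernel_extent: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.b:
            raise ValueError(f"blur parameter b must be >= 0, got {self.b}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        for nm_, g in (("s_gamma", self.s_gamma), ("d_gamma", self.d_gamma)):
            if g <= 0:
                raise ValueError(f"{nm_} must be > 0, got {g}")
        for nm_, v in (("s_boost", self.s_boost), ("d_boost", self.d_boost),
                       ("s_sat", self.s_sat), ("d_sat", self.d_sat)):
            if v < 0 or not np.isfinite(v):
                raise ValueError(f"{nm_} must be finite and >= 0, got {v}")
        for nm_, c in (("s_col", self.s_col), ("d_col", self.d_col)):
            if c is not None and any(x < 0 for x in c):
                raise ValueError(f"{nm_} must be non-negative, got {c}")
        if self.velvet:
            n = np.linalg.norm(self.nm)
            if abs(n - 1.0) > 1e-6:
                raise ValueError(f"nm must be unit length when velvet is set, |nm|={n}")


def shininess_from_blur(b: float, epsilon: float = 1e-6) -> float:
    """Remap the blur parameter b to the Phong-like shininess exponent.

    ``s = 1 + 1/((b/5)**4 * 100 + eps)``: b → 0 gives a huge exponent (no
    blur); b = 5 gives s ≈ 1.01 (very broad angular filter).
    """
    if b < 0:
        raise ValueError(f"b must be >= 0, got {b}")
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    return 1.0 + 1.0 / ((b / 5.0) ** 4 * 100.0 + epsilon)


def normal_blur(specular: np.ndarray, normals: np.ndarray, mask: np.ndarray,
                shininess: float, kernel_extent: int) -> np.ndarray:
    """Cross-bilateral blur of the specular layer guided by surface normals.

    Each output pixel is the weighted mean of the specular values of object
    pixels inside a ``kernel_extent`` box, with weight
    ``clamp(n·n0, 0, 1)**shininess`` (n0 = centre normal); weights are
    renormalized to sum to one over contributing pixels, so a constant image
    is preserved exactly.  Background pixels neither contribute nor change.
    """
    specular = np.asarray(specular, dtype=float)
    normals = np.asarray(normals, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if kernel_extent < 1:
        raise ValueError(f"kernel_extent must be >= 1, got {kernel_extent}")
    r = int(kernel_extent) // 2
    h, w = mask.shape
    spec_m = np.where(mask[..., None], specular, 0.0)
    norm_m = np.where(mask[..., None], normals, 0.0)

    pad = ((r, r), (r, r), (0, 0))
    spec_p = np.pad(spec_m, pad)
    norm_p = np.pad(norm_m, pad)
    mask_p = np.pad(mask, ((r, r), (r, r)))

    accum = np.zeros_like(spec_m)
    wsum = np.zeros((h, w))
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            sl = (slice(r + dy, r + dy + h), slice(r + dx, r + dx + w))
            nb_mask = mask_p[sl]
            ndot = np.einsum("ijk,ijk->ij", norm_p[sl], norm_m)
            wgt = np.clip(ndot, 0.0, 1.0) ** shininess * nb_mask
            accum += wgt[..., None] * spec_p[sl]
            wsum += wgt
    out = np.where((wsum > 0)[..., None], accum / np.maximum(wsum, 1e-300)[..., None],
                   spec_m)
    return np.where(mask[..., None], out, specular)


def colorize(component: np.ndarray, col) -> np.ndarray:
    """Multiply an image component per channel by a colour."""
    col = np.asarray(col, dtype=float)
    if np.any(col < 0):
        raise ValueError(f"colour must be non-negative, got {col}")
    return np.asarray(component, dtype=float) * col


def adjust_hsv(component: np.ndarray, gamma: float = 1.0, boost: float = 1.0,
               sat: float = 1.0) -> np.ndarray:
    """Adjust intensity and saturation of a component in HSV space.

    ``v' = boost * v**gamma``; ``s' = clamp(sat * s, 0, 1)``; hue unchanged.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    component = np.asarray(component, dtype=float)
    if np.any(component < 0):
        raise ValueError("component must be non-negative")
    if gamma == 1.0 and boost == 1.0 and sat == 1.0:
        return component.copy()
    # HSV with V = max(R,G,B); values may exceed 1 in linear light, which the
    # max/min arithmetic handles without clipping.
    hsv = skcolor.rgb2hsv(component)
    hsv[..., 2] = boost * hsv[..., 2] ** gamma
    hsv[..., 1] = np.clip(sat * hsv[..., 1], 0.0, 1.0)
    return skcolor.hsv2rgb(hsv)


def smoothstep(a: float, b: float, x) -> np.ndarray | float:
    """GLSL smooth step: cubic ease 3t² − 2t³ of the clamped normalized input."""
    if not a < b:
        raise ValueError(f"smoothstep requires a < b, got a={a}, b={b}")
    t = np.clip((np.asarray(x, dtype=float) - a) / (b - a), 0.0, 1.0)
    out = t * t * (3.0 - 2.0 * t)
    return float(out) if np.isscalar(x) else out


def velvet_filter(specular_blurred: np.ndarray, normals: np.ndarray,
                  mask: np.ndarray, nm) -> np.ndarray:
    """Darken the cores of the brightest highlights (velvet/satin look).

    The specular component is multiplied by two masks: ``m1``, a
    non-monotonic luminance remap that rises smoothly from 0 to 1 at half
    the maximum luminance ``lm`` and falls back to 0 at ``lm`` (producing
    elongated highlight loops), and ``m2 = clamp(n·nm, 0, 1)``, which
    attenuates highlights away from the scene's main highlight direction.
    An all-zero specular layer is returned unchanged.
    """
    specular_blurred = np.asarray(specular_blurred, dtype=float)
    nm = np.asarray(nm, dtype=float)
    if abs(np.linalg.norm(nm) - 1.0) > 1e-6:
        raise ValueError("nm must be a unit vector")
    mask = np.asarray(mask).astype(bool)
    lum = luminance(specular_blurred)
    lm = float(lum[mask].max()) if mask.any() else 0.0
    if lm == 0.0:
        return specular_blurred.copy()
    rising = smoothstep(0.0, lm / 2.0, lum)
    falling = 1.0 - smoothstep(lm / 2.0, lm, lum)
    m1 = np.where(lum < lm / 2.0, rising, falling)
    m2 = np.clip(np.einsum("ijk,k->ij", np.asarray(normals, dtype=float), nm),
                 0.0, 1.0)
    return specular_blurred * (m1 * m2)[..., None]


def apply_recipe(scene: SceneComponents, recipe: ManipulationRecipe) -> np.ndarray:
    """Run the full manipulation pipeline on one scene.

    Order: specular := full − diffuse2 (clamped); normal-guided blur;
    optional velvet filter; per-component colourization; per-component HSV
    adjustment; recomposition by addition.  The identity recipe reproduces
    the full rendering.
    """
    specular = np.maximum(scene.full - scene.diffuse2, 0.0)
    diffuse = scene.diffuse2.copy()

    if recipe.b > 0:
        s = shininess_from_blur(recipe.b, recipe.epsilon)
        extent = recipe.kernel_extent or default_kernel_extent(scene.shape[1])
        specular = normal_blur(specular, scene.normals, scene.mask,
                               shininess=s, kernel_extent=extent)
    if recipe.velvet:
        specular = velvet_filter(specular, scene.normals, scene.mask, recipe.nm)
    if recipe.s_col is not None:
        specular = colorize(specular, recipe.s_col)
    if recipe.d_col is not None:
        diffuse = colorize(diffuse, recipe.d_col)
    specular = adjust_hsv(specular, recipe.s_gamma, recipe.s_boost, recipe.s_sat)
    diffuse = adjust_hsv(diffuse, recipe.d_gamma, recipe.d_boost, recipe.d_sat)
    return np.maximum(specular + diffuse, 0.0)


def builtin_recipe(material: str, scene: str | None = None) -> ManipulationRecipe:
    """Load a shipped default recipe for a target material.

    The presets are editable, invented defaults (JSON in the package's
    ``data`` directory), meant as starting points for appearance transfer
    from a glazed-ceramic source stimulus.  The velvet recipe needs the
    scene's main highlight direction: pass ``scene`` as ``"shape|light"``
    (e.g. ``"bunny|campus"``); the stored direction is normalized to unit
    length.
    """
    data = json.loads(
        (Path(__file__).parent / "data" / "recipes.json").read_text())
    try:
        d = dict(data["recipes"][material])
    except KeyError:
        raise KeyError(f"unknown recipe {material!r}; "
                       f"available: {sorted(data['recipes'])}") from None
    for key in ("s_col", "d_col"):
        if key in d:
            d[key] = tuple(d[key])
    if d.get("velvet"):
        if scene is None:
            raise ValueError("the velvet recipe needs scene='shape|light' "
                             "to select its highlight direction nm")
        nm = np.asarray(data["velvet_nm"][scene], dtype=float)
        d["nm"] = tuple(nm / np.linalg.norm(nm))
    return ManipulationRecipe(name=material, **d)


def save_recipe(recipe: ManipulationRecipe, path) -> None:
    d = asdict(recipe)
    Path(path).write_text(json.dumps(d, indent=2))


def load_recipe(path) -> ManipulationRecipe:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recipe file not found: {path}")
    d = json.loads(path.read_text())
    for key in ("s_col", "d_col", "nm"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    return ManipulationRecipe(**d)
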