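"""Synthetic layered scenes and simulated observers with known ground truth.

The scene generator is an analytic stand-in for a physically based renderer:
procedural heightfield geometry (a sphere, optionally perturbed by smooth
sinusoidal bumps) is shaded with a small set of directional lights plus an
ambient term, using Lambertian diffuse shading and a Blinn–Phong-style
specular lobe.  This gives exactly separable diffuse and specular layers,
closed-form unit normals, and full control over the generating parameters —
which is the point: every downstream measurement can be checked against the
parameters that produced the image.

The mapping from the abstract design parameters to the shading model:

* ``specular_level`` scales the facing specular reflectance linearly
  (level × 8 %), so the specular layer is exactly linear in the level.
* ``roughness`` widens the specular lobe (exponent ``2 / (roughness+0.02)²``)
  and adds an isotropic Gaussian blur of the specular layer with
  ``sigma = roughness × width/32`` pixels; both effects are strictly
  monotone in roughness.
* ``anisotropic`` adds a directional Gaussian blur of the specular layer
  along an image-space axis rotated by ``aniso_rotation × 360°``,
  emulating elongated brushed-metal highlights.
* ``specular_tint`` interpolates the specular colour from white towards the
  hue of the base colour.

Observer simulators produce forced-choice confidence tables from a known
latent factor structure (softmax choice via the Gumbel-max trick) and gloss
ratings as a noisy clipped linear combination of the three gloss cues, so
the statistics stage can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .design import StimulusParams, specular_to_reflectance
from .scene import SceneComponents, luminance

__all__ = [
    "ShapeSpec",
    "LightSpec",
    "ObserverModel",
    "synth_scene",
    "simulate_categorical_responses",
    "simulate_gloss_ratings",
    "BUILTIN_SHAPES",
    "BUILTIN_LIGHTS",
]


@dataclass(frozen=True)
class ShapeSpec:
    """Procedural heightfield geometry: a sphere plus sinusoidal bumps.

    ``n_bumps`` sinusoidal products with frequencies up to ``bump_freq``
    (cycles per object diameter) and amplitude ``bump_amp`` (fraction of the
    sphere radius) are added to the spherical height; their frequencies and
    phases are drawn deterministically from the scene seed.
    """

    name: str
    n_bumps: int = 0
    bump_amp: float = 0.0
    bump_freq: float = 4.0
    radius: float = 0.92  # fraction of the half-width


#: Procedural stand-ins for the two scanned meshes: the "dragon" has dense
#: high-frequency relief, the "bunny" fewer, smoother lobes.
BUILTIN_SHAPES = {
    "sphere": ShapeSpec("sphere"),
    "dragon": ShapeSpec("dragon", n_bumps=10, bump_amp=0.06, bump_freq=6.0),
    "bunny": ShapeSpec("bunny", n_bumps=4, bump_amp=0.10, bump_freq=2.5),
}


@dataclass(frozen=True)
class LightSpec:
    """Directional lights plus an extended mirror environment.

    ``directions/intensities/colours`` define point-like sources that drive
    diffuse shading and narrow specular lobes.  ``env_patches`` are
    hard-edged bright regions of the surrounding environment (windows, sky),
    each ``(direction, cos_threshold, intensity)``: a patch contributes to
    the specular layer wherever the mirror reflection vector falls inside
    its cone.  They give the mirror image the extended, sharp-edged
    structure that real light probes produce.
    """

    name: str
    directions: tuple[tuple[float, float, float], ...]
    intensities: tuple[float, ...]
    colours: tuple[tuple[float, float, float], ...]
    ambient: float = 0.3
    env_patches: tuple[tuple[tuple[float, float, float], float, float], ...] = ()


BUILTIN_LIGHTS = {
    # Indoor-like: one dominant warm source high in front, two fill lights,
    # a large window patch and a smaller lamp patch in the mirror image.
    "kitchen": LightSpec(
        "kitchen",
        directions=((0.35, 0.45, 0.82), (-0.55, 0.15, 0.82), (0.6, -0.5, 0.63)),
        intensities=(1.0, 0.45, 0.25),
        colours=((1.0, 0.96, 0.88),) * 3,
        ambient=0.30,
        env_patches=(((0.4, 0.5, 0.77), 0.88, 3.0),
                     ((-0.6, 0.1, 0.79), 0.965, 2.2),
                     ((0.2, -0.65, 0.73), 0.93, 1.2)),
    ),
    # Outdoor-like: stronger key light, cooler tint, higher ambient, a wide
    # sky patch and a narrow sun patch.
    "campus": LightSpec(
        "campus",
        directions=((-0.25, 0.6, 0.76), (0.7, 0.1, 0.71)),
        intensities=(1.3, 0.35),
        colours=((0.92, 0.96, 1.04),) * 2,
        ambient=0.40,
        env_patches=(((0.0, 0.75, 0.66), 0.80, 2.4),
                     ((-0.45, 0.35, 0.82), 0.985, 4.0),
                     ((0.55, -0.4, 0.73), 0.94, 1.0)),
    ),
}


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _heightfield(shape_spec: ShapeSpec, size: tuple[int, int],
                 rng: np.random.Generator):
    """Return mask, height z and analytic gradients (zx, zy) on a unit grid."""
    h, w = size
    y, x = np.mgrid[0:h, 0:w]
    # Map to [-1, 1] with y up.
    x = (x - (w - 1) / 2) / ((w - 1) / 2)
    y = -(y - (h - 1) / 2) / ((h - 1) / 2)
    r = shape_spec.radius
    rr = x**2 + y**2
    mask = rr < r**2
    z = np.sqrt(np.maximum(r**2 - rr, 1e-6))
    zx = -x / z
    zy = -y / z
    for _ in range(shape_spec.n_bumps):
        fx, fy = rng.uniform(0.5, shape_spec.bump_freq, size=2)
        px, py = rng.uniform(0, 2 * np.pi, size=2)
        amp = shape_spec.bump_amp * r * rng.uniform(0.5, 1.0)
        sx, cx = np.sin(2 * np.pi * fx * x + px), np.cos(2 * np.pi * fx * x + px)
        sy, cy = np.sin(2 * np.pi * fy * y + py), np.cos(2 * np.pi * fy * y + py)
        z = z + amp * sx * sy
        zx = zx + amp * 2 * np.pi * fx * cx * sy
        zy = zy + amp * 2 * np.pi * fy * sx * cy
    return mask, z, zx, zy


def _normals_from_gradients(zx: np.ndarray, zy: np.ndarray) -> np.ndarray:
    n = np.stack([-zx, -zy, np.ones_like(zx)], axis=-1)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    return n


def _directional_blur(img: np.ndarray, sigma: float, angle_deg: float) -> np.ndarray:
    """Gaussian blur along one image-space direction (per channel)."""
    if sigma <= 0:
        return img
    if angle_deg % 180 == 0:
        return ndimage.gaussian_filter1d(img, sigma, axis=1)
    if angle_deg % 90 == 0:
        return ndimage.gaussian_filter1d(img, sigma, axis=0)
    out = np.empty_like(img)
    for c in range(img.shape[-1]):
        rot = ndimage.rotate(img[..., c], angle_deg, reshape=False, order=1,
                             mode="nearest")
        rot = ndimage.gaussian_filter1d(rot, sigma, axis=1)
        out[..., c] = ndimage.rotate(rot, -angle_deg, reshape=False, order=1,
                                     mode="nearest")
    return out


def _resolve_shape(shape_spec) -> ShapeSpec:
    if isinstance(shape_spec, ShapeSpec):
        return shape_spec
    try:
        return BUILTIN_SHAPES[shape_spec]
    except KeyError:
        raise ValueError(
            f"shape: unknown shape id {shape_spec!r}; "
            f"available: {sorted(BUILTIN_SHAPES)}"
        ) from None


def _resolve_light(light_spec) -> LightSpec:
    if isinstance(light_spec, LightSpec):
        return light_spec
    try:
        return BUILTIN_LIGHTS[light_spec]
    except KeyError:
        raise ValueError(
            f"light_field: unknown light field id {light_spec!r}; "
            f"available: {sorted(BUILTIN_LIGHTS)}"
        ) from None


def synth_scene(params: StimulusParams, shape_spec=None, light_spec=None,
                size: tuple[int, int] = (256, 256), seed: int = 0) -> SceneComponents:
    """Synthesize the layered components of one stimulus.

    Parameters
    ----------
    params
        The design cell to render.  ``params.shape`` / ``params.light_field``
        select built-in procedural geometry and lighting unless explicit
        ``shape_spec`` / ``light_spec`` objects are given.
    size
        Output (height, width); at least 64×64.
    seed
        Controls the deterministic bump layout of procedural geometry.  The
        generator is a pure function of ``(params, specs, size, seed)``.

    Returns
    -------
    SceneComponents
        With ``full == diffuse2 + specular`` exactly, and ``diffuse1`` a
        grey diffuse-only shading whose facing reflectivity equals the
        facing reflectivity of the specular layer.
    """
    if not isinstance(params, StimulusParams):
        params = StimulusParams(**params)
    h, w = size
    if h < 64 or w < 64:
        raise ValueError(f"size must be at least 64×64, got {size}")
    shape = _resolve_shape(shape_spec if shape_spec is not None else params.shape)
    light = _resolve_light(light_spec if light_spec is not None else params.light_field)

    rng = np.random.default_rng(seed)
    mask, _z, zx, zy = _heightfield(shape, (h, w), rng)
    normals = _normals_from_gradients(zx, zy)

    view = np.array([0.0, 0.0, 1.0])
    base_rgb = np.asarray(params.base_rgb, dtype=float)

    # Diffuse shading factor (shared by diffuse2 and diffuse1), per channel.
    shading = np.full((h, w, 3), light.ambient)
    spec_irradiance = np.zeros((h, w, 3))
    # Lobe exponent: strictly decreasing in roughness (wider lobe).
    exponent = 2.0 / (params.roughness + 0.02) ** 2
    for d, inten, col in zip(light.directions, light.intensities, light.colours):
        ldir = _normalize(np.asarray(d, dtype=float))
        ndotl = np.clip(normals @ ldir, 0.0, None)
        shading += inten * ndotl[..., None] * np.asarray(col)
        half = _normalize(ldir + view)
        ndoth = np.clip(normals @ half, 0.0, None)
        # Energy-normalized lobe: the (p+2)/2 factor keeps the hemisphere-
        # integrated specular energy on the Lambertian scale, so sharp lobes
        # concentrate the same light into bright narrow highlights.
        lobe = (exponent + 2.0) / 2.0 * ndoth**exponent
        spec_irradiance += inten * lobe[..., None] * np.asarray(col)
    # Mirror reflection of extended environment patches (R = reflection of
    # the view direction about the normal; v = +z).
    refl = np.stack([2 * normals[..., 2] * normals[..., 0],
                     2 * normals[..., 2] * normals[..., 1],
                     2 * normals[..., 2] ** 2 - 1], axis=-1)
    if light.env_patches:
        env = np.zeros(refl.shape[:2])
        for d, cos_thr, inten in light.env_patches:
            pdir = _normalize(np.asarray(d, dtype=float))
            env += inten * ((refl @ pdir) > cos_thr)
        # Mid-frequency ripple gives the mirror image structure at several
        # scales (real light probes are textured, not flat), so blur acts on
        # interior detail as well as on patch edges.
        u1 = _normalize(np.array([1.0, 0.3, -0.2]))
        u2 = _normalize(np.array([-0.2, 1.0, 0.4]))
        ripple = (1.0 + 0.35 * np.sin(14.0 * refl @ u1)
                  * np.sin(11.0 * refl @ u2))
        spec_irradiance += (env * ripple)[..., None]

    diffuse2 = base_rgb * shading

    # Facing specular reflectance: linear in the specular level (0–8 % per
    # unit level, extrapolated above 1).
    rho = specular_to_reflectance(params.specular_level) / 100.0
    if params.specular_tint > 0 and base_rgb.max() > 0:
        hue = base_rgb / base_rgb.max()
        spec_colour = (1 - params.specular_tint) + params.specular_tint * hue
    else:
        spec_colour = np.ones(3)
    specular = rho * spec_colour * spec_irradiance

    # Microroughness scatters the reflected environment: isotropic blur.
    # A small constant term anti-aliases the hard-edged mirror image at
    # zero roughness (the analytic shading is not band-limited).
    sigma_r = np.hypot(0.6 * w / 256.0, params.roughness * w / 32.0)
    specular = ndimage.gaussian_filter(specular, (sigma_r, sigma_r, 0))
    # Anisotropy elongates highlights along an image-space direction.
    sigma_a = params.anisotropic * w / 16.0
    if sigma_a > 0:
        specular = _directional_blur(specular, sigma_a, params.aniso_rotation * 360.0)

    m3 = mask[..., None]
    specular = np.where(m3, specular, 0.0)
    diffuse2 = np.where(m3, diffuse2, 0.0)
    full = diffuse2 + specular

    # Diffuse-only reference matched to the facing specular reflectivity:
    # a grey Lambertian surface with albedo rho under the same lights.
    diffuse1 = np.where(m3, rho * shading, 0.0)

    meta = {
        "shape": shape.name,
        "light_field": light.name,
        "size": [h, w],
        "seed": int(seed),
        "params": params.to_dict(),
    }
    return SceneComponents(full=full, diffuse1=diffuse1, diffuse2=diffuse2,
                           specular=specular, normals=normals, mask=mask, meta=meta)


# ---------------------------------------------------------------------------
# Simulated observers


def make_observer_loadings(n_categories: int, n_factors: int,
                           seed: int = 0) -> np.ndarray:
    """Simple-structure category loadings for the simulated 18-AFC observer.

    Each category loads strongly (0.7–0.95) on one factor, assigned round
    robin, plus one small random cross loading — the kind of structure real
    category terms show when several terms name the same latent material
    dimension.  Simple structure keeps the factor model identifiable up to
    sign and permutation, which is what makes recovery testable.
    """
    rng = np.random.default_rng(seed)
    L = np.zeros((n_categories, n_factors))
    for i in range(n_categories):
        L[i, i % n_factors] = rng.uniform(0.7, 0.95)
        L[i, rng.integers(0, n_factors)] += rng.uniform(0.0, 0.15)
    return L


@dataclass(frozen=True)
class ObserverModel:
    """Generating parameters for simulated forced-choice and rating observers.

    ``loadings`` (categories × factors) defines the latent factor structure
    behind category choices; ``temperature`` scales choice stochasticity
    (→ 0 gives the argmax category).  ``confidence_thresholds`` map the
    affinity margin of the chosen category onto the 1–3 confidence scale;
    ``None`` uses terciles of the sampled margins.  Gloss ratings are
    ``clip(w·(coverage, √contrast, √sharpness) + intercept + bias_p + ε, 0, 1)``.
    """

    loadings: np.ndarray | None = None
    temperature: float = 1.0
    confidence_thresholds: tuple[float, float] | None = None
    gloss_weights: tuple[float, float, float] = (0.8, 0.5, 0.4)
    gloss_intercept: float = 0.1
    rating_noise_sd: float = 0.05
    participant_bias_sd: float = 0.05
    categories: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")
        if self.rating_noise_sd < 0 or self.participant_bias_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.confidence_thresholds is not None:
            t1, t2 = self.confidence_thresholds
            if not t1 < t2:
                raise ValueError(
                    f"confidence thresholds must be strictly increasing, got {t1}, {t2}"
                )


def _category_labels(model: ObserverModel, n_cat: int) -> list[str]:
    if model.categories is not None:
        if len(model.categories) != n_cat:
            raise ValueError("number of category labels does not match loadings")
        return list(model.categories)
    return [f"cat{i:02d}" for i in range(n_cat)]


def simulate_categorical_responses(scores: np.ndarray, model: ObserverModel,
                                   n_participants: int,
                                   seed: int | None = None) -> pd.DataFrame:
    """Simulate an n-AFC task with confidence from a latent factor structure.

    Each (participant, stimulus) choice is sampled from a softmax over the
    category affinities ``loadings @ score`` at the model temperature
    (Gumbel-max sampling).  Confidence in {1, 2, 3} is derived from the
    affinity margin of the chosen category over the best alternative.

    Returns a long table with columns
    ``participant, stimulus, category, confidence``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be a stimuli × factors matrix")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if n_participants < 1:
        raise ValueError(f"n_participants must be >= 1, got {n_participants}")
    if model.loadings is None:
        raise ValueError("model.loadings is required for categorical simulation")
    loadings = np.asarray(model.loadings, dtype=float)
    if loadings.shape[1] != scores.shape[1]:
        raise ValueError(
            f"loadings have {loadings.shape[1]} factors but scores have {scores.shape[1]}"
        )
    n_stim, _ = scores.shape
    n_cat = loadings.shape[0]
    labels = _category_labels(model, n_cat)
    rng = np.random.default_rng(model.seed if seed is None else seed)

    affinity = scores @ loadings.T  # (n_stim, n_cat)
    # Gumbel-max sampling == softmax(affinity / T) sampling.
    gumbel = rng.gumbel(size=(n_participants, n_stim, n_cat))
    choice = np.argmax(affinity[None] / model.temperature + gumbel, axis=-1)

    # Choice margin on the probability scale (decisiveness of the softmax):
    # probability of the chosen category minus the best alternative's, so
    # the margin → 1 for every choice in the deterministic limit.
    z = affinity / model.temperature
    z = z - z.max(axis=-1, keepdims=True)
    probs = np.exp(z)
    probs /= probs.sum(axis=-1, keepdims=True)
    probs_b = np.broadcast_to(probs[None], (n_participants, n_stim, n_cat))
    chosen_p = np.take_along_axis(probs_b, choice[..., None], axis=-1)[..., 0]
    masked = probs_b.copy()
    np.put_along_axis(masked, choice[..., None], -np.inf, axis=-1)
    margin = chosen_p - masked.max(axis=-1)

    if model.confidence_thresholds is not None:
        t1, t2 = model.confidence_thresholds
    else:
        t1, t2 = np.quantile(margin, [1 / 3, 2 / 3])
    confidence = 1 + (margin >= t1).astype(int) + (margin >= t2).astype(int)

    part, stim = np.meshgrid(np.arange(n_participants), np.arange(n_stim),
                             indexing="ij")
    return pd.DataFrame({
        "participant": part.ravel(),
        "stimulus": stim.ravel(),
        "category": [labels[c] for c in choice.ravel()],
        "confidence": confidence.ravel(),
    })


def simulate_gloss_ratings(features: pd.DataFrame, model: ObserverModel,
                           n_raters: int, seed: int | None = None
                           ) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate gloss ratings as a noisy linear combination of the gloss cues.

    ``features`` must contain columns ``coverage, contrast, sharpness``
    (contrast and sharpness on their root-transformed scale).  Each rater has
    a constant additive bias; each rating adds i.i.d. Gaussian noise and is
    clipped to [0, 1].

    Returns
    -------
    (ratings, mean_ratings)
        Long table ``participant, stimulus, rating`` and the per-stimulus
        mean rating indexed by stimulus.
    """
    if len(features) == 0:
        raise ValueError("feature table is empty")
    if n_raters < 1:
        raise ValueError(f"n_raters must be >= 1, got {n_raters}")
    cols = ["coverage", "contrast", "sharpness"]
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    X = features[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature table contains non-finite values")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    base = X @ np.asarray(model.gloss_weights, dtype=float) + model.gloss_intercept
    bias = rng.normal(0.0, model.participant_bias_sd, size=n_raters)
    noise = rng.normal(0.0, model.rating_noise_sd, size=(n_raters, len(base)))
    ratings = np.clip(base[None, :] + bias[:, None] + noise, 0.0, 1.0)
    part, stim = np.meshgrid(np.arange(n_raters), np.arange(len(base)),
                             indexing="ij")
    stim_labels = (features.index.to_numpy() if features.index.is_unique
                   else np.arange(len(base)))
    table = pd.DataFrame({
        "participant": part.ravel(),
        "stimulus": np.asarray(stim_labels)[stim.ravel()],
        "rating": ratings.ravel(),
    })
    mean = table.groupby("stimulus", sort=False)["rating"].mean()
    return table, mean
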