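"""Objective visual features of specular reflections.

Six image-computable cues summarize the appearance of a glossy object from
its layered render components:

* **coverage** — fraction of object pixels that are specular *highlights*,
  where highlights are segmented by thresholding the purely specular render
  minus a reflectivity-matched diffuse reference (``diffuse1``) at one third
  of the maximum diffuse shading;
* **contrast** — sum over spatial-frequency bands of the RMS of the
  specular residual (``full - diffuse2``), root-transformed;
* **sharpness** — mean local-phase-coherence index over highlight pixels,
  root-transformed;
* **highlight/lowlight saturation** and **lowlight value** — mean HSV
  saturation inside/outside the highlight region and mean HSV value in the
  lowlight region of the full image.

The root transform on contrast and sharpness linearizes their relationship
to rated glossiness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .scene import SceneComponents, luminance

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "HighlightSegmentation",
    "segment_highlights",
    "specular_residual",
    "coverage",
    "band_contrast",
    "sharpness_lpc",
    "colour_cues",
    "feature_vector",
    "feature_vector_manipulated",
    "FEATURE_COLUMNS",
]

log = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "coverage", "sharpness", "contrast",
    "highlight_saturation", "lowlight_saturation", "lowlight_value",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable measurement parameters.

    ``n_bands`` is the maximum number of octave-spaced difference-of-Gaussian
    bands for the contrast cue (fewer are used when the frame is small);
    ``band_sigma0`` the finest Gaussian scale in pixels; ``root_exponent``
    the exponent of the linearizing transform on contrast and sharpness
    (0.5 = square root); ``threshold_fraction`` the highlight threshold as a
    fraction of the maximum diffuse shading.  ``lpc_wavelength`` is the
    finest filter wavelength (pixels) of the phase-coherence sharpness
    measure.
    """

    n_bands: int = 5
    band_sigma0: float = 1.0
    root_exponent: float = 0.5
    threshold_fraction: float = 1.0 / 3.0
    lpc_wavelength: float = 6.0
    lpc_n_orient: int = 4


@dataclass
class HighlightSegmentation:
    """Partition of the object mask into highlight and lowlight regions."""

    subtracted: np.ndarray
    threshold: float
    highlight_mask: np.ndarray
    lowlight_mask: np.ndarray
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class FeatureVector:
    """The six cues for one stimulus, plus measurement bookkeeping."""

    coverage: float
    sharpness: float
    contrast: float
    highlight_saturation: float
    lowlight_saturation: float
    lowlight_value: float
    threshold: float = float("nan")
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["flags"] = ";".join(self.flags)
        return d


def segment_highlights(specular: np.ndarray, diffuse1: np.ndarray,
                       mask: np.ndarray,
                       threshold_fraction: float = 1.0 / 3.0) -> HighlightSegmentation:
    """Split the object into specular highlights and lowlights.

    The purely specular render minus the reflectivity-matched diffuse
    reference gives a *subtracted* luminance image; object pixels above a
    threshold set at ``threshold_fraction`` (default one third) of the
    maximum diffuse shading are highlights, the rest lowlights.
    """
    specular = np.asarray(specular, dtype=float)
    diffuse1 = np.asarray(diffuse1, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if specular.shape[:2] != diffuse1.shape[:2] or mask.shape != specular.shape[:2]:
        raise ValueError("specular, diffuse1 and mask must share H×W")
    if not mask.any():
        raise ValueError("object mask is empty")
    flags: list[str] = []
    lum_d1 = luminance(diffuse1)
    subtracted = luminance(specular) - lum_d1
    t = threshold_fraction * float(lum_d1[mask].max())
    if t == 0.0:
        flags.append("zero_diffuse1")
        log.warning("diffuse1 is all zero on the mask; threshold is 0 and every "
                    "positive subtracted pixel becomes a highlight")
    highlight = mask & (subtracted > t)
    lowlight = mask & ~highlight
    return HighlightSegmentation(subtracted=subtracted, threshold=t,
                                 highlight_mask=highlight, lowlight_mask=lowlight,
                                 flags=flags)


def specular_residual(full: np.ndarray, diffuse2: np.ndarray,
                      mask: np.ndarray | None = None) -> np.ndarray:
    """Specular contribution isolated by subtracting the diffuse component.

    Negative values (render noise) are clamped to zero.  If ``mask`` is
    given, background pixels are zeroed so downstream band statistics cannot
    depend on them.
    """
    full = np.asarray(full, dtype=float)
    diffuse2 = np.asarray(diffuse2, dtype=float)
    if full.shape != diffuse2.shape:
        raise ValueError(
            f"full {full.shape} and diffuse2 {diffuse2.shape} shapes differ")
    residual = np.maximum(full - diffuse2, 0.0)
    if mask is not None:
        residual = np.where(np.asarray(mask, dtype=bool)[..., None], residual, 0.0)
    return residual


def coverage(seg: HighlightSegmentation, mask: np.ndarray) -> float:
    """Proportion of object pixels that are specular highlights."""
    mask = np.asarray(mask).astype(bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("object mask is empty")
    return float(seg.highlight_mask.sum()) / n


def band_contrast(residual: np.ndarray, mask: np.ndarray,
                  config: FeatureConfig = FeatureConfig()) -> float:
    """Band-summed RMS contrast of the specular residual.

    The residual luminance (background zeroed) is decomposed into
    octave-spaced difference-of-Gaussian bands, ``sigma_k = sigma0 * 2**k``;
    each band contributes the standard deviation of its response over object
    pixels.  Bands whose support exceeds the frame are dropped (logged).
    The result is linear in the residual amplitude.
    """
    residual = np.asarray(residual, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if not np.all(np.isfinite(residual)):
        raise ValueError("residual must be finite")
    if not mask.any():
        raise ValueError("object mask is empty")
    lum = luminance(residual) * mask
    min_dim = min(lum.shape)
    total = 0.0
    used = 0
    prev = lum
    for k in range(config.n_bands):
        sigma = config.band_sigma0 * 2.0 ** (k + 1)
        if 4 * sigma > min_dim:
            break
        smooth = ndimage.gaussian_filter(prev, sigma=sigma, mode="reflect",
                                         truncate=4.0)
        band = prev - smooth
        total += float(band[mask].std())
        prev = smooth
        used += 1
    if used < config.n_bands:
        log.info("band_contrast: used %d of %d bands (frame min dim %d px)",
                 used, config.n_bands, min_dim)
    return total


def _log_gabor_bank(shape: tuple[int, int], wavelengths: list[float],
                    n_orient: int, sigma_r: float = 0.55,
                    sigma_theta: float = 0.55):
    """Frequency-domain log-Gabor filters at the given wavelengths."""
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0  # avoid log(0); DC is zeroed below
    theta = np.arctan2(-fy, fx)
    bank = []
    for wl in wavelengths:
        f0 = 1.0 / wl
        radial = np.exp(-(np.log(f / f0) ** 2) / (2 * np.log(sigma_r) ** 2))
        radial[0, 0] = 0.0
        scale_filters = []
        for j in range(n_orient):
            ang = j * np.pi / n_orient
            dtheta = np.angle(np.exp(1j * (theta - ang)))
            # Half-plane selection makes the spatial filter complex (analytic).
            angular = (np.exp(-(dtheta ** 2) / (2 * sigma_theta ** 2))
                       * (np.abs(dtheta) < np.pi / 2))
            scale_filters.append(radial * angular)
        bank.append(scale_filters)
    return bank


def sharpness_lpc(residual: np.ndarray, seg: HighlightSegmentation,
                  config: FeatureConfig = FeatureConfig()) -> tuple[float, list[str]]:
    """Mean local-phase-coherence sharpness over the highlight region.

    Complex log-Gabor responses ``c1, c2, c3`` at octave-spaced scales are
    combined per pixel and orientation into the phase-coherence residue
    ``phi1 - 3*phi2 + 2*phi3`` (zero at a phase-coherent feature such as a
    sharp edge).  Coherence-weighted fine-scale energy is aggregated over
    the highlight region against coarse-scale energy,

    ``x = sum_hi sum_o |c1_o| cos(residue_o)  /  sum_hi sum_o |c3_o|``,

    so both dephasing and high-frequency attenuation under blur lower the
    statistic, and flat highlight interiors (which carry no energy at any
    scale) do not dilute it.  The returned index is ``x / (1 + x)``, a
    strictly increasing squash onto [0, 1]; 0 with a flag when the highlight
    mask is empty or the residual carries no band energy.
    """
    residual = np.asarray(residual, dtype=float)
    if not np.all(np.isfinite(residual)):
        raise ValueError("residual must be finite")
    hi = seg.highlight_mask
    if not hi.any():
        return 0.0, ["empty_highlight_mask"]
    obj = hi | seg.lowlight_mask
    lum = luminance(residual) * obj
    wavelengths = [config.lpc_wavelength * 2.0 ** k for k in range(3)]
    bank = _log_gabor_bank(lum.shape, wavelengths, config.lpc_n_orient)
    spectrum = np.fft.fft2(lum)
    num = np.zeros(lum.shape)
    den = np.zeros(lum.shape)
    for j in range(config.lpc_n_orient):
        c1 = np.fft.ifft2(spectrum * bank[0][j])
        c2 = np.fft.ifft2(spectrum * bank[1][j])
        c3 = np.fft.ifft2(spectrum * bank[2][j])
        residue = c1 * np.conj(c2) ** 3 * c3 ** 2
        num += np.abs(c1) * np.cos(np.angle(residue))
        den += np.abs(c3)
    total_den = float(den[hi].sum())
    if total_den < 1e-12:
        return 0.0, ["degenerate_residual"]
    x = max(float(num[hi].sum()), 0.0) / total_den
    return x / (1.0 + x), []


def _sat_val(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """HSV saturation and value: S = (max-min)/max (0 where max==0), V = max."""
    mx = rgb.max(axis=-1)
    mn = rgb.min(axis=-1)
    sat = np.where(mx > 0, (mx - mn) / np.where(mx > 0, mx, 1.0), 0.0)
    return sat, mx


def colour_cues(full: np.ndarray, seg: HighlightSegmentation,
                mask: np.ndarray) -> tuple[float, float, float, list[str]]:
    """Mean saturation in the highlight and lowlight regions, and mean
    lowlight value, from the full image in HSV space."""
    full = np.asarray(full, dtype=float)
    if full.ndim != 3 or full.shape[-1] != 3:
        raise ValueError("full must be an RGB image")
    sat, val = _sat_val(full)
    flags: list[str] = []
    if seg.highlight_mask.any():
        hi_sat = float(sat[seg.highlight_mask].mean())
    else:
        hi_sat, flags = 0.0, flags + ["empty_highlight_mask"]
    if seg.lowlight_mask.any():
        lo_sat = float(sat[seg.lowlight_mask].mean())
        lo_val = float(val[seg.lowlight_mask].mean())
    else:
        lo_sat, lo_val = 0.0, 0.0
        flags.append("empty_lowlight_mask")
    return hi_sat, lo_sat, lo_val, flags


def _assemble(scene: SceneComponents, seg: HighlightSegmentation,
              config: FeatureConfig) -> FeatureVector:
    residual = specular_residual(scene.full, scene.diffuse2, scene.mask)
    cov = coverage(seg, scene.mask)
    contrast_raw = band_contrast(residual, scene.mask, config)
    sharp_raw, sharp_flags = sharpness_lpc(residual, seg, config)
    hi_sat, lo_sat, lo_val, colour_flags = colour_cues(scene.full, seg, scene.mask)
    e = config.root_exponent
    return FeatureVector(
        coverage=cov,
        sharpness=sharp_raw ** e,
        contrast=contrast_raw ** e,
        highlight_saturation=hi_sat,
        lowlight_saturation=lo_sat,
        lowlight_value=lo_val,
        threshold=seg.threshold,
        flags=tuple(seg.flags + sharp_flags + colour_flags),
    )


def feature_vector(scene: SceneComponents,
                   config: FeatureConfig = FeatureConfig()) -> FeatureVector:
    """Measure the six cues from a complete set of scene components."""
    seg = segment_highlights(scene.specular, scene.diffuse1, scene.mask,
                             config.threshold_fraction)
    return _assemble(scene, seg, config)


def feature_vector_manipulated(scene: SceneComponents, b: float,
                               config: FeatureConfig = FeatureConfig(),
                               epsilon: float = 1e-6,
                               kernel_extent: int | None = None) -> FeatureVector:
    """Measure the cues of a feature-manipulated stimulus.

    Identical to :func:`feature_vector` except that the highlight/lowlight
    segmentation consumes the specular render after the normal-guided blur
    with parameter ``b``, accounting for the spread of highlight coverage a
    sharpness manipulation induces.  ``b = 0`` reduces exactly to
    :func:`feature_vector`.
    """
    from .filters import normal_blur, shininess_from_blur, default_kernel_extent

    if b == 0:
        spec = scene.specular
    else:
        s = shininess_from_blur(b, epsilon)
        extent = kernel_extent or default_kernel_extent(scene.shape[1])
        spec = normal_blur(scene.specular, scene.normals, scene.mask,
                           shininess=s, kernel_extent=extent)
    seg = segment_highlights(spec, scene.diffuse1, scene.mask,
                             config.threshold_fraction)
    return _assemble(scene, seg, config)
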