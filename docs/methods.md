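# Methods

`glossim` studies how the image structure produced by specular reflections
relates to perceived surface gloss and material category.  It implements the
full analysis loop — layered stimulus generation, image-computable feature
measurement, appearance-transfer filtering, and perceptual statistics — with
every stage testable against known ground truth.

## Layered scene representation

A stimulus is a set of aligned linear-light layers (`SceneComponents`): the
full rendering, the diffuse component of that rendering (*diffuse 2*), a
diffuse-only rendering matched to the facing specular reflectivity
(*diffuse 1*), the purely specular rendering, per-pixel unit surface
normals, and the binary object mask.  Two invariants hold by construction
for synthesized scenes and are checked on load: `full = diffuse2 + specular`
on the mask, and unit normals on the mask.

Layers are stored as float TIFF files (bit-exact round trip) with a JSON
sidecar carrying the generating parameters and seed, plus an 8-bit
gamma-encoded PNG preview.  Float TIFF was chosen as the lossless
linear-light container supported end to end by the scientific Python imaging
stack.

## Synthetic scene generator

The generator is an analytic stand-in for a path tracer, chosen so that the
diffuse/specular decomposition is exact and normals are closed-form:

* **Geometry** — procedural heightfields: a sphere optionally perturbed by
  smooth sinusoidal bumps.  The built-in `dragon` has dense high-frequency
  relief, the `bunny` fewer smooth lobes; bump frequencies and phases are
  drawn deterministically from the scene seed.  Normals come from analytic
  height gradients, so they are exactly unit length.
* **Diffuse shading** — Lambertian under a few directional lights plus an
  ambient term, multiplied by the base colour.  The built-in `kitchen` and
  `campus` light fields differ in light geometry, tint and ambient level.
* **Specular shading** — an energy-normalized Blinn–Phong lobe per light
  (the `(p+2)/2` factor keeps the hemisphere-integrated specular energy on
  the Lambertian scale, so mirror-like surfaces concentrate the same light
  into bright narrow highlights, as real BRDFs do), plus a mirror image of
  extended *environment patches*: hard-edged bright cones in reflection
  space (windows, sky, lamps) modulated by a mid-frequency ripple.  The
  patches matter: with point lights alone, a mirror-smooth surface shows
  only sub-pixel highlights at desk resolutions and no measure of sharpness
  behaves sensibly.  A small constant blur (σ = 0.6 px at 256 px width)
  anti-aliases the analytic shading, which is not band-limited.
* **Parameter mapping** — the specular level maps linearly to facing
  reflectance (level × 8 %, so 0.1 → 0.8 % and 5 → 40 %); the specular
  layer is therefore *exactly* linear in the level.  Roughness widens the
  lobe (exponent `2/(roughness + 0.02)²`) and adds image-space blur
  (σ = roughness × width/32 px) — both strictly monotone, which is what
  makes the measured-sharpness-vs-roughness contract testable.  Anisotropy
  is emulated as a directional Gaussian blur of the specular layer along an
  image axis rotated by `aniso_rotation × 360°`.  Specular tint
  interpolates the highlight colour from white toward the base hue.
* **Diffuse 1** — a grey Lambertian shading with albedo equal to the facing
  specular reflectance, mirroring the reflectivity-matched diffuse
  reference used for highlight segmentation.

What the generator does **not** emulate: global illumination, Fresnel
grazing-angle effects, real mesh geometry, texture/mesostructure, and
photometric calibration.  Tests passing on these scenes show that the
measurement and statistics chain behaves correctly under known ground
truth; they do not certify feature values on real renderings.

Default frame size is 256 × 256 (tests use 64–128 px where the property
under test allows it).  The box-kernel extent of the normal-guided blur and
the roughness blur scale with frame width (160 px at a 1080-px frame), so
parameter semantics are roughly resolution-independent; residual scale
dependence of band counts and filter wavelengths is exposed in
`FeatureConfig`.

## Feature measurement

Six cues per stimulus (`feature_vector`):

* **Segmentation** — the subtracted image `lum(specular) − lum(diffuse1)`
  is thresholded at one third of the maximum diffuse-1 luminance; object
  pixels above threshold are highlights, the rest lowlights.  Luminance is
  the unweighted RGB mean (the cue definitions operate on plain RGB images,
  and the stimuli include strongly coloured channels).  An all-zero
  diffuse 1 yields threshold 0 and a warning flag.
* **Coverage** — highlight pixels / object pixels.
* **Contrast** — the specular residual `max(full − diffuse2, 0)` (background
  zeroed) is decomposed into octave-spaced difference-of-Gaussian bands
  (σ = 1, 2, 4, … px, up to 5 bands or what the frame supports); each band
  contributes its standard deviation over object pixels, without mean
  normalization (the residual is already an increment over diffuse
  shading).  The statistic is exactly linear in residual amplitude.
* **Sharpness** — a local-phase-coherence index from complex log-Gabor
  filters at three octave-spaced scales (finest wavelength 6 px, four
  orientations, half-plane angular windows).  At a phase-coherent feature
  the scale-wise phases satisfy `φ1 − 3φ2 + 2φ3 = 0`.  Coherence-weighted
  fine-scale energy is aggregated over the highlight region against
  coarse-scale energy, `x = Σ|c1|cos(φ1−3φ2+2φ3) / Σ|c3|`, and squashed to
  [0, 1] by `x/(1+x)`.  Region-level aggregation (rather than a per-pixel
  mean) was chosen because flat highlight interiors carry no band energy
  and would otherwise dilute the statistic non-monotonically; both
  dephasing and high-frequency attenuation under blur strictly lower the
  index, which is verified on explicit blur ladders.
* **Colour cues** — mean HSV saturation (`(max−min)/max`, 0 where max = 0)
  in the highlight and lowlight regions, and mean HSV value (`max`) in the
  lowlight region, from the full image.  Empty regions yield 0 with a flag.

Contrast and sharpness are root-transformed (default √, configurable
exponent) to linearize their relationship with rated gloss.  For
feature-manipulated stimuli, `feature_vector_manipulated` runs the
segmentation on the normal-blurred specular render (so a sharpness
manipulation's effect on coverage is accounted for); `b = 0` reduces
exactly to the unmanipulated path.

## Appearance-transfer filters

`apply_recipe` implements the compositing pipeline: specular := full −
diffuse2 (clamped); cross-bilateral blur with a box spatial kernel and
range weight `clamp(n·n0, 0, 1)^s`, renormalized to unit weight over
contributing object pixels, with `s = 1 + 1/((b/5)⁴·100 + ε)`; optional
velvet filter (`m1` the non-monotonic smoothstep luminance remap peaking at
half the maximum specular luminance, `m2 = clamp(n·nm, 0, 1)` toward the
scene's main highlight direction, applied right after blurring); optional
per-component colour multiplication (`d_col = (0,0,0)` discards the diffuse
layer); HSV value/saturation adjustment `v' = boost·v^γ`,
`s' = clamp(sat·s, 0, 1)`; re-addition.  Negative `n·n0` clamps to zero
before exponentiation (non-integer powers of negatives are undefined and
back-facing surfaces should not contribute); `m2` clamps likewise.  The
identity recipe reproduces the full rendering to 1e-6 (HSV round-trip
tolerance); `b = 0` skips the blur exactly.

Per-material starting recipes ship as editable JSON presets
(`builtin_recipe`); their numeric values are invented defaults except the
four per-scene velvet highlight directions, which are normalized to unit
length on load.

## Perceptual statistics

* **Term reduction** — retain free-naming terms used by ≥ 5 participants,
  then apply an explicit analyst-supplied merge map.
* **Profiles** — stimulus × category sums of 1–3 confidence scores;
  permutation-invariant and additive over participant subsets.
* **Factor analysis** — maximum-likelihood FA (via scikit-learn) on
  column-standardized profiles; stimuli are observations, categories
  variables.  Factor count is capped by the degrees-of-freedom limit
  (largest m with `((p−m)² − (p+m))/2 ≥ 0`; 12 for 18 categories).  Factor
  scores use the Bartlett WLS estimator
  `F = Z Ψ⁻¹Λ (Λ'Ψ⁻¹Λ)⁻¹`.  No rotation by default; varimax by flag.
  Shared-variance fractions are squared-loading sums normalized by the
  total communality.  Each stimulus is assigned to the factor of its most
  extreme score; stimuli whose extreme score is negative form one extra
  dimension on the factor where they are most numerous (≥ 5 by default),
  otherwise they are flagged unassigned.  Near-zero uniquenesses are
  flagged as Heywood cases; zero-variance categories are rejected with
  advice.
* **LOCO LDA** — pooled-covariance linear discriminant analysis
  (scikit-learn, `lsqr` solver with optional shrinkage; least squares
  gives a pseudo-inverse fallback for singular covariance), one fold per
  shape × light-field condition.  Test items whose class is missing from a
  training fold are flagged and excluded from that fold's denominator.
  With 13 balanced classes the permutation chance level is 1/13 ≈ 7.7 %.
* **Gloss regression** — OLS (statsmodels) of mean ratings on the three
  gloss cues; with n stimuli the F statistic has (3, n−4) degrees of
  freedom (920 included stimuli → F(3, 916)).
* **Agreement** — median pairwise Pearson r across raters and mean
  leave-one-out R² (squared correlation of each rater with the mean of the
  others); constant raters are skipped with a flag.
* **RSA** — Spearman correlation between stimulus dissimilarities from
  category profiles (correlation distance) and from standardized features
  (Euclidean).
* **Model comparison** — per material dimension, adjusted-R² comparison of
  `score ~ gloss` against `score ~ three cues`.

Correlations are reported raw (Fisher z available via `fisher_z`); the
analysis chain emits flags rather than silently dropping data.

## Simulated observers

Categorical responses: category affinities `L·s` from a known
categories × factors loading matrix; choices are softmax samples at a
temperature (Gumbel-max sampling), confidence 1–3 from terciles of the
choice margin *on the probability scale*, so the deterministic limit
(temperature → 0) yields unanimous argmax choices at confidence 3.  The
default loading generator produces simple structure (each category loads
0.7–0.95 on one factor plus one small cross-loading), which keeps the
factor model identifiable up to sign and permutation — the property that
makes recovery testing meaningful.

Gloss ratings: `clip(w·(coverage, √contrast, √sharpness) + intercept +
bias_p + ε, 0, 1)` with per-rater bias and i.i.d. noise.  Recovery tests
keep the generating range inside [0, 1] so clipping cannot bias the OLS
estimator; with n = 924 stimuli, noise σ = 0.05 and 8 raters, each weight
falls within 2 standard errors in ~97 of 100 seeds.

## Reproducibility

All generators are pure functions of their inputs and a seed; the pipeline
(`run_pipeline`) derives one child seed per stage from the run seed and
records SHA-256 checksums of every tabular output in its manifest, so a
re-run with the same configuration is verified bit-identical.  Degenerate
inputs (empty masks, all-zero layers, constant raters, singular
correlation matrices, classes missing from folds) raise or flag explicitly
rather than propagating NaNs.

## Known limitations

The synthetic scenes are analytic approximations; absolute feature values
are not comparable with path-traced stimuli, only the contracted
monotonicities and invariances are.  The sharpness index is a
re-implementation of the phase-coherence idea, not numerically equal to any
particular reference implementation.  LDA assumes shared covariance and
linear class boundaries; materials defined by nonlinear feature
combinations are beyond it by design.  The factor model's rotation
indeterminacy means recovered loadings are only meaningful up to rotation
unless the generating structure is simple.
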