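# Methods

This note documents the models and procedures implemented in `kakispec`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data experiments do and do not demonstrate.

## Data model

A hyperspectral cube is a `(rows, cols, bands)` array with a strictly
increasing wavelength axis; the instrument geometry this package targets is
60 bands from 450 to 1040 nm in 10 nm steps. Cubes are tagged either
`raw_counts` or `reflectance`; reflectance values live in [0, 1.5] (headroom
above the 0.99 white-target value for noise). Cubes round-trip through an
ENVI text-header + raw-binary layout (BSQ/BIL/BIP interleaves on read,
float32 BSQ on write) and a single-file `.npz` container that also preserves
the origin tag. Spatial coordinates are 0-based `(row, col)` with row 0 at
the top; connected components are 4-connected throughout.

## Reflectance calibration

ρ(x,y,λ) = ρ_ref(λ) · (R − R_dark) / (R_white − R_dark), evaluated per pixel
and band. ρ_ref defaults to the scalar 0.99 (a 99% Spectralon tile) with a
per-band override hook for non-flat targets. References may be full frames
or spatially flat 1×1 cubes that broadcast (synthetic fixtures). Values
outside [0, 1.5] — noise-driven negatives where raw < dark, or overshoots —
are clipped and counted in the log rather than raised: a handful of noisy
pixels must not abort an image. Any site where white ≤ dark makes the
correction undefined and raises, naming the first offending coordinate.

## Preprocessing operators

* **Savitzky–Golay** (window *w* odd ≥ 3, polyorder *p* < *w*, deriv
  *d* ≤ *p*): local least-squares polynomial filtering along the band axis.
  Boundary samples are re-fit on the truncated one-sided window, so the
  spectrum keeps its length and any polynomial row of degree ≤ *p* is
  reproduced exactly everywhere. Smoothing uses (5, 2, 0); the aging recipe
  uses the derivative variant (3, 2, 1) — "derivative" unqualified is taken
  as the first derivative, the chemometric convention, with the order
  exposed in the configuration.
* **SNV**: each spectrum is centred and scaled by its own mean and sample
  (n−1) standard deviation, removing multiplicative scatter (and, in the
  synthetic scenes, the vignette factor exactly). Rows with zero spread map
  to zeros with a logged count instead of raising — flat background pixels
  are normal, not errors.
* **Mean centring** stores the training column means so held-out spectra are
  centred with the *training* statistics.
* **Cube denoising** is a pluggable stage ahead of the PCA steps. The
  default is the identity; Gaussian per-band spatial smoothing and top-*k*
  PCA-truncation reconstruction are available. The pipeline's logic does not
  depend on the denoiser choice.

## PCA

Fitted on pixels as observations and bands as variables, with centring but
no variance scaling, by deterministic SVD. Each loading's sign is fixed so
its largest-magnitude coefficient is positive, which makes component
identities ("the PC6 image") stable across runs. Explained-variance
fractions are eigenvalue shares of total variance.

* **PCA #1 (fruit segmentation)** is fitted per image — it only needs scene
  contrast, and per-image fitting keeps the stage self-contained.
* **PCA #2 (damage)** is fitted once on the pooled, SG(5,2,0)+SNV
  preprocessed fruit pixels of a small training sample (default two bruised
  fruit per day, seeded), then reused for every image (fit-then-project).

## Fruit segmentation

PC1 score image → min–max normalisation to [0, 1] over valid pixels →
greyscale closing (disk radius 3 at 128×128 scale) → Otsu threshold →
opening (disk radius 5) → largest 4-connected component. Otsu labels two
classes but not which is fruit; the class with the higher mean NIR
reflectance (bands ≥ 800 nm) is taken as fruit, because fruit tissue is
NIR-bright while background and the dry calyx are not. Structuring-element
radii are configuration values and should scale with resolution.

**Otsu's threshold** is computed over a 256-bin histogram of the input
range by maximising between-class variance, with ties resolved to the
lowest qualifying threshold; the returned value is the upper edge of the
best low-class bin, so `values <= t` reproduces the optimal histogram split
exactly. Note a consequence of the lowest-tie rule: on perfectly separated
bimodal data the variance is constant across the empty gap, so the
threshold sits at the gap's lower edge, not mid-gap (implementations that
average tied maxima report mid-gap; the partition is identical).

## Damage segmentation

Fruit-pixel spectra → SG(5,2,0) → SNV → projection onto PCA #2 → one
configurable PC score image → Otsu over fruit pixels only (the background
is already masked). The *minority* class within the fruit is the bruise
candidate: a bruise is a localised subregion, and the PC sign is purely
conventional, so polarity cannot be fixed a priori. Candidate 4-connected
regions then pass a three-part filter:

* **min area** — default 0.2% of the fruit area (floor 1 px);
* **min circularity** — 4πA/P² ≥ 0.3, where P is the boundary-walk
  (marching-squares outer-contour) perimeter; the isoperimetric form caps at
  1.0 and a single pixel is defined as 1.0. The contour-length perimeter is
  used because border-pixel-weight estimators undercount 1-px-wide
  structures by ~2×, which would let exactly the "long and narrow"
  edge artefacts through that the filter exists to remove;
* **max boundary fraction** — at most 50% of region pixels within a 3-px rim
  inside the fruit boundary, since curvature-induced illumination errors hug
  the rim.

A fruit is *damaged* iff at least one region survives; the mean **raw**
reflectance spectrum (calibrated, not SNV'd) over the surviving pixels is
the aging feature. A spectrally flat fruit (degenerate Otsu input) yields an
*intact* verdict with a logged degenerate flag: no contrast is no evidence
of damage.

**Which PC image?** The PC image in which a bruise is best delimited
depends on the spectral complexity of the scene and, in this method family,
is chosen per dataset by inspection (PC6 on the laboratory instrument this
pipeline models, which is the module default). The synthetic scenes are
spectrally low-rank — a handful of material templates plus iid noise — so
the bruise contrast concentrates in PC2; `pipeline.synthetic_scene_config()`
pins `selected_pc=2` for all synthetic runs.

**Region-filter floor for the synthetic study.** The synthetic configuration
also raises the minimum region area to 1.5% of the fruit area. The impact
device cannot produce an arbitrarily small bruise: the smallest simulated
bruise (day 0) covers >3% of the visible fruit face, while iid-noise blobs
in the score image stay under ~1%, so a 1.5% floor separates the two with
margin on both sides. Measured on the generator: noise regions ≤ 0.85% of
fruit area with circularity mostly < 0.6; true bruises ≥ 3.3% with
circularity ≥ 0.86.

## Damage aging (PLS-DA)

One observation per detected-damaged fruit: the mean damage spectrum,
preprocessed by SG derivative (3, 2, 1) → SNV → mean centring. Day labels
{0, 1, 2, 3} are dummy-coded and a PLS2 regression (NIPALS, no variance
scaling) is fitted; prediction is the argmax of the four predicted
indicators, ties going to the lowest day. With all latent variables the fit
reproduces ordinary least squares, which the tests use as an oracle. The
X-centring is folded into the stored intercept so a serialised model is a
single affine map plus its recipe.

The latent-variable count is chosen by stratified k-fold (default 10)
cross-validated misclassification on the calibration split, ties to the
fewest LVs; the fold count drops to the rarest class size when classes are
small, and candidate counts are capped so every fold remains fittable. The
calibration/test split is stratified 2/3–1/3 and seeded. Intact fruit never
enter the aging stage, and training labels are always the known induction
days from the manifest, never the detector's output.

A caution that shaped the tests: argmax-decoded linear PLS-DA cannot
separate four classes laid out collinearly in feature space (with equal
class sizes all four score lines cross at one point, so the middle classes
never win). Class geometries in the toy fixtures are therefore in general
position; on the synthetic spectra the day signal is multi-dimensional and
the issue does not arise.

## Synthetic scene generator

Each 128×128 scene (resolution is a knob; the camera's native 1392×1040
would only scale runtimes) contains a fruit ellipse (semi-axes ≈ 44×40 px,
jittered per cube), a star-shaped calyx patch at the fruit top rendered
with a dark leaf-like template, a dark background, and for bruised states a
circular bruise fully inside the fruit whose radius grows with day
(8/10/12/14 px). Pixel spectra are material templates times a radial
vignette factor (strength 0.15, i.e. up to 15% falloff at the corners) plus
iid Gaussian noise (sd 0.01 reflectance units), clipped to [0, 1.5]. A
scene seed fully determines the cube.

Template curves are smooth invented fixtures; only their *orderings* are
treated as normative, mirroring what is measured on real bruised persimmon:
mean reflectance over 450–660 nm intact > day 0 > … > day 3 (progressive
browning); at 670 nm every bruise above intact (chlorophyll-band flip); at
970 nm intact > day 3 > day 2 > day 1 > day 0 (free water right after
impact, drying afterwards). A `contrast` parameter in [0, 1] scales the
bruise-vs-intact separation, collapsing to intact at 0 — this drives the
detection-difficulty monotonicity tests.

What the generator does **not** emulate: textured or specular surfaces,
spatially correlated sensor noise, illumination colour, multi-fruit or
touching-fruit scenes, impact physics. Passing tests therefore demonstrate
the pipeline's logic — calibration, segmentation geometry, filter
behaviour, classifier wiring — not field performance on real fruit, whose
headline accuracies depend on the instrument's image set.

## Problem sizes and determinism

The test suite and the acceptance script run entirely at desk scale, chosen
so the whole suite finishes in a few minutes on one CPU: detection over 10
cubes per state (50 total), aging over 80 bruised cubes per day (320), PCA
training on 2 fruit per day. All randomness — scene geometry, training-image
sampling, splits, CV folds — flows from explicit seeds, and repeated runs
are verified to produce identical summaries, reports and models.

## Known limitations

* The minority-class rule for Otsu polarity fails if a bruise ever covers
  more than half the fruit face; bruises of that scale are outside the
  method's premise (they would be visible).
* Fruit/background orientation relies on an NIR-reflectance contrast; a
  bright NIR background would defeat it.
* The aging model is a linear classifier on one mean spectrum per fruit; it
  inherits PLS-DA's linear decision geometry.
* ENVI support covers the header fields this pipeline needs (dims,
  interleave, data type, byte order, wavelengths), not the full ENVI
  specification.
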