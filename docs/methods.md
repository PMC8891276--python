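# Methods

## Sensor model and calibration

A monochrome scientific camera under flat illumination is modeled per
pixel as

    counts = clip(round(gain · Poisson(flux) + offset + N(0, read_noise)), 0, 65535)

with `gain` in ADU per photoelectron, the dark `offset` and the
electronic `read_noise` in ADU. The implied mean–variance relation
(photon transfer curve, PTC)

    var(μ) = gain · max(μ − offset, 0) + read_noise²

is fitted by weighted least squares of the per-level temporal variance
against the per-level temporal mean over a ladder of flat-field stacks.
Statistics are *temporal* (per pixel, across frames, then pooled over
pixels), which removes fixed-pattern non-uniformity from the variance
estimate; the offset is taken from the darkest stack's mean rather than
fitted, which removes its collinearity with the gain; levels above 90%
of full scale are excluded because clipping biases variance downward.
Weights are the inverse sampling variance of a sample variance,
2·var²/n. The fit needs at least three unsaturated levels. Defaults
used throughout (and in the tests): 8 levels × 50 frames; the reference
sensor is gain 2 ADU/e⁻, offset 100 ADU, read noise 3 ADU — a typical
moderately amplified CMOS operating point.

Deliberately out of scope: per-pixel gain/offset maps (PRNU/DSNU), and
wavelength-dependent quantum efficiency. A single global μ→σ mapping is
used.

## Counter-based sampling and raw-equivalent replicas

All sensor randomness is a pure function of
`(seed, stream, absolute pixel coordinate)`: a SplitMix64 hash produces
two uniforms per pixel, one mapped through the Poisson inverse CDF
(exact below mean 256, a three-term Cornish–Fisher expansion above,
where its distributional error is far below one count) and one through
the normal quantile. Consequences that the tests rely on: replicas are
bit-reproducible from `(seed, n)`, mutually independent (one stream per
replica), and generation commutes with cropping when the crop origin is
carried along.

A *raw-equivalent replica* redraws every pixel from the calibrated law
at the observed value v (latent flux `max(v − offset, 0)/gain`). This
conditions on the observed image rather than on an unknown denoised
mean; it is the convention applied uniformly to the replicas and to
every comparison, and it slightly inflates the replica spread relative
to resampling the (unavailable) true scene. The default replica count
is n = 10; spreads use the n−1 sample SD.

## The noise-preserving codec

An open implementation of metrologically accurate, noise-replacing
compression, defined by its three stated properties rather than by any
proprietary file format: the decoded image mimics the raw pixel-value
statistics, the preparation step costs 1.2 dB of per-pixel SNR, and
ratios of 5:1–10:1 are reached with a lossless back end.

* **Quantization ladder.** Pixel values are binned with a local step
  Δ(v) = k·σ(v) (σ floored at 0.5 ADU so the ladder stays finite for
  noiseless models), built once per model by integrating 1/(k·σ(v))
  over the 16-bit range.
* **Payload.** Bin indices are delta-coded, zigzag-packed and deflated
  (zlib level 9). Ratios are quoted against the in-memory 16-bit buffer
  size, avoiding TIFF container noise.
* **Decode.** Each index is replaced by a seeded uniform draw over the
  bin's integer range (counter-based, so decoding is deterministic
  given the recorded seed).
* **Budget calibration.** Quantize-then-dither adds ≈ Δ²/6 of noise
  power, so the nominal scale is k = √(12·(10^0.12 − 1)/2) ≈ 1.38; k is
  fixed per model by Brent root-finding on the *measured* round-trip
  noise-power increase over synthetic flats at four means spanning the
  calibrated range (24 frames of 96×96 per mean), targeting 1.2 dB, and
  cached. The calibrated value for the reference sensor is ≈ 1.38.

JPEG variants first apply the fixed 16→8-bit reduction
(`floor(v/256)`, decoded as `×256`), then encode baseline JPEG; the
integer quality in [1, 100] is chosen by bisection on the monotone
quality→ratio relation so the achieved ratio (vs the 16-bit byte
count) is closest to the target. When even quality 1 cannot reach the
target the best effort is returned with a warning flag. JPEG is 2-D
only; depth reduction also applies voxel-wise to stacks.

## Segmentation

Pixel classification follows the trainable-segmentation pattern: a
feature stack (raw intensity plus operator responses at σ ∈ {1, 2, 4,
8} px), a random forest trained on sparse annotations with balanced
class weights, per-pixel posteriors as the fraction of tree votes, a
strict probability threshold (0.5 for cells/nuclei/plaques, 0.7 for
anatomy; ties fall to background), and 8-/26-connected component
labeling. The 2-D bank is Gaussian smoothing, Hessian eigenvalues,
Gaussian-smoothed Sobel magnitude, and difference of Gaussians
(σ, 2σ); the 3-D bank is Gaussian smoothing, Laplacian of Gaussian,
Gaussian gradient magnitude, and difference of Gaussians. Forest
defaults: 200 trees with 2 random features per node in 2-D, 100 trees
in 3-D, fixed seed. The Hessian feature is the eigenvalue set of the
Gaussian-smoothed Hessian — interactive tools differ version-to-version
in their exact plane list, so this fixed choice is recorded instead.
The classifier is trained exactly once per audit, on the raw image
only, and its training-data hash is carried in every report.

## Morphometry

Nineteen per-object parameters with fixed conventions (0-based pixel
centers, X = column; angles in degrees on [0, 180), counter-clockwise
from +X with Y up): area, X/Y center of mass, Crofton 4-direction
perimeter, moment-ellipse major/minor axes and angle, circularity
4πA/P² capped at 1, the Feret set (max caliper on the convex hull of
pixel corners, its start coordinates and angle, and the min caliper
width over hull edges), aspect ratio, roundness 4A/(π·major²),
solidity, Feret aspect ratio, compactness √(4A/π)/major, and extent.
The Crofton estimator differs slightly from other tools' perimeters
(≈8% low on axis-aligned squares), which propagates into the
circularity family; the estimator is fixed and documented rather than
matched to any specific tool. Global metrics are N_tot and A_tot in
2-D and V_tot plus the marching-cubes isosurface area SA_tot in 3-D
(voxel-face counting was rejected: it overestimates a sphere's area by
~50%).

Objects are matched raw→other by centroid: an exact match
(distance < 0.5 px) wins, otherwise the nearest neighbour, ties to the
smaller label; pairs farther than 3 px are rejected. Matching is
independent per raw object (uniqueness is not enforced; duplicates are
counted). Differences of angle-valued parameters are wrapped into
[−90°, 90°).

## Scoring conventions

ε = (χ_raw − χ_c)/σ_raw; tolerable iff |ε| < 1 strictly. Degenerate
spreads: σ_raw = 0 with Δ = 0 is tolerable-degenerate; σ_raw = 0 with
Δ ≠ 0 is not tolerable (infinite score), reported as undefined rather
than ±∞. Per-object σ_raw uses only replicas in which the object was
matched (at least 5 of 10; scaled down when fewer replicas are
configured).

Because segmentation outputs live on a discrete lattice (integer
areas, centroids rational in the pixel count), a very stable object can
yield 10 replicate values supported on one or two lattice points; the
resulting sample SD (0 or ~10⁻⁵) is not a dispersion estimate, and
dividing by it produces meaningless scores of order 10³. Scores whose
replicate sample has fewer than three distinct values are therefore
classed *degenerate (unresolved uncertainty)* and excluded from
averages — the minimal-support extension of the σ_raw = 0 convention,
applied identically to every variant.

Operator-level scores average the per-pixel ε of each (operator, σ)
feature plane over interior pixels (a border of 4·σ_max is excluded)
with σ_raw > 0; Hessian eigenvalue planes of one σ are merged. For the
tomography audit the raw data are the *projections*: the scene slice is
forward projected (discrete Radon transform), rendered through the
sensor model, compressed in projection space, and scored both there and
after ramp-filtered back projection.

## Phantoms

The generators emulate the three imaging regimes the audit targets at
desk scale, with flux levels fixed so the foreground sits at shot-noise
SNR ≈ 10 (100 e⁻) and the background at SNR ≈ 3 (9 e⁻), typical of
moderate-exposure micrographs:

* **Microspheres** — n disks (default 200 of radius 4 px on 512×512,
  the "standard" phantom), a fraction placed touching an existing disk
  (aggregation probability 0.3) so aggregates form as in real bead
  preparations.
* **Cells** — thresholded smoothed Gaussian random fields with textured
  interiors; the threshold quantile pins the requested confluence.
* **Nuclei volumes** — Gaussian-profile nuclei (half-max footprint
  defines the ground truth) over an ellipsoidal anatomy background,
  three ground-truth classes, centers kept 4 radii apart so profiles do
  not merge above the half-max threshold.
* **Tomography** — square slices, parallel-beam Radon projection with
  linear interpolation, FBP with ramp filter, reconstruction supported
  on the inscribed circle; 90–360 angles for quantitative use.

Annotations are programmatic scribbles: foreground sampled from the
eroded ground truth, background from the eroded complement, balanced
counts, never touching a true boundary.

What the phantoms deliberately do **not** model: optics (no PSF/MTF
beyond optional smoothing), spatially correlated noise, illumination
drift, photobleaching, anisotropic voxels beyond a metadata scale.
Passing tests therefore demonstrate the statistical machinery — noise
calibration, replica statistics, score behavior — not robustness to
optical artifacts of any specific instrument.

## Problem sizes and runtime choices

Audits run on 512×512 (standard) or 256×256 (ordering suites) scenes
with 10 replicas, 3-D tests on 64×128×128 volumes or smaller, and
tomography on 128–256 px slices; at these sizes a full 2-D audit with
four variants completes in well under a minute on one core, and the
complete test suite plus the acceptance script in a few minutes. The
SNR-budget measurement uses 100 replicate flats of 512×512.

## Known limitations

* The pooled SD of held-out replica scores sits near 1.3–1.4 rather
  than exactly 1: σ̂_raw from 10 replicas inflates a t-like statistic by
  √(9/7) ≈ 1.13, and training the classifier on the raw image imprints
  its specific noise realization on χ_raw, adding per-object bias
  heterogeneity. Both effects are properties of the audit protocol
  itself, not of the compression under test, and cancel out of
  *comparisons* between variants.
* The noise-preserving codec is an open re-implementation defined by
  its statistical contract; it makes no claim of bit compatibility with
  any proprietary format.
* JPEG targets can be unattainable on low-entropy 8-bit reductions
  (the encoder cannot make the file large enough); the best-effort
  ratio is flagged.
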