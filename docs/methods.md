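# Methods

## Problem and scope

Sericulture requires sorting silkworm pupae by species and sex before moth
eclosion so the correct parents are paired for hybrid egg production.
`pupaevision` implements an image-based identification pipeline for single
pupae photographed on a light background: segmentation, hand-crafted and
CNN-style feature extraction, feature fusion, shallow classification and
macro-averaged evaluation. Because no public pupa photo set exists at this
scale, the package ships a synthetic image generator that reproduces the
*structure* of such a study (5 species x 2 sexes x 3 postures, weight
covariates, molt debris) and serves as the test bed for every stage.

## Segmentation and cropping

The pupa is darker than the background, so segmentation is: luminance
grayscale (0.299 R + 0.587 G + 0.114 B), Otsu global threshold, inversion so
the pupa is foreground, one binary opening with a 5x5 elliptical structuring
element (removes thin molt filaments without eroding the body), connected
components, and an area filter (default 2% of the image area) that discards
debris; the largest survivor's outer boundary is the body contour. The crop
is a fixed 320x320 window centred on the filled-contour centroid, padded
with the background's median color at image borders; bodies larger than the
window are cropped with a warning and a `truncated` flag.

Otsu and the 2% area threshold are package choices — the procedure's steps
are standard but their parameters are not canonical; both are exposed in the
API. Contours are stored as marching-squares subpixel polygons; filling uses
an exact even-odd scanline rasterizer (a pixel is set when its center is
inside or on the polygon), written in vectorized numpy because the library
rasterizers were either a bottleneck at ~1000 vertices or rounded vertex
coordinates.

## The pupal shape descriptor (SD-PSF, 37 dimensions)

Fourteen global statistics plus a 23-point curvature profile:

- perimeter: arc length of the boundary polyline after 1-px polygon
  simplification. The raw marching-squares polyline zigzags at half-pixel
  scale and overstates the perimeter of smooth shapes by ~6% (a digital
  circle would score a circularity of 0.89 rather than 1.0); simplification
  removes the staircase while following real outline features.
- area: filled-mask pixel count.
- radii: min / mean / max of centroid-to-boundary distances, their min/max
  ratio, and *dispersity* = coefficient of variation of the radii (the
  dispersion measure chosen because it is not redundant with circularity).
- ellipse fit: major/minor axis lengths, aspect ratio and eccentricity from
  the second-moment (covariance) ellipse of the filled region, with the
  +1/12 pixel-variance correction.
- rectangularity: area over the minimum rotated bounding-rectangle area
  (shapely's oriented envelope).
- circularity 4*pi*A/P^2 and compactness P^2/A.

The curvature profile (KMM) is computed on the contour rotated so the fitted
major axis is horizontal: chord K (K = 1..23) is the pixel-column height
(max row − min row + 1) of the silhouette at column
`cmin + round(K*(W−1)/24)` of its bounding box. The `(W−1)` span makes the
sampling mirror-symmetric on the discrete axis (K and 24−K sample mirror
columns). Rasterization for the profile anchors the bounding-box corner at a
fixed half-integer subpixel phase, which makes the chords reproducible under
rigid motions of the input contour and keeps the marching-squares boundary
off the pixel-center grid.

Head and tail are disambiguated by TL1 = sum of chords 1..11 versus TL2 =
sum of chords 13..23: pupae taper toward the tail, so if the posterior half
carries more width (TL2 > TL1) the aligned contour is mirrored and
re-sampled, placing the wider (head) end at K = 1. This canonicalization
makes the descriptor invariant to 180-degree input rotations. Scale is
deliberately *not* normalized: absolute size is an informative trait (the
species and sexes differ systematically in size and weight).

The 37th slot is the fitted-ellipse eccentricity; it is computed for
alignment anyway and completes the 13 named global statistics + 23 chords to
the frozen 37-dimension contract. Feature order is fixed in
`SDPSF_FEATURE_NAMES`.

## Standard descriptors

- **HOG, 1296**: grayscale crop resized to 210x210 — the only input size at
  which 30-px cells and 2x2-cell blocks (stride one cell, 9 unsigned
  orientation bins, L2-Hys) produce exactly 7x7 cells, 6x6 blocks and
  6*6*2*2*9 = 1296 features.
- **Hu moments, 7**: invariant moments of the binary silhouette (pure shape,
  complementary to SD-PSF), reported as −sign(h)·log10(|h|+1e-30).
- **Equivalent (uniform) LBP, 59**: classic 3x3-neighborhood codes (bit set
  when neighbor >= center, circular order), 58 uniform patterns (<= 2
  circular transitions) plus one catch-all bin; histogram over pupa-mask
  pixels, normalized to sum 1. Codes are computed by direct array shifts
  rather than an interpolating circular-LBP routine, so a constant region
  maps to the all-ones uniform code.
- **GLCM, 20**: 64-level uniform quantization of 0..255; symmetric,
  normalized co-occurrence at distance 1 for offsets 0° (0,1), 45° (−1,1),
  90° (−1,0), 135° (−1,−1), restricted to pixel pairs inside the mask; per
  angle the statistics [angular second moment, contrast, entropy (bits),
  correlation, inverse difference moment], angle-major order. A
  single-gray-level region has undefined correlation; it is reported as 0.
- **Color histogram, 768**: HSV conversion, 256 bins per channel over the
  mask, each channel normalized to sum 1, concatenated H||S||V.

LBP/GLCM/color are mask-restricted so background pixels carry no class
signal.

## CNN-style features and training protocol

A backbone maps a 224x224 channel-normalized RGB crop to the 1000-dim output
of an ImageNet classification head, used directly as a feature vector. The
always-available `tiny-test` backbone is a small randomly initialized numpy
network (16x16 average pooling → 588 → 64 ReLU → 1000) with the same output
contract; the six named ImageNet architectures are an optional torchvision
plug-in and raise a clear error when weights cannot be loaded. All protocol
logic is therefore testable without downloads or a GPU.

Fine-tuning attaches a temporary linear head for the task classes and trains
the stack with SGD (momentum 0.9), cross-entropy, batch size 64, initial
learning rate 1e-4 decayed by x0.8 every 5 epochs
(`lr(e) = 1e-4 * 0.8^floor(e/5)`, epochs 0-based), and a two-phase early
stop: convergence begins at the first epoch whose trailing five training
losses fluctuate (max−min) by < 0.001; training halts at the first
subsequent epoch — at least five later, so the validation window lies wholly
after the plateau — whose trailing five validation losses shift by < 0.005.
"Fluctuation" is measured as the window's max−min. A cap of 200 epochs
guards non-converging runs. The returned checkpoint is the epoch with peak
validation accuracy. Augmentation draws a seeded random subset of four
families (flips, integer translations, rotations, brightness scaling) with
bounded magnitudes; zero bounds give the exact identity.

## Partitioning, fusion and classifiers

Pupae (not images) are the sampling unit: the three posture images of one
pupa always land in one split, eliminating identity leakage. Within each
class, pupae are ordered by weight and assigned systematically — every 5th
to test for the 8:2 split, every 10th to calibration and every 10th to test
for 8:1:1 — so split weight distributions match (weight-stratified
systematic sampling).

Fusion z-scores each descriptor block (they mix pixel units with ratios),
compresses any block wider than 500 dimensions to exactly 500 with a
variance-maximizing linear projection (PCA) fitted on the training rows
only, and concatenates in fixed member order. When the training split has
fewer than 500 rows the covariance is rank-deficient; the projection is
completed with zero-variance axes (zero columns) so the output dimension
stays exactly 500. Test rows reuse the train-fitted scalers and projection
unchanged.

Three classifier families with fixed settings (random state 9 throughout)
and exhaustive accuracy-scored 5-fold stratified-CV grid search:

| family | fixed | grid (traditional) | fixed (deep/fusion) |
|---|---|---|---|
| MLP | ReLU, L-BFGS | hidden in {25,50,...,150,(25,25),...,(100,100)} x alpha in {1e-1..1e-6} | hidden 120, alpha 1e-5 |
| SVM | one-vs-rest, degree 3 | RBF, C in {2^-5..2^5}, gamma in {2^-15,2^-13,...,2^5} | linear, C=1 |
| RF | Gini, min split 2 / leaf 1 | trees 200..800 step 10 (61 points) | 500 trees |

Prediction returns per-class scores (probabilities when available, else
one-vs-rest decision values) with the hard label defined as the score
argmax, so labels and curves are always consistent.

## Evaluation

Metrics treat the n-class problem as n one-vs-rest binary problems and
average arithmetically: accuracy = mean (TP+TN)/N, precision = mean
TP/(TP+FP), recall = mean TP/(TP+FN), and F1 = 2PR/(P+R) computed from the
macro precision and recall (per-class F1 is also emitted). Because the
macro binary accuracy counts true negatives it always dominates the plain
multiclass accuracy (trace/total) for n > 2; both are reported so either
reading of "accuracy" is available. Curves are one-vs-rest threshold
sweeps; ROC area by trapezoid, PR area as step-wise average precision
(trapezoidal PR areas are optimistically biased). Classes absent from the
test labels yield flagged, undefined curves excluded from averages.
Undefined precision/recall ratios (empty denominators) are reported as 0.

## Synthetic generator

Each pupa body is an elongated super-ellipse (exponent 2.5) with a
longitudinal taper `1 − tau*((t+1)/2)^2` (head blunt at t = −1, tail
narrowed at t = +1), rotated at a random angle on a 480x480 canvas — large
enough that the 320 crop never clips a default body. Species control length,
elongation, HSV base color and cuticle-noise amplitude; the sexes differ by
an extra posterior taper, a ~5% body-size reduction, an additive weight
shift, and a slight cuticle darkening (on real pupae, color features alone
separate the sexes well, so a sex-free color channel would misrepresent the
conditions being emulated). Postures share all per-pupa draws and differ
deterministically: the side view is narrower with an asymmetric dorsal
bulge, the abdomen view slightly flatter/wider ventrally. Weight is
lognormal around a length-cubed scale (grams; defaults near 1 g, males
~0.2 g lighter) and identical across the three postures of a pupa.

The half-width profile is rescaled so that the *moment-fitted* ellipse axis
ratio of the rendered body equals the profile's nominal aspect ratio
(`b = a*M(tau)/aspect`, with `M` the fitted ratio of the unit-width body);
without this the taper would bias the fit by several percent. Shading is
cylindrical with faint segment banding plus seeded per-pixel grain; the
background is light (~235) with coarse low-amplitude mottle. Debris
fragments are small dark ellipses (area-capped, default < 0.5% of the
canvas) placed with rejection sampling at a 5-px margin from the body.

Determinism: one integer seed per pupa drives all latents; dataset seeds are
derived via `SeedSequence(seed, spawn_key=(species, sex, index))`. Identical
seeds give bit-identical images.

What the generator does **not** emulate: gonadal tail markings (the manual
sexing cue), specular highlights and shadows, camera distortion,
multi-pupa scenes, and real inter-individual texture structure. Passing
tests therefore demonstrate that the pipeline's machinery is correct and
can recover class structure when it exists — not field-accuracy on real
photographs.

## Problem sizes and numerical choices

The bundled benchmark uses 20 pupae per class (600 images) with the
{SD-PSF + color histogram + SVM} pipeline, chosen so a full grid search and
its chance-level null complete comfortably on a single CPU; the structural
checks generate the full 3600-image set but keep only labels and weights.
Chord oracles tolerate +-2 px (rasterization); ellipse-fit oracles ~1%;
rigid-motion invariance of SD-PSF is < 2% per entry at the generator's
default body scale (~250-300 px), where one pixel of chord jitter stays
under 2% of even the narrow tail chords. Ties in ellipse orientation
(perfect circles) resolve to angle 0; single-gray-level GLCM correlation is
0; Hu moments use a 1e-30 log guard.

## Known limitations

- The six pretrained ImageNet backbones require the optional torchvision
  extra; without it only `tiny-test` runs (the protocol itself is fully
  tested either way).
- Single pupa per image; touching or overlapping pupae are out of scope.
- SD-PSF assumes the body is wider at the head than the tail; species
  without that asymmetry would make the TL1/TL2 flip arbitrary (stable, but
  not anatomically meaningful).
- The synthetic accuracy figures characterize the pipeline on generated
  data only and are not comparable to accuracies on real photographs.
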