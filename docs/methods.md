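# Methods

This note documents the model implemented by `lmfd`, the conventions and
defaults it pins down, what the synthetic fixtures emulate, and the
limitations the test suite makes visible.

## The descriptor

A keypoint at `(row, col)` is described from the odd-sided square patch
of side `ps` centred on it. A sliding window of side `w = 2·kz + 1`
visits all `W = (ps − w + 1)²` positions of the patch in raster order
(top-left to bottom-right, stride 1). Three binary blocks are computed:

**Symbolic block** (`W·(w²−1)` bits). Within each window the central
pixel is compared to each of the `w²−1` surrounding pixels; the bit is 1
iff the centre is *strictly* brighter. Surrounding pixels are ordered
ring-by-ring outward from the centre, each ring clockwise starting at
its top-left corner; for `w = 3` this is the familiar 8-neighbour
clockwise walk from the top-left. Ties (equal pixels) give 0, matching
the strict `d > 0` sign rule of the descriptor definition; the
sign/magnitude *transform* by contrast assigns sign 1 to zero
differences (`d ≥ 0`), and the two conventions are kept where each is
defined.

**Mean block** (`W` bits). `m_c` is the mean of the window centred on
the keypoint (the patch centre). Each window contributes 1 iff its mean
strictly exceeds `m_c`. Means are computed in double precision; sums of
8-bit integers are exact in float64, so the comparisons are exact.

**Centroid block** (`W` bits). For each window the intensity-weighted
centroid location is computed (the geometric window centre when the
window's total intensity is 0). The *centroid value* `g_n` is the
intensity of the pixel nearest to that location, per-axis rounding with
exact .5 ties resolved toward the window centre. The reference is
`c = (patch mean + image mean)/2`, the image mean computed once per
source image. Bit 1 iff `g_n > c`. The centroid value and the reference
are under-determined in the descriptor's published description; this
rule is one admissible reading, fixed here and verified bit-for-bit
against an independent nested-loop oracle so it is at least
self-consistent and reproducible.

**Combination.** The blocks concatenate in one of six orders (`CSM`,
`CMS`, `SCM`, `SMC`, `MSC`, `MCS`), the first-named block at the lowest
bit indices; the default is `MSC` (mean block most significant, the
ordering reported to match best). Bits are packed little-endian within
bytes; the on-disk format records `r`, `kz`, `ps`, the order and the bit
width in its header. Total width is `W·(w²−1) + 2W`: 90 bits for the
`r=3, kz=1, ps=5` preset and 450 bits for `r=5, kz=3, ps=9`. (A
published figure mentions 18-bit combined descriptors, which no layout
derivable from the definitions reproduces; the `M` and `C` blocks alone
give 18 bits for `W = 9`. The width here follows the per-block
definitions.)

**Verified properties** (all asserted in the test suite):

- sign/magnitude round trip is the identity over the full difference
  range [−255, 255];
- every block equals its brute-force oracle bit-for-bit on random
  patches for both presets;
- adding a constant to the patch leaves the symbolic and mean blocks
  unchanged; the symbolic block also survives positive affine contrast
  (no clipping/ties). The centroid block is *not* strictly additive-
  invariant even with the image mean recomputed: the intensity-weighted
  centroid location itself moves with the offset and can select a
  different nearest pixel (≈2 % of random 5×5 patches); invariance holds
  whenever the selected pixel is unchanged, which is what the property
  test asserts;
- 90° patch rotation permutes the window grid and cyclically shifts each
  symbolic ring code by `(w²−1)/4` positions; mean and centroid bits
  follow the window permutation alone. Exact for `w = 3` because all
  intermediate sums are integer-valued in float64.

Equivariance is not invariance: under arbitrary rotations the bit
*positions* move, so Hamming distances between a patch and its rotated
copy are large. The descriptor defines no orientation normalization, and
the empirical rotation sweep (below) shows the consequence.

## Detection

Corners are found with the 16-point segment test on the radius-3
Bresenham circle (clockwise from 12 o'clock): a pixel is a corner when
at least `arc_length` contiguous circle pixels are all brighter than the
centre by more than `t` or all darker by more than `t`. Defaults
`t = 20`, `arc_length = 9` follow the common FAST-9 convention (the
source description names neither). The score is the maximum of
`Σ(|d_p| − t)` over qualifying contiguous arcs — equivalently over
maximal qualifying runs, since the summand is positive inside a run.
Non-maximum suppression keeps the highest score within a Chebyshev
radius (default 3 px), ties resolved toward the smaller `(row, col)` so
runs are deterministic. Keypoints closer to the border than
`⌈ps/2⌉ + 3` px are excluded so the patch and circle always fit.

Note that an ideal checkerboard produces *no* segment-test corners: at
cell corners the circle alternates bright/dark in runs of ≈4–8, never 9.
The fixtures' checker texture is therefore used for exactness tests, not
for matching protocols.

## Matching, registration, stitching

Matching is mutual nearest-neighbour by Hamming distance on the packed
bits (popcount of XOR), ties to the smallest index, results sorted by
(distance, first index). A distance cap and a Lowe-style ratio test are
available but off by default. Descriptors with different block orders
are refused: a block reorder is a bit permutation applied to both sides,
which *preserves* every pairwise Hamming distance — so with plain NN
matching the six orders provably give identical match sets. The order
comparison protocol is therefore only informative when matching is
restricted to a bit prefix (`prefix_bits`), i.e. to the high-order
blocks of the chosen combination, and the implementation provides
exactly that switch.

Homographies act on homogeneous `(x, y, 1) = (col, row, 1)` points,
normalized to unit bottom-right entry. Estimation is Hartley-normalized
DLT (centroid to origin, mean distance √2, smallest-singular-vector
solution); RANSAC draws seeded 4-point minimal samples (default 2000
iterations, 3 px inlier threshold), scores by inlier count with total
inlier error as tie-break, and refits on all inliers of the best model.
Stitching composes the canvas as the union of the first frame and the
second frame's footprint, warps with bilinear interpolation, applies a
single scalar exposure gain to the second image (ratio of overlap
means — the simplest faithful greyscale reading of "a certain degree of
colour correction"), and feather-blends with distance-transform weights.

## Evaluation protocols and fixtures

The synthetic generators supply every input: four texture families
(binary checkerboard; oriented sinusoidal grating; Gaussian-smoothed
white noise rescaled to full range; horizontal ramp), homography-warped
pairs storing the exact ground truth, rotation series about the image
centre (multiples of 90° use exact trigonometric values so lattice
rotations are exact pixel permutations), and additive clipped-rounded
Gaussian noise applied after warping (sensor noise on the second
exposure). All generators are pure functions of their arguments.

- **MMA**: fraction of matches whose reprojection error under the true
  homography is ≤ τ for τ = 1..10 px.
- **Rotation sweep**: correct (≤ 3 px) cross-checked matches between an
  image and its rotations. Measured on 128 px smoothed-noise textures,
  the count collapses from ~170 at 0° to single digits beyond ~30°,
  recovering only near 360° — the quantitative face of
  equivariance-without-invariance noted above.
- **Noise sweep**: ratio of correct matches after adding noise of
  σ ∈ {10..50} to the second view, relative to σ = 0; the σ = 0 ratio
  is exactly 1 by construction. The 3 px correctness tolerance is a
  pinned protocol constant (none is published), exposed in config.
- **Order comparison**: identical pipeline per block order; equal counts
  under plain NN (provably), ranked counts under prefix matching.

**Protocol problem sizes.** The protocols run on 96–160 px textures with
a few hundred keypoints per image — enough for stable counts while
keeping a full run of the suite plus the acceptance script to a couple
of minutes. One sizing choice matters scientifically: on 96–128 px
synthetic textures the default 90-bit descriptor is *not* distinctive
enough for an informative noise sweep — within one clean image the
median Hamming distance to the nearest other descriptor is ≈4 bits,
while σ = 10 noise already perturbs a descriptor by ≈20 bits, so
nearest-neighbour matching fails for reasons unrelated to the noise
response being measured. The noise protocol therefore runs with the
wider-support preset `r = 7, kz = 1` (13×13 patches, 1210 bits), which
separates impostors from noise perturbation and yields a ratio curve
that decays smoothly (≈0.55 at σ = 10 to ≈0.12 at σ = 50, averaged over
20 textures).

**What the fixtures do not show.** The textures are stationary, noise
is i.i.d. Gaussian, illumination is constant, and ground truth is an
exact global homography. Passing these protocols says nothing about
occlusion, local parallax, photometric nonlinearity, compression
artefacts, or the match densities reachable on natural images; the
external-benchmark adapters are deliberately out of scope.

## Texture classification

Images are CLAHE-equalized (clip limit 2.0 in multiples of the mean
histogram bin — converted internally to the 0–1 fraction the library
backend expects as `clip/256` — over 8 px tiles; constant images pass
through), then described *densely*: patches of side `ps` on a regular
grid (stride `ps`, no detector — histogram featurization implies dense
pooling). Each window contributes an 8-bit symbolic code to a 256-bin
histogram; for `kz > 1` the code is computed on the 8 ring pixels at the
window's axis and diagonal extremes so it stays 8-bit. The feature
vector is the L1-normalized histogram plus the two-bin frequency
distributions of the mean and centroid bits (260 dimensions). The
classifier is an RBF-SVM (`C = 10`, scale gamma) behind per-fold
standardization inside stratified k-fold cross-validation; all
hyperparameters are pinned in config since none are published.

The synthetic 5-class dataset (checker/grating/noise/ramp families with
per-image parameter jitter, ±8° rotation and σ = 4 sensor noise) is
separated essentially perfectly (mean 5-fold accuracy ≈0.98–1.0 across
seeds), and label-permuted controls score at chance (0.2 within three
binomial standard errors). That verifies the pipeline end-to-end, not
performance on real microscopy data: the synthetic classes differ far
more than subcellular organelle textures do.

## Known limitations

- No orientation assignment: matching degrades rapidly beyond ≈15° of
  relative rotation, and stitching is only reliable for translation-
  dominant or small-rotation view pairs.
- The centroid rule is one reading of an under-specified definition
  (see above); alternative readings would produce different `C` blocks.
- The scalar-gain exposure model cannot represent vignetting or
  nonlinear tone curves.
- The stitcher registers exactly two images; no bundle adjustment, seam
  finding or multi-band blending.
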