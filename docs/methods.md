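# Methods

`culmvb` quantifies how vascular bundles are distributed and shaped across
the wall of a moso-bamboo culm cross-section, and how that changes between
internodes. This note documents the models, the synthetic data the package
is exercised on, the numerical choices, and the limits of what the tests
demonstrate.

## The radial coordinate

All positions are expressed on a normalized radial coordinate
p = (row − epidermis_row) / (pith_row − epidermis_row), with p = 0 at the
epidermis boundary and p = 1 at the pith-cavity boundary. Images follow a
fixed orientation: rows run radially with row 0 on the epidermis side,
columns tangentially. Bundle positions are the p of their area centroid,
clamped to [0, 1]. The frame is exact when ground truth is available;
from a raw image it spans the outermost and innermost rows in which more
than half of the pixels are darker than the background intensity (0.88 by
default; parenchyma renders near 0.78, background near 0.97, so the
boundary rows move by at most ~2 px across thresholds 0.4–0.6).

## Synthetic culm sections

No public image set accompanies the descriptor tables this design follows,
so the package carries a first-class generator whose defaults encode the
qualitative radial and internode gradients as study conditions:

* density and bundle count highest at the epidermis, decreasing inward;
* bundle area increasing from epidermis to pith
  (A(p) = A₀·(1 + ρp), internode 2: A₀ = 780 px², ρ = 2.2);
* aspect (tangential bbox width / radial height) rising linearly from
  0.50 at the epidermis to 1.25 at the pith for internode 2 (upper
  internodes start higher and end slightly higher);
* four morphotype stages along p — a single quasi-elliptical fiber strand
  (p < 0.12), two fiber lobes around a phloem/xylem gap (p < 0.38), then
  four lobes around enlarging metaxylem lumina (the last stage tangentially
  widened). Lumina are carved as interior holes and the outline is dented
  with narrow cos⁴ notches, so each stamp stays a single connected
  component while extent declines with stage (≈0.78 → 0.69 → 0.63 → 0.54);
* a single tangential row of tangentially elongated (aspect ≥ 1.35)
  bundles hugging the pith boundary;
* internode archetypes 2/12/22/32: the basal internode has the thickest
  wall (640 px at the desk scale, at 4.70 µm/px), the largest and most
  radially elongated bundles, and the lowest whole-wall bundle area ratio
  (interior coverage scale k = 0.16 → 0.28 from internode 2 to 32 in
  cov(p) = k·(1.5 − p)).

Placement uses two mechanisms. Peripheral bundles in real culms pack
almost shoulder to shoulder — area fractions near 70% in the outermost
band — which random sequential placement cannot reach (it jams near 55%
coverage), so the outermost bundles are laid on jittered structured
tangential rows; the pitch of the first row is solved numerically from the
archetype's target epidermal area fraction (0.70) and the rendered stamp's
pixel count inside the outer 5% band. The interior is filled by
inhomogeneous rejection sampling against the density profile (at most 200
attempts per bundle, 2-px dilated occupancy, instances never share a
pixel). Both structured zones can be disabled through archetype overrides,
which the uniform-placement Monte-Carlo test uses.

Image formation is brightfield-like: parenchyma at intensity 0.78 with a
smooth Gaussian-filtered texture (σ = 6 px, amplitude 0.03), bundles at
0.38 (contrast 0.4), background 0.97, plus white Gaussian noise σ = 0.05,
clipped to [0, 1] — imperfect for naive thresholding but learnable.

What the generator does **not** emulate: cell-level lumina textures inside
bundles, staining variation, illumination gradients, stitching seams, or
internode-specific appearance. Internodes differ only in geometry (wall
thickness, density, size, aspect), not in texture or contrast. Passing
tests therefore demonstrate correctness of the measurement and learning
machinery under controlled geometry, not performance on real histology;
in particular the mixed- versus basal-only training contrast is much
weaker here than with real sections, where upper internodes also look
different.

## Morphometry

All descriptors are computed from first principles on the pixel grid:

* connected components by row-run union-find (default connectivity 8,
  the conservative choice when bridging pixels may merge bundles), labels
  in raster order of first pixel;
* area = pixel count; centroid = mean pixel coordinate;
* eccentricity from normalized central second moments via
  λ± = (μ₂₀+μ₀₂)/2 ± √(4μ₁₁² + (μ₂₀−μ₀₂)²)/2, e = √(1 − λ₋/λ₊);
* convex area = shoelace area of the monotone-chain hull of pixel corner
  points (a single pixel has hull area 1); candidate points are per-row and
  per-column extreme pixels, which provably contain all hull vertices;
* perimeter = length of the 8-connected outer boundary chain from
  Moore-neighbor tracing with Jacob's stopping criterion (axial step 1,
  diagonal √2); interior holes do not contribute, and a single pixel has
  a degenerate chain of length 0;
* aspect = bbox width / bbox height, extent = area / bbox area, with
  half-open 0-based bounding boxes.

Border-touching bundles are measured but flagged, and excluded from
radial profiles and VAE extraction by default. scikit-image regionprops
and Qhull serve only as oracles in the test suite.

## Radial profiles

Area-fraction profiles use equal-width bins in p (default 20), counting
bundle pixels over tissue pixels per bin; empty bins report NaN. Count
profiles default to 10 bins. Moving profiles slide a window of exactly 25
consecutive bundles sorted by p and report the window-mean position, mean
and population SD of the chosen descriptor; an absolute mode reports
pixels from the epidermis instead of p. Refining bins preserves the
tissue-weighted mean fraction exactly, which the tests assert.

## Segmentation

A compact U-Net-style network in NumPy (im2col 3×3 convolutions with
hand-derived backprop, 2×2 max-pool, nearest-neighbor upsampling with skip
concatenation, 1×1 sigmoid head). Desk defaults: tile 128, depth 3, 16
base filters (535,505 parameters), Adam 1e-3, 30 epochs, batch 4,
binarization threshold 0.5. Loss is mean per-pixel binary cross-entropy;
accuracy is the fraction of pixels where the thresholded prediction
matches the mask (equal to 1 − normalized Hamming distance). Full-image
prediction assembles edge-aligned tiles — remainder tiles shift inward
rather than zero-pad — and averages probabilities in overlaps before
thresholding. Evaluation counts, besides pixel accuracy, connection
(merge) errors — predicted components overlapping ≥ 10 px of two or more
ground-truth bundles — and missed bundles with no predicted overlap.

Training set sizes were chosen for single-CPU runs: ~30 training and ~10
held-out tiles from mixed-internode sections reach ≥ 98% held-out pixel
accuracy with minimum training loss ≤ 0.04 within 30 epochs.

## Statistics

One-way ANOVA with Tukey–Kramer HSD (q from the studentized range with
N − k df; global F/p via scipy) and Kruskal–Wallis with the
Dwass–Steel–Critchlow–Fligner all-pairs test. For a pair (i, j) DSCF
re-ranks the two groups jointly; W is the rank sum of group i,
E[W] = n_i(N+1)/2, Var = n_i n_j/12·[(N+1) − Σ(t³−t)/(N(N−1))] with
N = n_i + n_j and t the tie-group sizes, q = √2·|W − E[W]|/√Var referred
to the studentized range with k groups and infinite df. A fully tied pair
reports p = 1 by convention. α defaults to 0.05.

DSCF is an asymptotic test: with n = 8 per group its studentized-range
p-values sit within ~0.02 of an exact permutation of the max pairwise
statistic once the permutation tail uses the mid-p convention (the rank
null is discrete; counting ties fully into the tail overstates moderate
p-values by the atom at the observed statistic).

Compact letter displays use insert-and-absorb: one letter initially holds
every group, each significant pair splits any letter containing both, and
subset letters are absorbed. Sharing a letter is equivalent to "not
significantly different"; minimal letter count is not guaranteed.

## VAE morphing

Bundles are cropped about their centroids into squares (larger bbox side
plus 15% padding), bilinearly rescaled to 64×64. The desk VAE is an MLP —
encoder 4096→512→(µ, log σ², latent 32), mirrored decoder — trained with
per-image summed binary cross-entropy plus β·KL (β = 1), Adam 1e-3,
reparameterized sampling, log-variance clipped to ±8. An MLP rather than a
convolutional pair keeps CPU training in seconds at this input size; the
contract (diagonal Gaussian posterior, Bernoulli decoder) is unchanged,
and the configuration scales to larger inputs and latent spaces.

Morphing encodes anchor bundles — by default those nearest relative
positions 0.01, 0.09, 0.40, 0.71, 1.00 — to their posterior means (no
sampling, so paths are deterministic), interpolates piecewise-linearly,
and decodes every path point. Frame count is segments × frames_per_segment
+ 1, endpoints decode the anchor means exactly, and across the stage-1→4
path the decoded frames' extent declines monotonically within a 0.1
measurement tolerance, mirroring the fiber-strand → four-lobed
transformation.

## Pipeline

The `culmvb` CLI chains generate → train-seg → predict → measure →
profile → stats → train-vae → morph from a YAML config (schema version 1)
in which all randomness flows from named seeds; identical configs
reproduce byte-identical CSVs. Sections are stored as 8-bit grayscale
PNGs, instance masks as 16-bit PNGs, descriptors and profiles as CSV.
By default measurements are taken from ground-truth masks
(`measure_from: truth`); switching to `prediction` measures the
segmenter's output instead.

## Numerical and degenerate-input choices

* All neural computation in float32; training is deterministic for a fixed
  seed up to floating-point associativity.
* Bundle stamps are re-rendered once or twice with rescaled axes to bring
  pixel count within 5% of target (contract: 15%).
* A placement that cannot reach a quarter of the expected interior count
  raises, naming the density profile; saturation after that threshold
  truncates gracefully.
* Empty masks label to zero components; a blank image raises in frame
  construction; degenerate tissue frames (epidermis ≥ pith row) are
  rejected at construction.
* Studentized-range tail probabilities come from scipy's implementation
  (`studentized_range.sf`), accurate well beyond the 1e-6 design tolerance.

## Problem sizes

Default test and acceptance runs use: sections of 1024×~350–670 px
(internode-dependent), ~30 training tiles of 128 px for the desk
segmenter, 5 sections per internode-2 statistic, ~120 extracted bundle
images for the VAE at 64×64, 20,000 permutation draws and 1,000 null
simulations for the statistics calibration. These sizes were chosen as the
smallest at which the replicated quantities stabilize.

## Known limitations

* The generator's archetypes encode qualitative gradients with linear
  ramps; the real radial profiles are nonlinear (linear, parabolic and
  exponential fits have all been reported for fiber fraction).
* Merge-error counts depend on the 10-px overlap threshold; the hand
  count they emulate has no such parameter.
* The MLP VAE does not model spatial equivariance; morphs between very
  differently sized anchors can pass through faint intermediate frames.
* Whether hand-drawn masks in comparable studies include intra-bundle
  lumina is unstated; synthetic ground truth here excludes them (holes are
  background), and extent values inherit that convention.
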