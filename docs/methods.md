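# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations behind each module.

## Coordinates and intensity conventions

All images are row-major, 0-based `(row, column)` grids with the origin at the
top-left pixel. Intensities are arbitrary units and are never rescaled on
read: the anisotropy score and both N:C readouts are invariant to multiplying
all intensities by a positive constant (the tests assert this to 1e-9), so
camera gain and exposure drop out by construction.

## Fiber anisotropy

### Model

Fiber orientation is a nematic (headless) quantity: a fiber at angle θ is the
same fiber at θ + π. Statistics therefore live on the doubled circle. For a
pixel set with orientations θᵢ and weights wᵢ, the mean nematic tensor is the
traceless symmetric 2×2 matrix `[[c, s], [s, −c]]/2` with
`c = Σwᵢ cos 2θᵢ / Σwᵢ` and `s = Σwᵢ sin 2θᵢ / Σwᵢ`. Its eigenvalue
difference `√(c² + s²)` equals the circular resultant length of the doubled
angles — the standard nematic order parameter, 0 for isotropic and 1 for
perfectly aligned. The acceptance suite verifies this identity against a
direct resultant computation to 1e-12.

Local orientation comes from the intensity gradient estimated by central
differences on interior pixels; the fiber direction is the gradient rotated by
90°, giving `cos 2θ = (gy² − gx²)/g²` and `sin 2θ = −2 gx gy / g²`. Border
pixels, zero-gradient pixels, and pixels outside an optional mask carry zero
weight. Central differences are the simplest consistent estimator; fancier
stencils change scores by far less than texture variability.

### Weighting modes

Two weighting modes are provided:

* `unit` (default): every oriented pixel counts once. The score is then a pure
  orientation statistic — every pixel's direction is one vote.
* `grad2`: pixels are weighted by squared gradient magnitude, making the
  statistic equivalent to the structure-tensor anisotropy. Ridge flanks of
  bright fibers dominate and weak background gradients are suppressed.

The distinction matters on noisy images. Background camera noise produces
random orientations at low gradient magnitude; under unit weighting these
dilute the score toward 0 on sparse fiber images, while under `grad2` they are
negligible. The order-parameter recovery checks therefore measure with
`grad2`, which recovers the planted order parameter of synthetic fiber images
within 0.05 across von Mises concentrations κ ∈ {0, 1, 2, 4, 8} (512×512
images, 300 fibers, 5 seeds per κ — the problem size all fiber-recovery runs
use). Unit weighting remains the default for the score itself because it makes
the measurement's meaning (fraction of aligned orientation votes) independent
of the image's contrast distribution.

### Multiscale aggregation

The patch collection divides the image into N×N non-overlapping patches for
every N in {2ⁱ} ∪ {3ⁱ}, i ≥ 0, keeping the sizes whose floor-divided patch
sides are at least `min_patch_px` (default 10). The alternative reading of the
scale collection as multiples {2i} ∪ {3i} is selectable in the configuration
(`scale_base="multiples"`); the powers reading is the default because the
multiples reading would start at N = 0, which is not a tiling. When a side is
not divisible by N, the last patch row/column absorbs the remainder so patches
tile the image exactly.

A patch is processed only when it contains at least `min_valid_pixels`
(default 100 = 10×10, matching the minimum patch area) oriented pixels;
skipped patches are omitted from the per-pixel mean rather than scored 0, so
flat background neither contributes nor dilutes. Each pixel's value is the
mean score of the processed patches containing it across scales, and the
global score is the mean over pixels with at least one contribution. If no
patch at any scale qualifies (constant image, or a mask covering fewer than
`min_valid_pixels` pixels), the analysis raises a "no quantifiable texture"
error instead of fabricating a 0.

Numerical details: when every defined pixel carries the same value the global
mean is returned exactly (not via floating accumulation), which makes the
single-scale plan {1} bit-identical to the whole-image patch score. Patch
`c, s` means are clipped to the unit disk against rounding excess.

Interpretation caveat: at fine scales a patch crossed by only a few fibers is
locally aligned even when the global texture is isotropic, so the multiscale
score of a sparse isotropic image sits above the whole-image order parameter.
That is by design — the multiscale score measures organization at all scales
and locations — but it means only the whole-image scale should be compared
with the planted order parameter of a generator.

## Nucleocytoplasmic quantification

### Segmentation

The DNA channel is smoothed (Gaussian, σ = 2 px default), thresholded with
global Otsu, hole-filled, and split by a watershed on the smoothed
Euclidean distance transform (smoothing the distance map keeps boundary noise
from seeding spurious fragments inside one nucleus). Two refinements matter in
practice and are part of the recipe:

* **Per-nucleus half-max boundary.** A single global threshold hands bright
  nuclei an oversized dim halo (their smoothed profile crosses the global
  threshold farther out), which dilutes their mean intensity and can mask
  exactly the over-bright nuclei QC must catch. Each label is therefore re-cut
  at half of its own 90th-percentile intensity, taken from a finer smoothing
  scale (σ = 1) so high-curvature detail such as the tips of elongated nuclei
  survives.
* **Raster relabeling.** Labels are assigned in raster order of centroids so
  runs are reproducible and comparable against truth tables.

Externally produced masks can be supplied to bypass segmentation entirely.

### Quality control

Per nucleus: area, perimeter (border-pixel contour length as computed by
`skimage.measure.regionprops`), roundness 4πA/P², mean DNA-channel intensity,
and border contact (any pixel in the outermost row/column). Flags:

* `mitotic_intensity`: mean intensity > 2.0 × population median (the planted
  mitotic brightness in the generator is 2.5×, well past the cutoff);
* `aberrant_roundness`: roundness < 0.8. A 3:1 ellipse has continuum roundness
  ≈ 0.66 and a disk ≈ 1.0 (digitization biases both slightly down), so 0.8
  separates the classes with a wide margin on either side. A cutoff at 0.65
  would sit inside the ellipse's own sampling variation and is too brittle for
  a smoothed segmentation boundary;
* `area_out_of_range`: outside [min_area, max_area] (defaults 50–5000 px²);
* `border`: image-border contact.

QC exclusion on synthetic fields with 10% border, 10% mitotic and 10%
aberrant cells (50 cells per field, 3 seeds) reaches precision and recall 1.0.

### Regions and readouts

The cytosolic region is a ring grown radially from the nuclear border
(default width 4 px, Euclidean metric); where rings of neighboring cells
would overlap, each pixel goes to the nearest nucleus — deterministic and
symmetric. Rings never include nuclear pixels of any cell. The whole-cell
region (for the nuclear-to-total readout) grows each nucleus by
nearest-nucleus assignment over a support obtained by Otsu-thresholding the
smoothed marker channel, capped at 40 px; neighboring cells partition the
support.

Both readouts are always computed: `nc_ratio` (nuclear mean over ring mean;
NaN when the ring mean is 0, and such cells are excluded from ratio
summaries) and `nuclear_to_total` (summed nuclear marker over summed
whole-cell marker, in [0, 1]). The classification band `N if r > 1 + δ`,
`C if r < 1/(1+δ)`, `NC` otherwise is symmetric on the log scale, so a ratio
and its reciprocal always land in mirror classes; δ = 0.2 is a free parameter
with no canonical value — the categorical call in the source assays was
visual.

## Screen statistics

Z-scores are computed per plate and per replicate against that plate's own
control wells (pooled mode available): control mean and sample SD (n − 1,
appropriate for small control counts), `x` = mean of the siRNA's wells on
that plate/replicate, `Z = (x − mean)/SD`, then `mean_z` across replicates.
Hits require `|mean_z|` strictly greater than the threshold (2.5): boundary
values are not hits. Degenerate plates (constant controls) and plates with
fewer than 2 control wells are errors, not silent NaNs.

Genotype specificity: a hit in one genotype that is a non-hit in the other
(optionally also quieter than a margin `|Z| < m` in the other). Shared hits
must agree in sign.

Fisher enrichment is the exact hypergeometric tail computed from
log-factorials (`lgamma`), with the two-sided variant summing all outcomes
whose point probability does not exceed the observed one within a 1 + 1e-7
relative rounding guard — the same convention scipy uses, and the tests
cross-check both against scipy and against exact integer enumeration. The
alternative defaults to `greater` (enrichment).

Luciferase normalization divides the experimental reporter by the
constitutive secreted control per sample, then by the mean ratio of the
reference condition; gel contraction is the fractional area loss
`(A0 − A)/A0` relative to the full frame (or an explicit well area), reported
as fold change versus the control gel. Both are scale-invariant.

## Synthetic data generators

All generators are pure functions of their spec, including the seed
(acceptance checks assert bit-reproducibility).

* **Fibers**: angles with 2θ ~ von Mises(2μ, κ) — sampling on the doubled
  circle keeps the planted order parameter `|mean e^{2iθ}|` on the same scale
  as the anisotropy score; κ = 0 is uniform. Fibers render as full-length
  Gaussian-profile ridges (FWHM = fiber width, default 3 px, additive
  intensity) plus additive Gaussian noise clipped at 0. Defaults (512×512,
  300 fibers, intensity 100, noise SD 2) give realistic fiber coverage with a
  visible but not dominant noise floor.
* **Cell fields**: non-overlapping cells placed by rejection sampling (cap
  10 000 attempts, deterministic), each a nuclear disk (radius 9 px) inside a
  cytoplasmic disk (radius 20 px). The marker channel carries
  `nc_ratio_true × marker_base` in the nucleus and `marker_base` in the
  cytoplasm, under multiplicative lognormal noise with unit mean and the
  requested CV (fluorescence noise is roughly proportional to signal, and
  intensities stay positive). Planted defects: border cells (nucleus touches
  the frame), mitotic cells (2.5× DNA intensity), aberrant cells (area-
  preserving 3:1 ellipse at random orientation). The truth table enumerates
  exactly the rendered cells.
* **Screens**: one plate per replicate, 89 siRNAs × 4 wells + 32 control
  wells, 3 replicates; control wells ~ Normal(μ, σ), siRNA wells ~
  Normal(μ + effect·σ, σ), independent everywhere.

What the generators do **not** emulate — and hence what passing recovery tests
do not certify on real data: optical point-spread blur and chromatic shifts,
uneven illumination, touching/overlapping cells, cell-shape diversity,
texture inside nuclei, plate spatial effects (edge rows), and correlated
well-to-well noise. The recovery results bound algorithmic error under the
stated noise model, not instrument systematics.

## Problem sizes

Recovery runs use: 512×512 fiber images (300 fibers; 5 κ values × 5 seeds),
1024×1024 cell fields (50 cells; 4 ratios × 3 seeds and 3 QC seeds), and
89-siRNA 3-replicate screens (20 seeds, plus a 33-control calibration plate).
Fisher enumeration covers every 2×2 table with grand total ≤ 60 (635 375
tables). These sizes give stable statistics while keeping a full validation
run under a minute of CPU.

## Known limitations

* The gradient-based orientation estimator is undefined on saturated plateaus
  and biased at fiber crossings (gradients mix, lowering the local score).
* Segmentation assumes roughly convex nuclei separable by a distance-transform
  watershed; densely packed or lobed nuclei will merge or split.
* The ring readout assumes the perinuclear band is representative of the
  cytosol; cells with polarized marker distributions violate this.
* Plate normalization assumes controls are unbiased; no positional (B-score)
  correction is applied, and none of the multiple-testing machinery beyond the
  fixed threshold is included.
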