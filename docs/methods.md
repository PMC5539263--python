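# Methods

## Image model and pre-processing

All algorithms operate on 2-D integer matrices of 8-bit gray levels
0–255.  Keeping integers (rather than the 0–1 float scale, which is
simply level/255) makes "identical pixels" exact integer equality with
no floating-point tolerance; the counting statistics are therefore
bit-deterministic.

Color images are reduced by ITU-R BT.601 luminance
(0.299 R + 0.587 G + 0.114 B, round half up).  The conversion is a
convention choice — any fixed monotone luminance would serve — chosen
because it is the most common still-image convention; it maps
equal-channel pixels (g, g, g) exactly to g.  Images deeper than 8 bits
are rescaled to 0–255 with rounding.  JPEG input is accepted with a
warning: lossy compression perturbs pixel values, and the exact-identity
statistics degrade sharply on re-encoded data.

**Monochrome masking.**  Uniform regions (typically clipped white and
black) are self-similar everywhere and would flood the statistics with
false matches.  Configurable levels (default {0, 255}) are replaced by
the unique sentinels −1, −2, … assigned in row-major order.  Sentinels
lie outside the gray range and comparisons additionally treat *any*
negative value as a non-match, so a masked pixel matches nothing — not
even its own sentinel in a self-comparison, which matters because both
operands of a self-scan share one masked array.  The variance statistic
refuses masked input outright: a sentinel is a placeholder, not a
brightness, so difference variances over it are meaningless.

## Cyclic-shift comparison

At shift (i, j) pixel A[r, c] is paired with
B[(r + i) mod rows_B, (c + j) mod cols_B]: content that does not overlap
wraps to the opposite side, so every pixel pair is superimposed at
exactly one shift.  For unequal sizes the comparison window is the
smaller extent per dimension, the shift space the larger, and each image
is indexed modulo its own dimensions — every relative placement of the
smaller image over the larger is covered.  Pipelines put the smaller
image first, so a duplicated crop's best shift is directly its position
in the larger image.

Per-shift statistics:

- *pixelwise*: count of exact equalities over the window; integer in
  [0, m·n].
- *nearest neighbor*: count of anchors whose full 3×3 block is equal in
  both overlaid images.  Anchors run over the non-wrapping window
  interior, so a hit certifies a real contiguous neighborhood; the
  zero-shift self-count is (m−2)(n−2) and a hit implies ≥ 9 pixelwise
  matches at that shift.
- *variance*: sum over 3×3 blocks of the population variance (divide by
  9) of the per-pixel differences in the block.  Taking the variance of
  the *difference* image is what yields exact invariance under a
  constant brightness offset — the defining feature of this statistic;
  pooling the 18 raw values of both blocks instead would not be
  brightness-invariant.  Accumulation is plain float64 summation.

**Block anchoring.**  The two 3×3 statistics anchor differently, on
purpose.  Variance blocks wrap toroidally within the window (one block
per window position), matching the cyclic geometry of the overlay; this
makes the variance grid *exactly* symmetric under swapping the images —
grid(A,B)[i,j] = grid(B,A)[(M−i) mod M, (N−j) mod N] — because the
difference field at the mirrored shift is a toroidal translation of the
negated original.  With non-wrapping anchors that symmetry provably
fails: the anchor set is not translation-invariant, and the seam blocks
excluded on one side differ from those excluded on the other (deviations
of order 10⁴ on 12×12 noise pairs).  Nearest-neighbor blocks do *not*
wrap, because their purpose is localization of real image neighborhoods;
their swap symmetry is exact up to chance 3×3 identities straddling the
window seam, which have probability ~L⁻⁹ per anchor (L = number of
levels) and never occur on the fixtures used here.  One visible
consequence: on a 3×3 window the nine toroidal variance blocks each
cover all nine cells in permuted order, so a single centered outlier of
−9 yields 9 × 8 = 72, not a single block's 8.

## Screening

Raw grids always score high near the zero shift — neighboring pixels
resemble each other — so shifts within toroidal Chebyshev distance
*radius* of (0, 0) are excluded first (default 5 px, configurable; the
exclusion is symmetric, covering shifts like (M−1, 0) that are small
displacements in the opposite direction).  Eligible shifts strictly
above a threshold (counting statistics) or strictly below a cut-point
(variance) are ranked best-first; equal scores order row-major by
(di, dj) so reports are deterministic.

Absolute thresholds are image-specific (they scale with window area and
level count), so defaults are quantiles of the eligible grid values: the
top 0.05 % for counting, the bottom 0.1 % for variance.  Absolute
overrides are accepted in the configuration, and every threshold
actually applied is echoed to the log and into the report.

**Localization matrices** count per anchor, over all shifts, how often
the 3×3 block there was identical (nearest neighbor) or had difference
variance strictly below the cut-point (variance).  The nearest-neighbor
totals obey Σ localization = Σ shift-grid — each identical block
increments its anchor once per shift — which is tested exactly.

**Rectangle reconstruction.**  A match mask at one candidate shift is
decomposed by greedily extracting the largest all-true axis-aligned
rectangle (stack-of-heights algorithm, ties resolved toward the
top-left) and repeating while rectangles of ≥ min_area pixels remain
(default 9, one 3×3 neighborhood — the smallest region the block
statistics can certify).  Each rectangle is reported with its
shift-displaced counterpart; remaining true pixels are reported as a
residual count rather than forced into rectangles.  Greedy extraction is
simple and deterministic; it can split an L-shaped match into two
rectangles, which matches how stepwise copy-and-paste manipulations are
actually layered.

## Synthetic fixtures

Generators are pure functions of their parameters including the seed.
Backgrounds are i.i.d. uniform integer levels on [low, high]; defaults
are 100×100 pixels over the 64 levels 96–159 — weak, mid-gray,
high-entropy noise of the kind that makes copy-move screening feasible
in real blots, at a size where a full scan of all 10⁴ shifts takes
seconds.  Planted copies write source + offset into a destination
rectangle (offsets that would clip outside 0–255 are rejected, keeping
brightness invariance exact); the ground-truth shift is
(Δrow mod rows, Δcol mod cols).  Duplicated-crop pairs return the
original, the crop and the crop origin, which is exactly the shift the
pair comparison should rank first.

What the fixtures do **not** emulate: spatial texture and correlation of
real backgrounds, JPEG block artifacts, rescaling, rotation.  Passing
tests demonstrate correctness of the statistics and recovery under the
stated noise model, not detection power on degraded real-world data —
on which exact-identity methods are known to fail.

## Detectability of the variance minimum

For a planted copy whose interior contains B full 3×3 blocks in an M×M
window over iid noise, the variance statistic's dip at the true shift is
B·E[block var], while the standard deviation of the variance sum across
unrelated shifts is ≈ 2Mσ², with E[block var] = (8/9)·2σ²; the noise
level σ² cancels and the detectability ratio is ≈ (8/9)·B/M.  For the
true shift to be the *global* minimum among ~M² candidates the dip must
beat an extreme-value fluctuation of ≈ 3.6 standard deviations, i.e.
B ≳ 4M.  A 20×15 copy in a 100×100 window (B = 234, ratio ≈ 2.1) sits
in the extreme low tail of the grid — typically within the lowest few
of ~10⁴ shifts — but is *not* reliably the minimum; a 30×20 copy
(B = 504) is borderline.  The acceptance script reports the measured
rank-1 rate honestly.  The counting statistics do not share this limit:
their chance-match noise is orders of magnitude below the planted
signal at these sizes, and their rank-1 recovery is essentially certain.

## Numerical and interface choices

- Grids are dense arrays indexed [shift_row][shift_col]; counting grids
  are int64, variance grids float64.  The brute-force oracle used in
  tests shares no code with the scanners; counting grids must agree
  exactly, variance grids to 1e−9 relative.
- Thresholding is strict (>, <), so a threshold equal to the best score
  yields no candidates.
- Reports are JSON with fixed field order; identical inputs and
  configuration give byte-identical reports except for the single
  `generated_at` field.  Candidate tables export to CSV, grids to CSV
  and 16-bit grayscale PNG heatmaps (min–max scaled).
- Pair comparisons default to pixelwise + variance; nearest neighbor is
  opt-in there, being the most expensive statistic and the least robust
  to independent re-encoding of the two files.
- Runtime is O(M·N·m·n) per statistic — exhaustive by design.  A
  100×100 self-scan takes seconds; screening large archives at full
  resolution is out of scope.

## Known limitations

No scaling or rotation correction: a duplicate resized by even a few
pixels is invisible to all three statistics.  No JPEG-artifact or edge
analysis for detecting *added* content.  No significance calibration of
counts — thresholds are exploratory quantiles, and any flagged image
requires human review.
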