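# shiftscreen

Screening of scientific images — micrographs, electrophoresis gels,
western blots — for two common kinds of figure manipulation:

1. **copy-move within one image**: unwanted content (a band, a blemish)
   hidden by pasting a patch of background noise over it, leaving two
   regions of the image pixel-identical;
2. **duplicated images**: the same image, or a crop of it, reused in a
   different figure or publication.

The tool is a quality-assurance aid for journal editors, laboratory
supervisors and integrity reviewers.  It ranks *suspicious shifts*, it
does not pass judgment: exit codes signal operational failure only, and
whether a flagged image was actually manipulated is a call for human
experts.

## Method

An image is an integer matrix of 8-bit gray levels (0–255); color input
is converted by BT.601 luminance, and large monochrome areas (pure
black/white) are replaced by unique sentinel values that can never
match, since uniform regions would otherwise match everywhere.

Two images A and B (or an image against itself) are superimposed at
**every cyclic shift** (i, j): pixel A[r, c] meets
B[(r+i) mod M, (c+j) mod N], with non-overlapping rows and columns
wrapping to the opposite side.  Each shift gets one entry in a *result
matrix* R, computed by three statistics:

- **pixelwise** — R[i, j] = number of exactly identical superimposed
  pixels.  Because every pixel pair meets at exactly one shift,
  Σᵢⱼ R[i, j] = Σᵥ h_A(v)·h_B(v) for the gray-level histograms h — an
  exact conservation law used as a self-check.
- **nearest neighbor** — R[i, j] = number of positions whose full 3×3
  neighborhood is identical in both overlaid images (anchored at the
  block's top-left pixel).  Chance 3×3 identities are vanishingly rare
  in noisy backgrounds, so even small copied patches stand out.
- **variance** — R[i, j] = Σ over 3×3 blocks of the population variance
  of the per-pixel difference A − B_shifted.  A constant difference has
  zero variance, so this statistic also finds copies whose brightness
  was offset to blend in; *low* values signal similarity.

Shifts within a small toroidal radius of (0, 0) (default 5 px) are
excluded — neighboring pixels naturally resemble each other, so tiny
shifts always score high — and surviving shifts that pass a threshold
(by default a quantile of the grid: top 0.05 % for the counting
statistics, bottom 0.1 % for variance) become ranked candidates.
Localization matrices then count, per pixel, at how many shifts the 3×3
block anchored there matched, pinpointing *where* the duplicated
material lies, and a match mask at a candidate shift can be decomposed
into the copy-and-paste rectangles that would explain it.

Limitations: the statistics require exact (or brightness-offset-exact)
pixel agreement, so rescaled, rotated or JPEG-recompressed duplicates
defeat them; use lossless PNG data whenever possible.

## Worked example

Generate a 100×100 noise fixture (levels 96–159) with a 20×15 rectangle
copied from (10, 12) to (55, 48) — ground-truth shift (45, 36) — and
self-scan it:

```
$ shiftscreen synth --rows 100 --cols 100 --low 96 --high 159 --seed 7 \
      --copy "10,12,20,15:55,48" --out demo/fx
fixture written; ground truth in demo/fx/fixture.json

$ shiftscreen scan demo/fx/fixture.png --out demo/scan
[pixelwise] direction=high threshold=201 radius=5 candidates=4
[nearest_neighbor] direction=high threshold=0 radius=5 candidates=2
[variance] direction=low threshold=5.87467e+06 radius=5 candidates=10
report written to demo/scan/report.json
```

The top candidates in `demo/scan/report.json`:

```
pixelwise          rank 1: shift (45, 36)  score 449
nearest_neighbor   rank 1: shift (45, 36)  score 234
```

The rank-1 shift is exactly the planted displacement.  The pixelwise
score 449 is the 300 copied pixels plus ~150 chance matches (10 000
pixels over 64 levels); the nearest-neighbor score 234 = 18·13 is the
count of 3×3 blocks fully inside the copied rectangle, with zero chance
hits.  Each statistic also flags the mirror shift (55, 64) =
(100−45, 100−36), the same duplication traversed in the opposite
direction.  `candidates.csv` tabulates all findings and
`heatmaps/*.png` visualize the result matrices.

Other commands: `shiftscreen compare a.png b.png --out DIR` for
duplicate/crop detection between two images (the reported shift is the
crop's position in the larger image), and
`shiftscreen batch DIR --out OUT` to self-scan every image in a
directory and compare every unordered pair.

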