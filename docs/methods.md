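# Methods

## Problem and model

A stained blood smear viewed at high magnification contains three pixel
populations that matter here: a pale, nearly achromatic background; red
blood cells (anucleate, reddish); and white blood cells, each a lighter
cytoplasm around a dark purple nucleus. The segmentation model rests on
three color facts about Wright staining, each encoded in a different
color representation:

- the nucleus is the most saturated structure and the poorest in green
  chromaticity, so the ratio of the (normalized) HSI saturation plane to
  the g-chromaticity plane is large on nuclei and below 1 elsewhere;
- the CMYK cyan fraction orders nucleus > cytoplasm > red cells ≈
  background, giving a whole-cell signal;
- WBC pixels have a higher blue/green chromaticity ratio than red cells
  or background.

Because every cue is a ratio of channel fractions, a global multiplicative
illumination change cancels exactly (up to 8-bit rounding); this is the
source of the pipeline's robustness across lamps and labs.

The cell-separation model assumes one nucleus per cell. Nucleus groups
mark cells; an overlapping clump is recognized morphologically and split
by marker-controlled watershed on the negated distance-to-background
surface, so basin boundaries fall along the waist between cells.

## Working resolution and parameters

Inputs are downscaled by `resize_factor` (default 0.2) before processing;
**every pixel-unit parameter is defined at that working scale**, where
single WBC areas span roughly 460–3367 px and nucleus lobes 124–872 px.
Defaults (all in `SegmentationParams`, serializable to YAML/JSON):

| name | default | unit | role |
|---|---|---|---|
| S1 | 100 | px | min nucleus component kept (platelet/speck removal) |
| S2 | 350 | px | min WBC component kept |
| T2 | 5 | px | padding of the lobe-connecting rectangle |
| l11 | 55 | px | max lobe-to-lobe distance for connection |
| s11, s12 | 100, 950 | px | strict single-lobe area band |
| S3 | 3500 | px | adhesive-clump area threshold (strict >) |
| R | 3.00 | – | adhesive-clump roundness threshold (strict >) |
| Rs | 7 | px | distance-plateau height seeding the second pass |
| hs, hr | 3, 3 | px, gray | mean-shift bandwidths (4 iterations) |
| N | 3 / 1.5 | – | WBC-to-nucleus area ratio, peripheral / marrow |

Roundness is the chain-code compactness perimeter²/(4π·area): 1 for an
ideal disk, ~1.1 for a digital disk, 1.5–3.1 for real single cells
(irregular membranes), and above 3 for merged clumps — which is why the
adhesion test couples a roundness floor with an area floor no single cell
exceeds. The perimeter comes from Moore-neighbor boundary tracing with
√2-weighted diagonal steps; a single-pixel region is assigned perimeter 1
so ratios stay finite.

## Numerical choices

- **Otsu** is an exhaustive 256-bin between-class-variance scan; ties go
  to the smallest threshold, and foreground is strictly above it. A
  constant plane returns its own value with a warning (empty foreground).
- **Enhancement capping.** The nucleus enhancement IE is unbounded where
  the normalized g plane approaches zero (inside the nucleus itself). The
  plane is capped at the lower quartile of IE over nucleus-candidate
  pixels before byte scaling, which packs the candidate class into the top
  histogram bins and lets Otsu separate it from the background instead of
  splitting the candidates' own heavy tail.
- **Candidate gate.** Min-max normalization is anchored by whatever spans
  the extremes, so on an image with no (or a tiny) nucleus the red cells
  would inherit the anchor role. The nucleus mask is therefore gated by
  the scale-free defining inequality of a stained nucleus: raw saturation
  strictly exceeding raw green chromaticity. Red cells and background
  satisfy the reverse inequality by a wide margin.
- **Mean shift** runs per pixel in the joint (x, y, intensity) space with
  a flat kernel (Chebyshev spatial window of radius hs, intensity window
  hr), stopping after 4 iterations or an intensity shift below 0.5. The
  output takes the converged intensity; the update is a mean of input
  samples, so the filter is a contraction on the intensity range. It is
  implemented as a numba-compiled kernel with strictly sequential
  accumulation so that a pure-Python re-implementation reproduces it
  bit-for-bit.
- **Adaptive threshold.** The background pixel budget is
  S_image − N·S_nucleus, with S_nucleus the raw nucleus-mask area (the
  lobe-connecting rectangles contain non-nucleus pixels and are excluded).
  The returned gray level is the smallest whose cumulative histogram
  reaches the budget; a budget above the image area warns and thresholds
  at 0.
- **Watershed** uses scikit-image's priority flood on the negated
  Euclidean distance transform, restricted to the cell mask, connectivity
  4; every foreground pixel joins exactly one basin. Correctness is
  checked in the tests against an independent minimax criterion: each
  pixel must be assigned to a marker minimizing the path-maximum surface
  height, ties being genuinely implementation-defined (literal partition
  equality between two flooding implementations is ill-posed, because
  whole equal-height plateaus flip on tie order). A `dist_to_seed`
  surface is available as a config switch.
- **Second-pass markers.** Distance plateaus (EDT ≥ Rs) below 30 px and
  erosion cores below 100 px (the minimum nucleus area) are rejected as
  markers: irregular boundaries shed slivers under erosion, and a sliver
  marker would carve a spurious cell out of a clump. A region that erodes
  away before splitting is returned unsplit.
- **Matching** (evaluation) is greedy one-to-one by descending IoU, and a
  pair matches only when its IoU strictly exceeds the threshold, so a
  prediction covering exactly half a cell does not count as correct at
  the 0.5 setting.

## Synthetic scenes

The generator emulates exactly the properties the method relies on, at
working resolution directly (so tests run the pipeline with
`resize_factor = 1`): palette chosen to satisfy all three stain orderings
with margin; isolated-cell radii 14–30 px (areas within the observed
460–3367 px band); nucleus area a fixed fraction of the cell (1/3
peripheral-like, 2/3 for thin-cytoplasm marrow blasts); optional
multi-lobed nuclei whose lobe areas and gaps satisfy the lobe-connection
geometry; overlap clusters built as chains of large cells (radii 26–30 px,
center distances 0.84–0.96 of the radius sum); global illumination
scaling applied before additive Gaussian noise (default sd 4 gray levels,
deliberately mild so tests probe the algorithm rather than denoising).

Boundaries carry smooth radial raggedness (harmonics 2–16, radial sd 15%
of the radius). This is calibrated to the morphology the adhesion test
presumes: single cells score roundness centered in the observed 1.5–3.1
band (the upper tail extends somewhat past it, harmlessly — singles never
reach the area floor), while overlapping clumps exceed roundness 3 and
area 3500 px, as adhesive targets are reported to do. With smooth disks
instead, a two-cell clump would score roundness ≈ 1.2 and the adhesion
test could never fire — raggedness is a modeled feature of stained cells,
not decoration.

Cells of different clusters keep their nuclei ≥ 60 px apart so the lobe
connection can never bridge separate cells that are not genuinely
overlapping. Ground truth resolves contested overlap pixels to the cell
with the smallest radius-normalized center distance; nucleus pixels always
belong to their own cell.

What the generator does **not** emulate: chromatin texture, out-of-focus
blur, stain batch variation, cell-type-specific color differences
(eosinophil granules etc.), and red cells overlapping white cells.
Passing tests therefore demonstrate the correctness of the color algebra,
threshold logic and watershed machinery under the stated stain-ordering
assumptions — not performance on any particular scanner's images.

## Validation and problem sizes

The dataset-scale figures quoted for the original method come from
private hospital images, so the suite validates instead: the two numbers
recomputable from the published counting table (recall 95.5% from
TP = 1481, FN = 69; F-measure 97% from P = 99%, R = 95.5%); exact oracle
agreement of the mean-shift filter (100 random 16×16 planes) and
flood-level consistency of the watershed (200 random ≤ 24×24 masks);
end-to-end illumination invariance over 20 scenes (identical counts,
per-cell IoU ≥ 0.9 between factors 1.0 and 0.7); adhesive separation of
2–6-cell clumps over 100 scenes (≥ 95% exact counts; ≥ 85% when merged
nuclei force the erosion pass, over 40 scenes); and aggregate F1 ≥ 0.90
on a 50-image mixed batch. These scene counts keep the whole suite in the
low minutes on one core while leaving the rates' confidence intervals
well clear of the bounds.

## Known limitations

- Thresholds assume the working scale; feeding full-resolution images
  with `resize_factor = 1` would invalidate every area parameter.
- The adhesion test misses clumps whose union stays compact or small
  (e.g. two small lymphocytes in tight overlap) — consistent with the
  under-segmentation counts reported for the original method.
- One nucleus per cell is assumed; binucleate cells would be split.
- The second watershed pass splits a region at the first component-count
  increase, so a clump hidden behind a single seed can at most double per
  pass.
- Marker-controlled watershed places boundaries along the distance-map
  ridge, which approximates but does not trace the true membrane in
  deeply occluded overlaps.
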