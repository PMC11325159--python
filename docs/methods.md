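# Methods

## Model and assumptions

The pipeline assumes a scene that decomposes into regions which are
homogeneous in colour and/or texture and separated by intensity edges. It
is fully unsupervised: the number of segments is estimated from the image's
own colour statistics, never supplied. Three properties drive the design:

1. Edges of the luma image outline candidate regions (contour cue).
2. Redundant region seeds — close together and texturally alike — can be
   merged without losing structure (texture cue).
3. The number of *perceptually distinct* colours approximates the number of
   clusters a colour-space clustering should use (colour cue).

All colour work happens in RGB; the luma conversion uses the ITU-R BT.601
weights 0.299/0.587/0.114, the most common convention for 8-bit imagery.
Images are used as-is: no pre-smoothing or resizing beyond the Gaussian
stage inside the edge detector.

## Stage parameters

| parameter | default | units | role |
|---|---|---|---|
| `canny_sigma` | 1.4 | px | Gaussian scale before Sobel gradients |
| `canny_low_frac` / `canny_high_frac` | 0.10 / 0.20 | fraction of max gradient | hysteresis thresholds |
| `connectivity` | 4 | — | connected components of non-edge pixels |
| `tau_color` | 25 | RGB distance | join adjacent regions closer than this |
| `min_area` | 20 | px | absorb smaller regions into the closest-colour neighbour |
| `base_wavelength` × 2^i, i<5 | 4,8,16,32,64 | px | Gabor wavelength grid (8 orientations kπ/8) |
| σ = 0.56 λ, γ = 0.5, ψ = 0 | — | — | ≈1-octave Gabor envelope, even phase |
| `merge_threshold` | 0.05 × diagonal | px (features unit-free) | D·F product criterion |
| `quant_levels` (Q) | 4 | levels/channel | shade collapsing for the colour-frequency index |
| `f_min` | 0.01 | fraction | minimum pixel share of a "main colour" |
| `fcm_m`, `fcm_tol`, `fcm_max_iter` | 2, 1e-5, 300 | — | FCM fuzzifier / convergence |

Canny thresholds are expressed relative to the maximum gradient magnitude so
one default works across contrasts. The merge threshold is expressed
relative to the image diagonal because, with feature coordinates normalized
to [0, 1], the product D·F carries the spatial unit; 0.05 × diagonal merges
seeds closer than a few percent of the image extent when their textures
agree, which on seeded fixtures reduces the center set substantially while
never linking across a texture boundary. Q = 4 and f_min = 0.01 implement
"collapse shades, keep main colours": 64 colour bins, of which only bins
covering at least 1 % of the image count toward K, clipped to [2, 64].

## Numerical and algorithmic choices

- **Non-maximum suppression** quantizes the gradient direction to four bins
  and is interpolation-free for exact reproducibility. Plateau ties break
  toward the pixel first along the positive gradient direction, so a
  symmetric smoothed step yields a 1-px edge. Borders reflect during
  smoothing/differentiation; NMS treats out-of-image neighbours as zero.
- **Connected components** run on the complement of the edge map (regions
  are areas bounded by contours) with 4-connectivity, so a thin 8-connected
  edge chain separates regions. A config switch (`cc_target: edges`)
  preserves the alternative reading of components on the edge pixels.
- **Region joining** is a union-find transitive closure over the adjacency
  graph (strict `< tau_color`), followed by iterative absorption of
  sub-`min_area` regions into their closest-colour neighbour; merged
  properties are area-weighted.
- **Gabor features** are the smoothed (scale 0.5 λ) magnitudes of the even
  (cosine) filter responses, DC-corrected so flat areas respond zero;
  wavelengths that do not fit the image (λ ≥ min(H, W)/2) contribute zero
  planes so the feature length stays 40. The even projection is
  phase-sensitive for off-band kernels; a quadrature (even+odd energy)
  variant, which is translation invariant for periodic textures, is
  available via `gabor_quadrature`. The even-only default keeps a single
  convolution per kernel and discriminates the textures the merge criterion
  needs.
- **Center merging** is a single transitive-closure pass, not an iterated
  fixpoint with recomputed features: merging moves centers, but the merged
  feature is the group mean, and one pass already realises the intended
  "substantial but partial" reduction.
- **FCM** initialises by farthest-point seeding from the input points
  (seeded, deterministic), which places one seed per well-separated colour
  group. A point coincident with one or more centres receives crisp
  membership split equally among them. The objective J_m is recorded per
  iteration; alternating updates guarantee a non-increasing trace.
  K from the colour-frequency index is additionally capped by the number of
  distinct FCM input points.
- **Degenerate inputs**: a single-colour image returns one label with a
  warning; fewer than two seeded regions triggers a K = 2 FCM directly on
  pixel colours.
- **Metrics**: predicted segments are mapped to ground-truth labels by
  majority overlap (ties to the smaller label), then one-vs-rest confusion
  counts are micro-averaged. Empty denominators yield 1 for overlap metrics
  (absent and unpredicted class), 0 for MCC, always flagged. Specificity is
  TN/(TN+FP); the nonstandard TN/(TN+FN) variant that some sources print is
  available via `paper_formulas` for literal comparability. PRI uses the
  contingency-table identity, O(N + L²). SNR/PSNR compare the original
  against the cluster-colour reconstruction and report +∞ (JSON null,
  flagged) for identical images.

## Synthetic fixtures: what they emulate, and what they do not

The generator renders piecewise-constant coloured regions (rectangles,
disks, stripes), optional sinusoidal luma gratings, and additive Gaussian
channel noise, with exact ground truth. Design choices:

- Palette channel values sit at the centres of broad intensity bands
  ({32, 96, 160, 224}) and the colours are spread in luma. This emulates
  the regime the method targets — scenes whose dominant colours are
  unambiguous — and keeps both the colour tally and the luma edge detector
  honestly informative at noise σ = 10 (band margins ≈ 3 σ).
- The `shapes` layout places each shape in its own slot with jittered
  position/extent, sized so shapes never overlap or touch the border:
  occlusion junctions are a separate, harder problem (see limitations).
- Gratings modulate luma only (added equally to all channels), so the
  two-texture fixtures hold mean colour fixed and isolate the Gabor/merge
  stages.
- Noise is clipped (not wrapped) to [0, 255]; σ = 0 reproduces the
  noise-free image bit-exactly.

Passing on these fixtures demonstrates correct mechanics — stage wiring,
cluster-count estimation, texture discrimination, determinism — not
performance on natural images, which have soft edges, shading gradients,
and textured regions with varying mean colour.

Problem sizes used by the test suite and the reproduction script — 96×96
canvases, 20 fixtures per condition, two noise levels — were chosen as the
smallest sizes at which every stage (including the λ = 32 kernels) operates
non-trivially.

## Known limitations

- Canny contours with gaps leak regions together; no morphological gap
  closing is attempted. T-junctions from occluding objects are the typical
  failure site.
- Colour distinctions that vanish in luma (isoluminant edges) are invisible
  to step I; the colour-frequency index and FCM may still recover such
  regions, but without dedicated seeds.
- The colour-frequency index under-counts when distinct scene colours share
  a quantization bin, and over-counts when noise or shading spreads one
  colour across bins.
- FCM clusters colours only; spatial coherence of labels is not enforced.
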