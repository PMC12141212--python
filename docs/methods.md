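# Methods

## The counting problem

A chloroplast in a thick cell is visible, in reasonable focus, in a handful
of adjacent planes of a z-series and invisible elsewhere. Counting one plane
misses most of the cell's complement; summing planes counts each organelle
several times. `chlorocount` treats counting as a deduplication problem over
per-slice 2D box detections, deliberately independent of how those boxes
were produced.

## Deduplication model

The registry ("benchmark") algorithm scans slices in focal order and keeps
one entry per distinct chloroplast:

1. Drop detections with confidence below `min_confidence` (default 0.5, the
   operating point commonly used when thresholding detector outputs).
2. For each slice, compute IOU between every surviving detection and every
   entry's *current* box (its most recently matched box).
3. Accept (detection, entry) pairs greedily by descending IOU, one-to-one
   within the slice, keeping only pairs with IOU **strictly greater** than
   `tau` (default 0.3). A matched detection is appended to the entry's
   history and becomes its current box; an unmatched detection founds a new
   entry.

Design choices where more than one reading was defensible:

- **Strict inequality at `tau`.** Merging requires exceeding the threshold;
  an IOU of exactly `tau` founds a new entry. Ties at the threshold are
  measure-zero for continuous boxes, but the convention is fixed and tested.
- **Match against the latest box, and replace it on merge.** Focal
  adjustments introduce lateral drift; tracking the newest box tolerates
  cumulative displacement that matching against the first-seen box would
  not. The alternative (keep the first box) systematically splits drifting
  objects into multiple entries.
- **Match against the whole registry, not the previous slice.** An entry
  whose chloroplast fell below detectability in one plane can re-absorb it
  in a later plane ("bridging"); restricting matches to the immediately
  preceding slice would double-count such objects.
- **Greedy one-to-one within a slice.** Two same-slice detections can never
  collapse into one entry, so within-slice duplicates are the detector's
  responsibility (no non-maximum suppression is applied here).
- **Invariants enforced at run time:** the sum of entry-history lengths
  always equals the number of processed detections, and the 3D count is
  bounded below by the largest per-slice count and above by the total.

`sweep_threshold` reports the count as a function of `tau`; it is
non-decreasing because the merge condition is monotone in `tau`. A plateau
around the default indicates the count is insensitive to the exact
threshold for that stack.

## Per-cell attribution

A detection belongs to the cell whose label lies under its box center
(rounded to the containing pixel). Center-point containment was chosen over
maximum mask overlap: it is deterministic, O(1) per box, and robust to boxes
slightly overhanging thin cell walls. A 3D entry votes with all boxes in
its history; the majority cell wins, ties resolved by the earliest-slice
vote (the in-focus planes come first for objects drifting across a
boundary). Entries voting for background are excluded from every profile
but reported, so per-cell counts plus background always equal the benchmark
count. Cells touching the raster border can be excluded
(`--exclude-border-cells`) to emulate restricting analysis to intact cells.

## Evaluation metrics

`match` performs greedy one-to-one matching by descending IOU at
`iou_min = 0.5` (ties by higher confidence, then lower prediction index) —
the matching criterion itself is a package decision, as detection work
rarely states it. Precision, recall and F1 follow the standard confusion
definitions with 0/0 = 0. The PR curve records cumulative (recall,
precision) down the confidence ranking; a curve without ground-truth boxes
is an error rather than a degenerate 0. AP integrates the
all-points-interpolated envelope (precision at recall r is the maximum
precision at any recall ≥ r, zero beyond the maximum recall) exactly over
its breakpoints — the modern PASCAL-style evaluation, with no 11-point
sampling. The tests check this implementation against adaptive quadrature
of the same envelope, an independent numerical route.

## Synthetic stacks

The generator emulates a 60× bright-field/fluorescence field of view. Its
defaults are fixed study conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| image | 320 × 320 px | field of view |
| `n_slices` | 5 | planes in the z-series (typical series length) |
| `n_cells` | 4 | Voronoi cells from a jittered seed grid |
| `count_range` | 5–20 per cell | chloroplast complement |
| `axis_range` | 4–7 px | ellipse semi-axes |
| `sigma0` | 0.8 px | in-focus blur |
| `blur_slope` | 1.5 px/slice | defocus growth: σ(z,s) = σ₀ + slope·\|z−s\| |
| `visibility_sigma` | 2.5 px | blur beyond which no ground-truth box is emitted |
| `attenuation` | 0.3 /slice | intensity falloff 1/(1 + 0.3·\|z−s\|) |
| `jitter_px` | 1.0 px | per-slice lateral stage drift (std) |
| `noise_scale` | 0.01 | additive Gaussian background noise (std) |
| `min_separation` | 18 px | minimum center-to-center distance |

Chloroplast depths are uniform over the stack, so each object is visible in
roughly two to three of five planes — per-slice counts undershoot the true
complement by half or more, which is exactly the regime where deduplication
matters. Placement samples uniformly from the pixels that keep the whole
ellipse strictly inside its cell and respect `min_separation`; if that set
empties, generation fails loudly naming the cell rather than silently
crowding objects. All randomness flows from the single spec seed, and a
fixed spec reproduces bit-identical stacks.

What the simulator does **not** model: realistic microscope PSFs (defocus
is isotropic Gaussian), chlorophyll autofluorescence spectra and chromatic
effects, touching/overlapping chloroplasts, irregular (non-convex) cell
shapes, uneven illumination, and detector-specific failure modes of trained
networks. Passing tests therefore demonstrate the correctness of the
counting, attribution, and evaluation machinery under controlled geometry —
not the accuracy of any particular detector on real micrographs.

## Built-in detector

Gaussian smoothing (σ = 1 px) → global threshold → 8-connected components →
area filter → tight bounding boxes. Otsu thresholding is the default for
arbitrary imagery; on the synthetic scenes a fixed absolute threshold of
0.15 is used, because the ~20 %-of-peak contour of a Gaussian-blurred
ellipse sits near the blur-dilated extent that defines the ground-truth
boxes, keeping detected and true boxes congruent. Confidence is the
component's **peak** smoothed intensity minus the mean background, clipped
to [0, 1]: with a low global threshold, a defocused object's footprint is
dominated by dim halo pixels, so mean-based contrast would grade in-focus
and defocused instances of the same object very differently, while peak
contrast degrades smoothly with defocus. The detector exists to exercise
the pipeline without trained weights; it makes no claim to neural-network
accuracy, and any stronger detector enters through the same per-slice text
format.

## Clustering

Per-cell features are exactly the two plotted axes, cell area (px²) and
chloroplast count. Features are standardized to zero mean and unit variance
per column (making the result invariant to area units) and partitioned by
k-means with a fixed seed and user-chosen k (default 2); the method is the
simplest reproducible reading of "cell-type clustering" in this feature
space, and the raw table is always exported for users preferring their own
method. k is not selected automatically.

## Numerical and degenerate-input conventions

- Boxes are continuous, top-left origin, area = width × height; degenerate
  (zero-area) boxes are rejected at construction.
- Normalized ↔ pixel conversion round-trips exactly for boxes strictly
  inside the image; protruding boxes are clamped, fully-outside boxes are
  errors.
- An empty stack counts 0 (not an error); an empty prediction directory is
  an error (a stack needs at least one slice).
- Label maps must be 2D integer rasters; ids are preserved verbatim, never
  renumbered.
- A constant image under Otsu thresholding yields zero detections.
- Problem sizes in the test-suite simulations (320 px fields, 5 slices,
  ≤ 45 objects; 20 stacks for the monotonicity sweep) were chosen so the
  full suite completes in seconds while still exercising every regime —
  merging, bridging, visibility loss, and jitter-dominated failure.

## Known limitations

- The registry has no motion model: monotone lateral drift larger than the
  box size between consecutive planes splits an object.
- Volumetric (voxel) IOU and z-interpolation of boxes are out of scope; the
  method operates purely on per-plane 2D geometry.
- Center-point attribution can misassign a box whose center falls just
  across a thin cell wall in a minority of planes; the majority vote
  mitigates but cannot eliminate this.
- Very dense fields where distinct neighbors overlap above `tau` across
  planes will under-count; lowering `tau` trades this against splitting.
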