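# Methods

This note records the models, parameter choices and numerical conventions
behind membratrack, and what the synthetic benchmark does and does not
establish about real microscopy data.

## Image model and assumptions

The pipeline assumes a confluent epithelial sheet imaged so that
fluorescence is concentrated on cell membranes: thin (1–3 px) bright
curvilinear structures enclosing dimmer interiors, with optical blur and
sensor noise on top.  It operates on 2-D frames; volumetric inputs are
reduced by maximum-intensity z-projection before analysis, so all motility
quantities describe in-plane motion of the projected sheet.  Calibration
(µm/pixel, min/frame) is never inferred from file metadata — it is supplied
explicitly by the caller.

Coordinates are 0-based raster coordinates, x = column (rightward),
y = row (downward), pixel centres at integers.  Directions reported by the
motility module are converted to mathematical orientation (y up), so 90°
means "up" in the displayed image.

## Ridge enhancement

Membrane ridgeness at scale σ is the γ-normalized negative principal
Hessian eigenvalue of the Gaussian-smoothed frame, σ²·max(0, −λ₁), where
the Hessian is formed by central finite differences of the smoothed image
and λ₁ is the eigenvalue of larger magnitude.  The single-eigenvalue
bright-line criterion is the simplest operator that enhances membranes,
ignores locally linear intensity (cytoplasm, gradients), and needs no
tuning beyond the scale list; the additional blobness/structureness terms
of full vesselness filters add nothing for closed thin boundaries.  The
frame is min–max rescaled to [0, 1] first, which makes the response
invariant under affine intensity changes of the input.  Defaults:
σ ∈ {1, 2} px, matching membranes 1–3 px thick at typical sampling.  Note
that the γ-normalized response to a Gaussian ridge of width w peaks at
σ = √2·w, so the scale list should bracket, not equal, the expected
half-width.  All convolutions and morphology use reflect padding; spurious
border ridges are thereby avoided.

Gap closing is grayscale closing of the ridge map with a disk of radius 2.
The disk is rasterized as all pixels within radius + 0.5 of the centre:
a strict Euclidean rasterization of radius 1 is a 4-connected cross whose
single-pixel tip slips through a one-pixel break in a thin line, so strict
disks can never bridge such breaks; the half-pixel margin (radius 1 → full
3×3) restores the intended behaviour.  Closing is extensive and
idempotent, and it is applied to ridgeness rather than to the raw image so
that bridging a membrane break cannot brighten cytoplasm.

## h-minima and watershed

The watershed relief is the gap-closed ridge map: membranes are high
ground, cell interiors are basins.  Spurious shallow basins are removed
with the h-minima transform — morphological reconstruction by erosion of
(relief + h) constrained from below by the relief, 4-connectivity.  Two
properties worth stating precisely: the transform is *not* idempotent
(surviving minima have their depth reduced by h, and a second application
raises them again), and surviving minima have depth d − h, not ≥ h; the
operative guarantee is that minima with dynamics ≤ h are annihilated.

h is expressed relative to the relief's dynamic range so the same setting
transfers across source bit depths.  The default is h = 0.10 × range:
with the σ = 1 ridge channel in the scale list, pixel noise at realistic
SNR (membrane/noise ≈ 20) leaves shallow ridgeness fluctuations inside
cells whose dynamics exceed 5 % of the range but stay well below 10 %,
while genuine inter-cell basins are separated by membrane ridges spanning
most of the range.  At 10 % the marker count equals the true cell count on
the reference scenes at both zero and σ = 0.05 noise.

The watershed flood is marker-controlled with fully specified determinism:
a priority queue keyed by (relief value, insertion age) — Meyer's flooding
order — with seed pixels enqueued by (label, raster index) and neighbours
visited in raster order.  On a flat relief this reduces to multi-source
breadth-first growth: two markers split the field along the equidistant
line, with exact ties going to the smaller label's wave.  Label-priority
tie-breaking was rejected because on flat plateaus it lets the smallest
label flood the entire plateau.  Watershed-line pixels are absorbed into
the first-arriving region rather than kept as a zero-valued skeleton, so
cell areas tile the tissue and the mean-area time series is well defined;
the boundary overlay, when needed, is recomputed as inter-label
interfaces.  Regions smaller than 30 px² are merged into the neighbour
with the longest shared boundary (smallest region first, ties to the
smaller label).  Border-touching cells are kept by default: growing
tissue extends past the field edge and those cells are typically the
objects of interest.  4-connectivity is used for minima, regions and
flooding alike; 8-connectivity would leak across 1-px membranes.

## Tracking

Association is frame-to-frame: cost = Euclidean centroid distance in
pixels, distances above the gate (default 15 px) forbidden, solved exactly
by the Hungarian method (`scipy.optimize.linear_sum_assignment`) on a
square matrix padded with virtual non-assignment rows/columns at the gate
cost, so any pairing worse than the gate resolves to a miss plus a new
track.  Area and intensity terms are deliberately omitted from the cost
(hooks exist but default off).  Unmatched tracks become lost and are
terminated after more than 2 consecutive misses; a track that re-acquires
within the budget bridges the gap with a single step whose elapsed time
scales with the frame gap.  Unmatched detections found new tracks
unconditionally.  There is no mitosis model: a division keeps one child on
the parent track and the other founds a new track — a known limitation.
The gate and miss budget suit ≈ 1 cell-diameter/hour collective drift at
5-min sampling; both are configurable.

## Motility read-outs

The wind rose bins per-cell *net* displacement vectors (first-to-last
observation of each track) by default — one vote per cell over the
analysis window; per-step mode is available.  16 half-open sectors, the
first centred on 0°; speed bands half-open with the last unbounded
(default lower edges 0, 0.05, 0.1, 0.2 µm/min).  Zero-displacement vectors
have no direction and are excluded.  Spoke length = proportion of counted
vectors in the sector; nested band fractions sum to the spoke length, and
spoke lengths sum to 1 whenever any vector is counted.  Regional counts
assign each cell by centroid to left (x < split) or right (x ≥ split) of a
configurable vertical split, defaulting to the field midline; areas are
converted to µm² with the pixel size.

## Synthetic benchmark

The generator emulates the target signal, not the biology: cells are a
Voronoi mosaic of blue-noise-sampled sites (minimum-distance rejection at
0.7 × mean spacing, then 3 Lloyd relaxation iterations toward a regular,
honeycomb-like packing); motion is a global drift (default 1 px/frame
rightward, emulating tissue growth direction) plus per-cell Gaussian
jitter (0.3 px/frame).  Rendering: membrane intensity 1.0 on pixels within
1.5 px of a Voronoi boundary, cytoplasm 0.15, background 0.05, Gaussian
PSF σ = 1 px, Gaussian read noise σ = 0.02 (optional Poisson shot noise),
clipped at 0.  The reference mosaic is 49 cells in a 256×256 field
(≈ 41 px mean cell diameter) over 20 frames at 0.5 µm/px and 5 min/frame.
All randomness flows from one seed; identical seeds give bit-identical
scenes.

Ground-truth masks are the exact Voronoi partitions and ground-truth
tracks link each site's region across frames by construction, so
segmentation is scored by per-cell IoU (with missed/split/merged counts at
a 0.5 IoU / 20 % overlap convention) and tracking by the fraction of true
frame-to-frame links reproduced plus identity-switch counts.

What passing these benchmarks does **not** show: real membranes are curved
and of variable brightness, cells divide and leave the focal plane,
photobleaching dims later frames, and deconvolution artefacts differ from
Gaussian blur.  The synthetic results bound what the algorithms can do
under their own assumptions; parameters (especially h, the gate, and the
ridge scales) should be re-examined on real data.

## Problem sizes and numerical choices

The test suite and the acceptance script run single-frame segmentations of
the 49-cell reference mosaic, a 20-frame tracking run, an 8-frame growth
scenario and a 5-frame end-to-end determinism check — desk-scale problems
chosen so the whole suite runs in well under a minute while still
exercising every stage at realistic cell density.  Oracle checks use
16×16 reliefs (h-minima), 8×8 reliefs with 2–4 markers (watershed) and
assignment matrices up to 7×7 (exhaustive 7! enumeration).  Degenerate
inputs are defined, not rejected: a constant relief is a single whole-grid
regional minimum (one marker, one region), an empty track set yields a
header-only CSV, an all-filtered wind rose is returned zeroed with an
explicit empty flag.  The analysis path contains no randomness; the
pipeline embeds no timestamps, so reruns are byte-identical.
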