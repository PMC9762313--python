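# Methods

`pcquant` reimplements, as a tested library, the image-quantification
procedures behind a protocell (PC) delivery study in zebrafish: counting
~2 µm proteinosome-based protocells inside and outside leukocytes, tracking
free-circulating protocells in blood flow, scoring their colocalization with
lysosomal or cargo markers, and measuring pigmentation, tumor burden, and
serial-section volumes. Because the original live-animal image data are not
deposited, every stage is verified instead against synthetic scenes with
planted ground truth and against brute-force oracles.

## Detection model

All counting readouts share one detection pipeline
(`pcquant.segment.detect`):

1. **Prefilter** — per-slice 2-D median (window radius *r*, nearest-edge
   replication), Gaussian (normalized kernel, σ in pixels), or variance
   (population variance of the (2r+1)² window). Filters act on each (y, x)
   plane independently; anisotropic z is never mixed into a window.
2. **Background subtraction** — rolling-ball: the background is the
   grayscale opening with a disk of radius *R*; structures wider than the
   ball are treated as background, narrow peaks survive. Output clipped at 0.
3. **Threshold** — `t = max(k · t₀, t_min)`. The raw threshold `t₀` comes
   from Otsu (256-bin histogram spanning [min, max], maximizing between-class
   variance, ties to the lowest bin, returned as the winning bin's upper
   edge), the image mean, or a fixed value. The multiplier `k` (default 1)
   is applied before the minimum clamp `t_min` (default 0); the clamp exists
   to stop background segmentation in dim fields. `t_min` may optionally be
   read as a fraction of the intensity range instead of an absolute value.
4. **Binarization** — strictly greater than `t`, so a threshold at the image
   maximum yields no foreground.
5. **Hole filling** (optional) — background regions not connected to the
   image border become foreground, in the mask's native dimensionality.
6. **Labeling** — maximal connected components; default connectivity 8
   (2-D) / 26 (3-D), configurable to 4 / 6. Labels are assigned in raster
   order of each component's first voxel, making label maps deterministic.
7. **Watershed split** (optional) — seeds are local maxima of the Euclidean
   distance transform, merged when closer than the larger seed's inscribed
   radius; the watershed of the negated distance transform, constrained to
   the mask, partitions touching convex objects. Foreground is conserved
   exactly.
8. **Filtering** — objects below a voxel-count threshold, or whose centroid
   lies outside an optional ROI mask, are removed; survivors are relabeled
   canonically.

Design choices that were genuinely open: the order of the multiplier and the
minimum clamp (multiply first, then clamp — the natural reading of a
"minimum permitted" value); the 256-bin Otsu with ties to the lowest bin
(reproducible across dtypes); strict `>` binarization; watershed seeding by
distance-transform maxima (the standard shape-based split for round cells).

## Quantified readouts

- **Containment** (`quantify.containment`): a protocell is *inside* a cell
  iff the cell label at its rounded centroid voxel is non-zero. The centroid
  rule was chosen over partial-overlap rules because the assay's readout is
  binary in/out per protocell; it is robust to soft object edges. Reported:
  % of protocells inside cells and % of cells containing ≥ 1 protocell,
  with exact conservation (n_inside + n_outside = n_total).
- **Marker colocalization** (`quantify.classify_marker_positive`): an object
  is marker-positive when the fraction of its voxels inside the marker mask
  reaches τ. τ = 1.0 encodes the strict "fully colocalized" lysosome rule
  (an automated proxy for what was originally a manual call); τ = 0.5 is
  the default for intact-protocell (membrane ∩ cargo) calls.
- **Pigmentation** (`quantify.pigmentation_fraction`): % of region pixels on
  the pigment side of an automatic threshold. The thresholding method and
  polarity are configurable; the defaults are Otsu and *dark* (pigment is
  below threshold in brightfield).
- **Fluorescent pixel count**: region pixels strictly above a threshold.
- **Area fractions**: stain-positive and double-positive percentages are
  pure pixel ratios within the tumor region.
- **Tumor area and growth**: foreground pixel count × (pixel size)²;
  timecourses are expressed as % of the first timepoint (100 at baseline;
  a zero baseline is an error).
- **Serial-section volume** (`quantify.section_volume`): the Cavalieri
  estimator Σ areaᵢ × thickness, thickness defaulting to 10 µm (the
  cryosection thickness). Sub-pixel area estimation is deliberately
  omitted — areas are pixel counts, as in the source workflows.

## Tracking

Per-frame detections are linked pairwise between consecutive frames.
Admissible links satisfy (i) physical distance ≤ `max_link_distance` and
(ii) displacement angle within ± `max_deviation` (default 70°, inclusive at
the boundary) of the preferred flow direction (default +x, "left to
right"). The original description "favor linking left to right, with a
maximum permitted deviation" is implemented as a hard gate, since
"maximum permitted" indicates rejection; a greedy nearest-first mode exists
for cross-checks. Among admissible links, the assignment maximizes the
number of links and then minimizes total distance, solved globally with the
Hungarian algorithm; tests verify equality with exhaustive enumeration over
all injective assignments for ≤ 7 detections per frame. A zero-length
displacement has no direction and is always admissible. Gap closing is off
by default (`allow_gap_frames = 0`); when enabled, track ends may join later
track starts across up to that many missing frames, with the distance budget
scaled by the gap. Instantaneous velocity is ‖Δp‖ · pixel size / (Δframes ·
frame interval); frame intervals are user calibration — they are not
embedded in the original movies, so physical speeds always require an
explicit `frame_interval`.

## Synthetic scenes

The generator plants ground truth with the statistical structure each
readout assumes; its defaults are the study conditions used throughout the
tests:

- **Uptake scenes**: 50 cells (radius 5–8 µm) in a 200 × 200 µm field at
  0.5 µm/px, 50 protocells of diameter 2 µm, 40 % of cells loaded with 1–3
  protocells each, remaining protocells placed outside every cell with a
  clearance of at least one protocell radius; peak SNR 20. Cells are
  rendered as logistic-edged radial blobs (soft edges make the Otsu
  multiplier machinery meaningful); placement keeps a 7-px clearance between
  objects so that planted counts are recoverable exactly at SNR ≥ 20 — the
  scenes are built for test discrimination, not optical fidelity. "Inside"
  is defined geometrically at generation time (protocell center within the
  owner's boundary minus one protocell radius), so the truth is unambiguous
  under noise. Density presets `high/medium/low` (50/20/10 protocells per
  field) keep the 5 : 2 : 1 ratio of the injected titers
  (1.25×10⁷ / 5×10⁶ / 2.5×10⁶ protocells per µL).
- **Flow movies**: particles advance by exactly `v(t)·Δt` along a fixed
  direction, with `v(t) = v̄ (1 + a sin 2πft)`; defaults v̄ = 10 µm/s
  (red-blood-cell-like), a = 0.2, f = 2.5 Hz (heartbeat-like), Δt = 0.1 s.
  Particles leaving the field are removed and logged. Truth stores exact
  per-step displacements and speeds, so velocity recovery on noise-free
  detections is exact to floating point.
- **Section series**: slab cross-sections of a sphere or ellipsoid at depths
  (k+½)·thickness, rasterized at 0.5 µm/px; stain-positive masks pick a
  random pixel subset matching the requested fraction to within one pixel.
  The Cavalieri estimate of a 50 µm sphere at 10 µm sections carries the
  expected midpoint-rule error (≈ 0.4 %), shrinking ∝ thickness².
- **Pigment fields**: a smoothed random field thresholded at the requested
  quantile gives spatially coherent pigment patches with an exact dark-pixel
  count; dark (≈ 40) and bright (≈ 200) classes stay separable under the
  ± 3-intensity jitter.

Noise is Poisson shot plus Gaussian read noise with total standard deviation
peak/SNR at the peak signal, split evenly in variance; at SNR = ∞ the image
equals the noiseless render bitwise. One integer seed drives independent
substreams (cell placement, protocell placement, noise), so all outputs are
bitwise reproducible and adding protocells does not move cells.

What the synthetic scenes do **not** emulate: real point-spread functions
(blur is a logistic edge, not a measured PSF), vascular geometry,
photobleaching, autofluorescence, or depth-dependent attenuation. Passing
tests therefore demonstrate the correctness of the measurement code on data
satisfying its assumptions, not segmentation performance on real stacks —
on real data the threshold multiplier, minimum, and size filters must be
tuned per experiment, which is exactly why they are exposed.

## Numerical and interface choices

- 0-based pixel indices; voxel centers at integer coordinates; physical
  position = index × pixel size. Centroids and bounding boxes are reported
  in (x, y[, z]) order.
- Axis order of TIFF stacks is always declared (an ordered subset of
  `tzcyx`), either in metadata this package wrote or by the caller; nothing
  is guessed from shape heuristics. Missing or non-positive calibration is
  an error, never a default.
- Degenerate inputs raise typed errors: constant images under Otsu, zero
  first-timepoint areas, sections thicker than the solid, infeasible scene
  packing, empty regions.
- All CSVs carry a `#`-prefixed provenance header (version, config hash,
  seed) and full-precision numbers; rows keep input order.

## Problem sizes

The verification suite uses 200 random histograms for the Otsu oracle, 100
random masks (≤ 32³) at both connectivities for the labeling oracle, 10
scene seeds for uptake recovery, 200 random frame pairs (≤ 7 detections)
for assignment optimality, and 100-frame movies for velocity recovery —
sizes at which the brute-force oracles are exact and fast.

## Known limitations

- 3-D stacks are filtered per slice; fully 3-D windows are not offered.
- The watershed split assumes roughly convex objects; long concave cells
  would over-split.
- Tracking is 2-D (the source movies are 2-D projections) and has no motion
  model; dense crossing trajectories can swap identities within the gates.
- The containment rule uses protocell centroids; a protocell lying mostly
  inside a cell but with its centroid on a boundary voxel of background is
  counted outside.
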