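# Methods

This note documents the models, conventions and numerical choices
behind `scarquant`, in the spirit of a methods appendix: what each
stage computes, which decisions were genuinely open, and what the
synthetic tests do and do not demonstrate.

## Coordinate and format conventions

Voxel arrays are indexed `(slice, row, col)`, 0-based.  Contour
vertices and landmarks are continuous `(x, y)` pixel coordinates with
`x = col`, `y = row` and the pixel center at integer coordinates.
Angles are measured about the per-slice LV centroid (the area centroid
of the endocardial contour) as `atan2(y − cy, x − cx)`;
"counterclockwise" means increasing angle in this frame.  A pixel
belongs to a polygon iff its center passes an even-odd
(crossing-number) test; the center-in test alone decides boundary
pixels.  These conventions are enforced in one module (`imaging_io`)
and reused everywhere, because off-by-one drift between modules is the
dominant failure mode in this kind of geometry code.

Stacks are NIfTI-1 (header zooms carry the in-plane spacing and slice
thickness) or a directory of 16-bit PNG slices with a JSON geometry
sidecar; both round-trip 16-bit integer data losslessly.  Contours and
landmarks are small JSON documents (schemas in `imaging_io`).  DICOM
ingestion is out of scope for the pipeline core; convert to NIfTI
first.

## Intensity preprocessing

The preparation chain for learned detectors is center crop (default
160×160, offset `floor((dim−size)/2)`, odd remainders dropped
bottom/right), per-slice clipping of the brightest 2% of pixels
(threshold = 98th percentile, linear interpolation between order
statistics — pinning the percentile definition is what makes the clip
testable), standardization by dataset mean/SD (computed from the stack
when no dataset statistics are supplied), and rescaling to [0, 1].
The masked detector input is the voxelwise product of the preprocessed
BL stack and the rasterized LV wall.

The thresholding route instead uses an adaptive contrast stretch to
the 0–255 working scale: per slice, the window between the 1st and
99th intensity percentiles maps linearly onto [0, 255] with clamping.
Percentile stretching was chosen as the concrete realization of
"adaptive contrast optimization" because it is deterministic, robust
to outliers, and parameterized by two numbers.  Whether clipping and
stretching should be per-slice or per-volume is not externally fixed;
per-slice is the default (each short-axis image is processed on its
own terms) and both knobs are configurable.

Because BR and BL stacks are co-registered by acquisition, contour and
mask propagation between them is an identity coordinate transfer that
only validates the shared-geometry contract.

## Scar detection

**Multi-level Otsu.**  Three thresholds `0 ≤ t1 < t2 < t3 ≤ 255` are
chosen on a 256-bin histogram of the myocardial pixels (masking to the
wall is the default; whole-image mode exists) by maximizing the
between-class variance of the four resulting classes, equivalently
`Σ S_k²/W_k` over class weights `W` and intensity sums `S`.  The
search is exhaustive, so the result is a global maximizer; ties break
to the lexicographically smallest triple.  (Scanning only occupied
histogram bins is exact: any maximizer's thresholds reduce to occupied
bins without changing the partition, and no maximizer has an empty
class when ≥ 4 bins are occupied.)  Tissue classes: `v > t3` scar,
`t2 < v ≤ t3` gray zone, `v ≤ t2` healthy — three thresholds define
four intervals but black-blood suppression drives the lowest interval
toward zero signal, so the two lowest merge into healthy (a flag keeps
them separate).  Fewer than four distinct intensities is a degenerate
histogram and an error.

**Seeded region growing.**  Per slice, growth starts from a seed —
by default the gravity center of the largest 4-connected hyperintense
(scar-class) component, snapped to its nearest member pixel (Euclidean,
ties row-major); a wall-centroid seed would start in healthy tissue,
which is why the hyperintense component anchors it.  Each iteration
scans the 4-connected frontier restricted to the myocardium and admits
the pixel with minimal `|v − region mean|`, updating the mean after
every admission; growth stops when that minimal deviation exceeds
`max_deviation` or the wall component is exhausted.  Ties break on
`(row, col)`.  `max_deviation` defaults to 25 on the 0–255 scale: large
enough to absorb moderate noise inside dense scar, small enough that
the ~100-unit drop to gray zone or healthy signal halts growth; it is
exposed on the CLI because no externally fixed value exists.  Growth is
2-D per slice, matching the slice-wise processing of the rest of the
pipeline.

**External.**  A pre-computed mask or a callable `detector(pair, myo)`
fills the slot where a learned model would sit; the only contract is
containment in the myocardium.

## Quantification

**Levels.**  Slices containing myocardium are split into base / mid /
apex by index terciles, remainder assigned base-first (10 slices → 4/3/3);
`basal_first` states which end of the stack is basal, and an explicit
per-slice override wins.

**Sectors.**  For base and mid slices the two RV-insertion rays bound
the septal arc; its bisector splits it into two sectors and the
complementary arc is divided into four equal sectors (six total).  For
apical slices the two insertion rays and their reversals (the
landmark-to-centroid direction vectors, reversed) bound four sectors:
septal, inferior, lateral, anterior.  AHA numbering is anchored at the
anterior insertion ray and proceeds counterclockwise — base
2,3,4,5,6,1; mid 8,9,10,11,12,7; apex 14,15,16,13 — so segment 1/7 is
anterior and the septum lies between the insertions.  A pixel exactly
on a boundary angle belongs to the counterclockwise-following sector.
A 16-segment model is used throughout (no apical-cap segment); slices
whose endocardial contour vanishes are excluded from quantification.
Landmarks missing on a slice propagate from the nearest slice that has
them.

**Chords.**  Each quantified slice gets exactly 100 chords.  The
centerline is sampled at 100 angles equally spaced about the LV
centroid starting at the anterior insertion ray (equal-angle spacing
was chosen over arc-length spacing; it is the simpler convention and
the two coincide for near-circular walls).  The centerline point at
each angle is the midpoint of the endocardial and epicardial ray
intersections; each chord passes through its centerline point
perpendicular to the local centerline tangent (cyclic central
difference) and extends inward to the endocardium and outward to the
epicardium; thickness is the endo–epi distance times the in-plane
spacing.  Ray/chord–contour intersections use exact segment
intersection on the polygon (via shapely), nearest crossing first.

**Transmurality.**  Each chord is sampled at 0.25 px steps with
nearest-pixel mask lookup; transmurality is the ratio of scar samples
to wall samples along the chord — scar thickness over wall thickness
on the same discrete footing, so a transmural scar reads exactly 1.0.
(Dividing by all samples instead of wall samples systematically
under-reads transmural scars, because the endpoint samples of a chord
snap to pixels just outside the rasterized wall.)

**Global metrics.**  Volumes are pixel counts × voxel volume; scar
mass converts scar volume with the conventional myocardial density of
1.05 g/cm³ (configurable); extent is scar/myocardium volume in
percent; mean and max transmurality pool every chord of every
quantified slice.

## Reporting

`report.json` is the single source of truth; the HTML document and the
bullseye images are rendered from the same computed objects and never
recompute a number.  The 16-segment bullseye draws base/mid/apex as
three concentric rings on a fixed 0–100% viridis scale with numeric
labels (missing segments hatched); the chord bullseye draws one
100-bin ring per slice on a fixed [0, 1] scale.  Both renderers return
their serialized plot data for exact round-trip testing.  The default
timestamp is a fixed epoch string so identical inputs give
byte-identical reports; patient metadata defaults to anonymous.

## The phantom

The generator emulates the contrast regime the pipeline targets, not
MR physics.  Per slice the LV is a circular annulus (default endo/epi
radii 20/35 px on a 160×160, 1.5×1.5 mm grid, 8 mm slices, 12 slices);
contours are the exact circles used for rasterization.  On BL images
healthy wall spans a dark band (a deterministic radial gradient over
[5, 25], which keeps the histogram non-degenerate even without noise),
an optional peri-infarct gray-zone rim sits at 128, and scar is 255;
on BR images the blood pool is bright (230) and the wall mid-gray
(100).  Gaussian noise of configurable SD is added and the result
rounded and clipped to [0, 255].  Scars are annular sectors given by
slice, angular interval and a radial interval in wall-depth fractions,
so the true transmurality of every chord angle is known in closed
form; truth volumes are pixel counts of the rasterized truth masks, so
the analytic truth and a recomputation from the rasters agree exactly.
Landmarks sit on the epicardial circle at 60°/120° by default (60°
separation, mimicking septal insertion geometry).  The gray-zone
intensity (128) is an assumption — no external statistics exist for it
— and is flagged as such.

Because a scar sector's extent is `width/360 ×` the area fraction of
its radial interval, extent and transmurality cannot be dialed
independently; phantom grids are therefore parameterized by angular
width and transmurality.

What phantom tests show: exact bookkeeping (partition conservation,
volume arithmetic), correctness of the geometric engines against
independent oracles, and detector fidelity under the stated contrast
model.  What they do not show: performance on real LGE data with
partial-volume effects, surface-coil shading, misregistration, or
contours drawn by humans.

## Test problem sizes

Unit and acceptance tests use 96×96 phantoms with 6 (or 3) slices and
endo/epi radii 14/26 px; the acceptance script's demo case uses the
full 160×160 × 12-slice default.  The recovery grid is 3 angular
widths × 4 transmuralities × 2 noise levels (24 cases, extents
2.4–50%).  These sizes keep the whole suite around two minutes on one
CPU while leaving every per-slice quantity (chord count, sector
counts) at its clinical value.

## Known limitations

* **Three-category Otsu needs three clusters.**  On images that truly
  contain only two intensity populations (no gray zone) and where scar
  occupies close to half the wall, the four-class variance criterion
  places a split inside the scar cluster and the top-interval scar
  class under-segments (observed on two-cluster phantoms at extents
  ≥ ~46%).  This is a property of the classification scheme, not of
  the implementation; the recovery grid therefore uses the full
  three-tissue contrast model the scheme is defined over.  On real LGE
  data a peri-infarct intensity continuum is typically present.
* Region growing assumes one dominant scar per slice; disjoint scars
  need per-slice seeds.
* Chord construction assumes star-shaped contours about the LV
  centroid (true for LV short-axis anatomy); strongly non-convex
  contours can make a ray cross a contour more than once, in which
  case the nearest crossing is used.
* The centerline tangent uses a cyclic central difference over 100
  samples; for very eccentric walls the perpendicularity of chords is
  approximate at the 1–2° level.
* No 17-segment (apical cap) variant; chord spacing is equal-angle
  only (arc-length spacing is not implemented); no motion or
  misregistration handling.
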