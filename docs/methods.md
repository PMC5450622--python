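# Methods

This note records the models, conventions and numerical choices behind
`mansegkit`, in the order a session flows: stack → editing → metrics →
statistics → phantoms.

## Coordinates, units and stacks

One convention holds everywhere: voxel addresses are 0-based
`(x = column, y = row, z = slice)` with voxel centres at integer
coordinates; arrays are indexed `[y, x, z]`. Physical positions are
`(x·dx, y·dy, z·dz)` in micrometres. When a TIFF carries no geometry
and none is supplied, the fallback is the relative geometry
`(dx, dy, dz) = (1, 1, 2)` — the common confocal convention of a z-step
twice the in-plane pitch — and a warning is emitted, because every
downstream physical quantity depends on it.

Supported stacks are 8-, 12- and 16-bit unsigned grayscale; 12-bit data
travel in 16-bit containers with values validated against 4095, and the
declared depth is recorded in the TIFF ImageDescription tag so a bare
re-read recovers it.

## Editing semantics

**Freehand draw.** A contour is auto-closed and rasterized as: pixels
whose centre lies strictly inside the polygon under the even-odd
(crossing-number) rule, unioned with the 8-connected Bresenham trace of
every edge. Including the stroke guarantees that what the operator drew
is in the mask, and makes a degenerate (collinear) contour a thin line
rather than an error. Subpixel vertices are accepted; only
rasterization discretizes (half-up rounding, never banker's). Draws
accumulate by union, so drawing is monotone and idempotent.

**Undo.** A click removes the 8-connected **2-D** component under the
cursor on the clicked slice only. Removing the 3-D component instead
could silently destroy work on distant slices; the slice-local choice
is the conservative reading of a per-slice editing UI. A background
click warns and does nothing — a missed click should not corrupt state.

**Split.** The drawn line is rasterized 4-connected (Bresenham with
diagonal steps bridged). This matters: by the duality of 4- and
8-connectivity, only a 4-connected cut actually separates 8-connected
regions; an 8-connected line leaves diagonal leaks. The severed halves
stay in the same object — splitting separates structures, it does not
relabel them. The polyline is not auto-closed.

**Timer.** In headless replay, time comes from script timestamps, never
the wall clock, so sessions are bit-reproducible. Time accrues to the
active object while the timer runs; creating an object starts the
timer, pause/resume gate it, selecting another object redirects
subsequent time, and a script that ends while running is closed at its
final timestamp. Elapsed time is stored as integer milliseconds.

**Persistence.** A session saves to a zip container: `manifest.json`
(dims, geometry, per-object names and elapsed milliseconds, format
version) plus one multi-page 0/255 TIFF mask per object and optional
PLY meshes. The round trip is lossless for masks, names and times.

## Isosurface extraction and morphometry

Surfaces are marching-cubes isosurfaces, but not of the raw 0/1 volume:
contouring a binary volume yields a staircase surface whose area
overestimates a smooth object's by a scale-independent ~9% (measured on
digital balls here), even though its volume is nearly unbiased. The
mesh is therefore extracted at the zero level of a regularized signed
distance field:

1. pad the mask with background (meshes stay closed at stack borders);
2. SDF = EDT(mask) − EDT(background), physical-unit sampling;
3. Gaussian-smooth with σ = 1.2 voxels (suppresses the staircase);
4. subtract the first-order smoothing bias in one inverse-diffusion
   step, `f ← f − (σ²/2)∇²f` (plain smoothing shifts the level set
   inward by ≈ σ²·curvature, visibly shrinking thin structures);
5. clamp the field slightly positive at any foreground voxel the
   smoothing drove non-positive, so no mask voxel ever vanishes — a
   single isolated voxel still produces a small closed mesh.

On digital balls of radius 10–25 voxels this keeps mesh volume within
2% and area within 3% of the sphere closed forms (the acceptance suite
measures both). `smoothing_sigma=0` falls back to the plain binary
isosurface for users who want the classic behaviour. Mesh volume is the
absolute signed-tetrahedron sum and requires a closed mesh (every edge
on exactly two faces); an open mesh is an error naming the defect.
Voxel-count volume `N·dx·dy·dz` is always reported alongside as a
smoothing-free consistency check. Anisotropic geometries are handled by
physical-unit EDT sampling, but the smoothing and de-bias operate in
index space, so the regularization is approximate off-isotropy; the
voxel volume is the authoritative number for strongly anisotropic thin
structures.

## Gray-level Uniformity

The GU index implemented here is the variance-based, range-normalized
two-region form: `GU = 1 − Σⱼ wⱼσⱼ²/σ_norm²` with
`σ_norm² = ((f_max−f_min)/2)²` over the whole stack, weights
`wⱼ = |Rⱼ|/|Ω|`, population variances, regions = foreground and
background. It is bounded in [0, 1], equals 1 for a constant stack or a
perfectly two-level segmentation, and is invariant under affine
intensity rescaling. Because several monotone-equivalent GU variants
circulate, a foreground-only variant (background term dropped, same
weighting) is emitted alongside; any of them supports the same
rank-based inter-rater workflow. The exact formula constant is fixed
here so results are comparable across runs.

## Skeletons and Sholl analysis

Skeletonization is topology-preserving 3-D medial-axis thinning
(scikit-image's implementation of the standard parallel thinning
algorithm), so component counts are preserved and skeleton voxels are a
subset of the mask. The skeleton becomes a graph over 26-adjacent voxel
pairs.

A Sholl intersection is an **edge crossing**: edge (u, v) with
`d(u) ≤ d(v)` crosses radius r iff `d(u) < r ≤ d(v)`, distances in
physical micrometres from the centre. The rule is parameter-free,
matches the geometric meaning of a neurite piercing a sphere, counts a
tangent path touching from inside zero times, and admits an exact
brute-force oracle (walk every edge, test interval containment) used in
the tests. A voxel exactly on a sphere is assigned outward.

The default centre is the argmax of the anisotropic distance-to-
background transform — the thickest point of the object, a robust proxy
for the soma an operator would otherwise click — with ties broken
toward the smallest (z, y, x) and an explicit override available.
Default radii run from `max(dx, dy)` to the skeleton's maximal centre
distance in steps of `2·max(dx, dy)`.

The log-log fit regresses `log₁₀(N(r)/(4/3 π r³))` on `log₁₀ r` by
ordinary least squares over radii with nonzero counts (log of zero is
undefined, so empty shells are excluded). A constant-count profile
fits slope −3 exactly; counts growing like r³ fit slope 0.

## SWC matching

SWC files are the standard 7-column text format; parsing validates
field count, numeric fields, unique ids, resolvable parents and
acyclicity. Points of interest are roots, bifurcations (≥ 2 children)
and end-points (0 children), deduplicated by id; an `all`-nodes mode
exists because reference sets differ between workflows.

Matching selects, per reference point, the candidate minimizing the
full 3-D Euclidean distance — ties broken toward the smallest
(z, y, x) so results are deterministic — then checks
`d_xy = √(Δx²+Δy²)` and `d_z = |Δz|` separately against thresholds
stated in raw pixel/slice units (defaults 4.76 px and 17 slices, the
published thresholds for the neocortical layer-1 axon dataset of the
DIADEM challenge). Distances are deliberately **unscaled** by voxel
geometry because the thresholds are stated in pixels; SWC coordinates
are assumed to be in the stack's pixel/slice frame. Candidates default
to all foreground voxels of the segmented object; a skeleton-voxel
option trades completeness for speed and is recorded in the report.
Percentages are rounded half-up to two decimals.

## Friedman test

Within each block (neuron, or Sholl radius) the k raters receive
mid-ranks; the statistic is `χ²_F = 12/(nk(k+1)) Σⱼ Rⱼ² − 3n(k+1)`
divided by the tie-correction factor
`1 − Σ(t³−t)/(nk(k²−1))`; a fully tied table short-circuits to
statistic 0, p = 1. The p-value is the χ² upper tail on k−1 degrees of
freedom — the standard choice for this workflow's scale. The exact
permutation distribution is very discrete at n ≤ 5 blocks, so the
asymptotic p can differ noticeably from the exact p there; the test
suite therefore validates the statistic against exact enumeration over
all within-block permutations at small n, and the p-value against a
Monte-Carlo permutation p at n = 20 where the asymptote applies. For
Sholl comparisons, blocks are radii and treatments are raters, one test
per neuron; radii missing in any rater's profile are dropped listwise.

## Phantoms

The generator emulates the kind of acquisition this tooling targets: a
fluorescent neuron in a clarified-tissue confocal stack. Defaults are
chosen once as the package's study conditions:

| parameter | default | why |
|---|---|---|
| geometry | (0.62, 0.62, 1.24) µm | 40× confocal pixel pitch; z-step = 2× in-plane |
| dims | 128 × 128 × 64 | desk-scale working size; in-plane acquisition matrices are typically 512² |
| n_bifurcations | 3 | small binary arbor: 3 bifurcations, 4 end-points |
| segment length | 12–25 µm | dendritic internode scale |
| tube radius | 1.2–2.0 µm | neurite calibre at this resolution |
| soma radius | 5 µm | clearly thicker than any neurite, so the EDT centre lands in it |
| PSF σ | (0.62, 0.62, 1.24) µm | ≈ 1 voxel per axis, z-elongated like a confocal PSF |
| levels / noise | 30 / 200, σ = 10 (8-bit) | high-contrast fluorescence with moderate shot-like noise |

The tree grows from the volume centre with direction jitter around the
parent heading; exactly `n_bifurcations` tips split (binary tree ⇒
leaves = bifurcations + 1); segments that would leave the volume are
redrawn up to 100 times before the generator refuses. Ground truth is
the union of capsules (cylinders with spherical caps, radii linearly
interpolated between nodes) tested against voxel centres in physical
units — exact, resolution-independent, and analytically checkable
(single-capsule volume `πr²L + 4/3πr³`; overlapping unions are
integrated on a 3× finer grid in the tests). Rendering is plateau
intensities → anisotropic Gaussian blur → additive Gaussian noise →
clip and quantize; everything is deterministic given the seed. SWC
output uses pixel/slice coordinates (the matching module's frame) with
radii in in-plane pixel units.

What the phantom does **not** emulate: Poisson photon statistics,
depth-dependent attenuation and scattering, spectral bleed-through,
realistic cell-type-specific arbor statistics, or imaging artifacts
that make real manual segmentation hard (touching neighbours, gaps in
labelling). Passing the phantom pipeline therefore demonstrates the
correctness of the machinery — rasterization, replay, measurement,
matching — not segmentation difficulty on real tissue.

## Degenerate inputs and tie-breaks, collected

- Polygon with < 3 vertices: error; collinear polygon: boundary trace.
- Split with < 2 points: error; split over background: no-op.
- Undo on background: warned no-op. Click outside the image: error.
- Empty mask: error for meshing, skeletonization and soma location;
  volume 0 for voxel counting.
- Constant stack: GU = 1 by convention (σ_norm = 0 never divides).
- Sholl fit with < 2 nonzero radii: error.
- All rounding of coordinates is half-up; all spatial tie-breaks are
  lexicographic smallest (z, y, x).

## Known limitations

- The isosurface regularization is tuned in index space; for strongly
  anisotropic voxels, mesh area inherits an approximation error and the
  voxel volume should be preferred for thin structures.
- Features at the 1-voxel scale survive meshing (the foreground guard)
  but their mesh area/volume are below the method's resolution.
- The Friedman p is asymptotic; for n < 6 blocks, exact tables or
  permutation p-values are preferable if decisions ride on p near the
  threshold.
- The matching metric is the nearest-point simplification: it scores
  geometry only and is blind to topology (a broken-but-nearby tracing
  can score perfectly); the full topology-aware DIADEM metric is out of
  scope.
- Sessions hold boolean volumes in memory; stacks beyond ~10⁹ voxels
  per object are impractical.
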