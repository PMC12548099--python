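# Methods

## Scan-to-space model

The scanner is modeled as a pencil of rays through a single pivot. A voxel
index `(fast, slow, depth)` (0-based, fractional allowed) maps to the
physical point `d(α, β) · (pivot_offset_mm + depth·depth_step_mm)`, where
`α = (fast/(n_fast−1) − ½)·fov_fast_deg` (β analogous) and the unit
direction is obtained by rotating the central axis (+z) first by α about
the slow axis, then by β about the fast axis:

    d(α, β) = (sin α, −sin β cos α, cos β cos α)

The device's true scan-to-space calibration is not public, so the
transform is fully parameterized in a sidecar file (counts, FOV, depth
step, pivot offset) and alternate calibrations can be swapped in without
code changes. The transform is injective over the grid, adjacent indices
are equiangular, and points on one ray are spaced exactly one depth step
apart — these invariants are property-tested.

Axial length is estimated from the radial RPE distance at the fovea
through an affine calibration `AL = al_scale·r_fovea + al_offset_mm`. Two
profiles matter: the phantom ("central pivot") profile has the pivot at
the globe center, where `al_scale = 2` is exact; for clinical devices the
pair is a calibration input, and `al_offset_mm` absorbs the unknown
anterior-segment contribution rather than guessing it. A measured AL
supplied as metadata always takes precedence over the estimate.

## Surface extraction

Input volumes carry labels {0 background, 1 retina, 2 choroid}. The
segmentation has no explicit RPE class, so the RPE is defined as the
half-voxel interface between the last retina and first choroid voxel on
each A-scan (`z = first_choroid − 0.5`): the retina/choroid boundary is
the layer whose height is stable as disease thickens the inner retina.
Columns lacking either tissue are invalid. Columns with several retina
runs (segmentation noise) use the last retina→choroid transition and are
counted in a QC field; a retina voxel *after* the first choroid voxel is
an ordering violation and raises. Retinal thickness is counted along the
ray (voxels × depth step), matching per-A-scan depth maps; this
overestimates true perpendicular thickness on tilted retina and is
documented as an approximation. En face images are per-column maxima.

## Landmarks, border chains, sampling

The three manual annotations — disc-edge points, foveal center, border
points — are connected with integer Bresenham rasterization into
8-connected cell chains (the disc edge closed into a loop) and lifted to
3D at each cell's RPE depth; cells on invalid columns borrow the nearest
valid depth within 5 cells (configurable). The disc centroid is the
unweighted mean of the 3D edge-chain points (the filled-region centroid
was considered and rejected: the chain is what the annotation defines;
the difference is well under the disc radius for convex discs).

"Evenly spaced points per clock hour" is implemented as even in *en-face
bearing* about the disc center — clock hours are an angular unit about
the disc — not even in chain arclength. Bearings are unwrapped about the
fovea's bearing; the temporal hemisphere is the 180° half-plane
containing the fovea; sample bearings step every `30/density`° (density
10 by default) from the covered interval's start, half-open at the far
end, each sample taking the chain cell nearest in bearing. A border with
gaps is handled as a list of chains: coverage is the union, sampling runs
per chain. The assessed angle is the covered temporal extent, capped at
180°. Laterality tags affect reporting only, not geometry.

## Geodesics

Valid columns, lifted to 3D, form graph nodes; edges join each node to
its 16-neighborhood (8-neighborhood optional) with Euclidean chord
weights. Endpoints are spliced in at their exact 3D positions via chords
to the valid columns in a footprint around their en-face projection (the
footprint doubles from 2 cells until non-empty, capped at 10) — this is
how the disc centroid, which lies slightly below the surface, enters the
graph. Dijkstra gives shortest paths; their lengths overestimate true
geodesics by up to ~2.8% (16-neighborhood metrication).

The graph path is then straightened: resampled and smoothed on a
coarse-to-fine ladder (6→12→24→48 interior vertices), each pass replacing
every interior vertex with the surface projection (along its pivot ray,
bilinear in the radius field) of its neighbors' midpoint, stopping when
the length decrease falls below 1e-10 mm. This curve-shortening flow
converges to a geodesic of the interpolated surface; on phantom spheres
the residual is ~5·10⁻⁵ relative, and end-to-end phantom errors fall
under 1% at the 400×400 working grid. Every reported length is a polyline
between the exact endpoints, hence never below the straight-line
distance; `geodesic_distance` canonicalizes endpoint order so symmetry is
exact. The disc-to-fovea distance (FD) is measured geodesically for
consistency with the arclengths; the straight-line chord is retained in
the output (`fd_chord_mm`) for comparison.

One caution: where the surface has invalid holes, the projection uses the
nearest valid radius, so a straightened path may cross a hole as if the
surface were continued flat across it. Across the disc cap this is the
intended behavior; across large peripheral dropouts it will shorten paths.

## Biomarkers

`mean-RAL`/`min-RAL` are the unweighted mean and minimum of the retained
samples. AVR uses the cap formula **verbatim**:
`(π·AL²/2)·(1 − cos(meanRAL/AL))`. Note the internal inconsistency: the
angle `meanRAL/AL` treats AL as a radius while the prefactor `π·AL²/2`
treats it as a diameter; no geometric correction is applied, because the
published group-mean areas are reproduced only by the verbatim form (to
within 2% when evaluated at group means — Jensen's inequality accounts
for the residual, since group means enter a nonlinear formula). The
geometric reference `true_cap_area(r, s) = 2πr²(1 − cos(s/r))` is
provided separately for phantom work.

Zone labels use the ICROP constructions with strict inequalities: zone I
iff `min-RAL < 2·FD`; posterior zone II while `min-RAL < 2·FD + 2·DD`;
otherwise "II+". The disc diameter DD is a required parameter (default
1.1 mm, configurable) because no per-eye value is published; phantoms use
their own configured disc size on both sides of the comparison.

## Phantom

The phantom is a sphere of radius R ∈ [7, 9] mm centered on the pivot
(AL = 2R spans the 15.2–16.0 mm range reported for infant eyes), with a
retina shell of 0.20 mm and choroid of 0.15 mm; the retina thickens by
0.10 mm in a 2° band along the border to emulate the ROP ridge (the ridge
exists to exercise thickness maps — the border is annotated directly, as
clinicians do). The disc pole sits 25° off the scan axis so border radii
up to 90° stay inside the 140° FOV; the fovea lies 28.3° temporal of the
disc (FD = 3.80 mm at R = 7.7, echoing the clinical worked case); the
border is a base angular radius (default 60°, spanning 70° of bearing,
giving the reported mean assessed angle) minus an optional raised-cosine
notch. The taper keeps the border a continuous curve — a rectangular
notch would create radial walls whose rasterization has no closed-form
bearing map — while still attaining full depth at the notch center, so
the zone-flip threshold stays closed form.

Ground truth: FD = R·θ_fovea and RAL(bearing) = R·θ_border exactly.
Because the pipeline samples evenly in en-face bearing, truth reproduces
that sampling design analytically — the exact direction→index mapping
takes the border locus to the en-face plane, sample bearings are laid on
the covered interval, and each maps back to its spherical bearing — using
no pipeline objects. Landmarks are emitted at exact (fractional) grid
projections of the configured loci. Segmentation noise shifts each tissue
interface by ±1 voxel with a configurable per-column probability,
mimicking boundary uncertainty rather than salt-and-pepper error.
Everything is deterministic given the seed.

What phantom tests do **not** show: real eyes are not spheres, real
segmentations have spatially correlated errors and dropouts, and real
scan pivots are not at the globe center (so clinical AL calibration and
geodesic behavior off the calibrated profile are untested against truth).

## Cohort simulator and statistics

The simulator emulates the eye-level structure of a screening cohort at
first ROP diagnosis: a latent patient severity assigns zone by thresholds
matching the configured mix (default 18/5/29 patients over zones
I/PII/II); gestational age, birthweight and postmenstrual age are
patient-level per-zone normals (defaults 24.1/24.2/27.8 wk,
557.9/605.0/964.6 g, 33.3/32.6/35.9 wk); per-eye mean-RAL shares a
patient random effect with intra-class correlation 0.8 (not reported
anywhere; a stated assumption, configurable) around per-zone means
10.3/11.9/14.8 mm; min-RAL is the mean minus a positive offset; treatment
is Bernoulli with logit `10.2 − 0.95·meanRAL`, calibrated to the reported
per-zone treatment rates (62%/33%/0%).

AUROC uses the Mann–Whitney pair-counting form (ties ½), equal to
trapezoidal ROC integration with tie handling and exactly invariant under
monotone score transforms. The cluster bootstrap resamples patients with
replacement (2000 replicates by default), recomputes the statistic on the
concatenated eyes, and reports percentile 2.5/97.5 CIs (BCa was judged
unnecessary at these cluster counts). Replicate r draws from the r-th
spawned child of the seed sequence, so results are independent of
evaluation order; replicates with an undefined statistic (single outcome
class) are redrawn within their own stream and counted, and the analysis
aborts if more than half the replicates need redraws. Predictor pairs are
compared on the same resampled eyes (paired differences); significance is
read as the 95% CI excluding zero, the natural reading for a bootstrap
comparison. Coverage is validated in the test suite: over 300 simulated
two-eye cohorts (100 patients, known binormal AUROC 0.75, 500 replicates)
empirical 95% CI coverage is within 3 points of nominal. ANOVA and GEE
are deliberately delegated to standard statistical tooling; the package
exports the tidy eye-level CSV those tools consume.

## Problem sizes and numerical choices

Phantom validation runs a 3 radii × 4 border angles × {notch, no notch}
grid at a 400×400 en-face grid (0.02 mm depth step), with tolerances 3%
for FD/mean-RAL/min-RAL and 5% for AVR; mesh convergence is checked on
mean error over a phantom sample at 100/200/400. The depth quantization
floor is half a depth step (0.01 mm); en-face quantization enters through
annotation rounding and splice footprints and shrinks linearly with grid
size. Unit tests use 120–200 grids where closed forms, not convergence,
are under test. Ties in nearest-bearing sampling resolve to the first
minimal cell; zone boundaries are strict inequalities; degenerate inputs
(empty RAL arrays, single-class outcomes, zero-variance correlations,
disconnected surface components) raise typed errors rather than returning
sentinels.
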