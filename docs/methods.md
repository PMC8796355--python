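# Methods

This note documents the measurement model implemented by `cupcov`, the
choices made where the procedure was genuinely open, the synthetic phantom
the pipeline is validated on, and the limits of what those validations
show.

## Coordinate frame

The reference frame is the anterior pelvic plane (APP).  Four landmarks
over-determine a plane, so the coronal plane is taken exactly through three
points: both anterior-superior iliac spines (ASIS) and the *midpoint* of
the pubic tubercles.  The sagittal plane passes through the tubercle
midpoint perpendicular to the coronal plane with its normal along the
inter-ASIS direction; the horizontal plane is perpendicular to both.  Axes:
lateral (toward the study side), anterior, superior; origin at the tubercle
midpoint.  Pelvic tilt is deliberately not corrected — the APP itself is
the measurement reference, which is the stated convention of the planning
workflow this package models, and a known limitation of it.

Frame construction is equivariant under rigid motion of the landmarks, and
mirroring left/right flips only the lateral axis.

## Cup model and orientation

Two 44-mm hemispherical shells are modelled: the standard 4-mm-wall
implant, and a 0.01-mm "eggshell" whose outer surface is the uncoverage
measurement surface.  The measurement surface is the outer hemisphere only
(no rim annulus, no inner surface).  The hemisphere is triangulated on a
latitude/longitude grid with an apex fan; subdivision level k gives 3·2^k
colatitude rings (default k = 3, 4 512 facets, ~1.4 mm facets); the surface
area converges to 2πr² from below as k grows.

Orientation uses the radiographic convention: abduction (inclination) is
the angle between the longitudinal axis and the coronal-plane projection of
the cup's polar axis; anteversion is the angle between the polar axis and
the coronal plane.  The polar axis (pointing out of the opening) in
(lateral, anterior, superior) coordinates is
u = (cos RA·sin RI, sin RA, −cos RA·cos RI).  The angles are fixed at
45°/20°: the ±1° quoted for manual implantation is an execution tolerance,
not a parameter sweep.  Both angles are exposed in the run configuration.

## Placement

The implantation rules — medialize until the shell abuts the medial wall,
front edge tangent to the anterior wall, lower edge tangent to the
transverse ligament — describe a manual procedure.  The reproducible
algorithm used here:

1. **Seating.**  The cup translates along −u (its own polar axis, the
   reaming/insertion direction, whose dominant component is medial) from a
   start position outside the bone above the rim-landmark centroid.  The
   exact first-contact depth is the minimum, over outer-surface sample
   points, of the ray-cast entry distance into bone along −u — the limit
   of an infinitesimally fine step march.  Contact is detected on the dome
   cap (within ~53° of the apex) only: a ray nearly tangent to the socket
   wall amplifies surface-tessellation noise by 1/|n·u| and cannot localize
   contact; on a tessellated congruent socket this restriction changes the
   seat by < 0.03 mm while using near-rim rays mis-seats by ~0.1 mm.
2. **Tangency.**  The rim point nearest the anterior-wall landmark is
   matched to it along the anterior axis, and the inferior-most rim point
   to the transverse-ligament landmark along the superior axis, by
   coordinate descent in the plane perpendicular to u (so in-plane moves do
   not change the seating depth), re-seating after each correction, until
   both residuals are below `tol_mm` (default 0.2 mm) or `max_iter` is
   reached — in which case the placement *fails with the residuals listed*
   rather than silently accepting an infeasible configuration.  The three
   rules can over-determine the pose; surfacing the residuals is this
   package's resolution of that ambiguity.
3. **Diagnostics.**  The medial-contact constraint is reported active when
   advancing a further `step_mm` (default 0.1 mm) along −u drives sample
   points strictly into bone.  The converged pose, residuals and active
   constraints are recorded per hip.

"Tangent to the transverse ligament" is operationalized as matching
superior coordinates of the inferior rim point and the ligament landmark:
the ligament is a point in the data model, not a surface.

## Coverage and quadrants

A facet of the eggshell outer surface is covered iff its centroid is inside
host bone or within ε of the bone surface (`eps_mm`, default 0.1).  The
default absorbs CT-scale surface discretization (~0.5-mm facets) without
inventing coverage; whether the original Mimics-based measurement counted
sub-millimetre gaps as covered is unknowable, so ε is exposed in the
configuration.  Membership is a ray-parity test (a point is inside a
watertight mesh iff a ray from it crosses the surface an odd number of
times), with a random re-cast whenever a hit grazes an edge/vertex or a
near-parallel facet; surface distance uses exact point-triangle distances
on KD-tree candidate sets.

The quadrant system lifts the classic 2-D screw-zone construction to 3-D.
The quadrantal sagittal plane passes through both ASIS and the seated cup
centre (positive side anterior).  The 2-D perpendicular axis lifts
ambiguously to 3-D; this package fixes the quadrantal horizontal plane's
normal as the ipsilateral-ASIS → cup-centre direction (positive side
inferior), which makes it perpendicular to the quadrantal sagittal plane by
construction, since both of those points lie in it.  Facets are assigned to
A-S / A-I / P-S / P-I by the signs of their centroid's distances to the two
planes; centroids within 1e-9 mm of a plane go to the anterior/superior
side (deterministic, measure-zero).  Segmental ratios divide by the *total*
cup area, so they sum exactly to the TUCR (the reference cohort's printed
segmental means, 0.0832+0.0521+0.1012+0.0592 = 0.2957 against a printed
TUCR of 0.2958, confirm that denominator convention).

With the centroid rule the classification bias vanishes under refinement;
TUCR changes by well under 0.01 between subdivision levels 3 and 4 on all
fixtures, and matches the spherical-zone closed form and a 10⁶-point
Monte-Carlo oracle within 0.01 on planar-wall fixtures.

## Morphometrics

* **Height H**: perpendicular distance from the most superior *rim
  landmark* to the plane parallel to the horizontal plane through the
  acetabular lower-edge landmark, via the textbook point-plane formula.
  The rim landmark set is used rather than a mesh search because on a full
  hemipelvis the global superior extreme is the iliac crest.
* **A-P diameter R**: the bone surface is cut by the horizontal plane at
  ½H above the lower edge (an exact plane section, whose piecewise-linear
  error is far below the 0.5-mm CT slice thickness the slab convention
  mimics); R is the anterior-axis extent of the section restricted to the
  socket neighbourhood — within one cup radius (+0.3 mm margin) of the
  seated cup centre and on the bone side of the cup opening plane.
  Anchoring the region at the seated cup (the pipeline seats before it
  measures) is this package's deterministic stand-in for the manual region
  selection of the original workflow; landmark-anchored selection proved
  non-robust for tail-of-distribution anatomies.  H = 0 (all rim points at
  the lower-edge level) is reported as degenerate rather than an error.
* **Volume proxy V = H·R·R**: the printed planning formula, implemented
  literally without a conic shape constant.  It is a proxy, not a
  volumetric integral, and is reported as such.

## Statistics

Pearson r with simple linear regression (R² = r² — an identity for simple
regression, asserted to 1e-12), two-sided p from the t-transform with n−2
degrees of freedom; one-sample Kolmogorov–Smirnov against a normal with the
*sample* mean/SD, as the analysis plan names it — estimating the parameters
inflates the p-value (the Lilliefors caveat), which is documented rather
than silently substituted; Welch's t for the TUCR ≤ 0.3 vs > 0.3 group
comparison (the plan names no test; the groups are unequal and variance
equality unverified; the type-I error is calibrated to 0.05 ± 0.01 over
5 000 null simulations in the acceptance suite).  Zero-variance inputs
raise a typed error in the low-level functions and are reported as
"n/a" cells by the cohort summary.  Descriptives report mean, SD, observed
range, *and* mean ± 1.96·SD/√n, each labelled — the reference table's
"95 % CI" parentheses match data ranges for several variables, so no single
interpretation is imposed.  No multiple-testing correction is applied
(matching the plan; the report footer says so), and bilateral hips are
treated as independent records.

## The synthetic phantom

The generator builds a *socket block*, not an anatomical hemipelvis:

    bone = block ∩ {below the cup opening plane}
           − cup-congruent ball (the pre-reamed seat)
           − per-quadrant deficiency windows

A window is a radial wedge of the sphere's direction space adjacent to the
rim — {colatitude ≥ α_Q} within quadrant Q — with a flat floor 3 mm behind
the cup dome, mimicking peripheral dysplastic wall loss rather than random
holes.  α_Q is chosen so the window removes the requested fraction f_Q of
quadrant Q's cup area (solved on a 200 000-direction quasi-uniform sample).
Ground truth is evaluated on a 50 000-direction probe, so the stored
segmental truths carry ~2·10⁻³ sampling resolution.

The solid is meshed by marching cubes on an implicit CSG field (default
1.0-mm voxels; the grid origin carries an irrational sub-voxel offset so
flat faces never coincide with grid nodes, which would produce degenerate
triangles).  Marching cubes chamfers the sharp window edges by a fraction
of a voxel, systematically widening every window; `generate_hip` therefore
runs one to three calibration passes — classifying the direction probe
against the *actual* meshed phantom with the default coverage ε and
re-carving with adjusted window sizes — until the realized deficiency
matches the request within 0.0035.  The phantom is thus calibrated at the
default ε = 0.1 mm.

Landmarks: the anterior-wall and transverse-ligament points are the most
anterior and most inferior points of the true cup rim (so the tangency
rules are consistent with the construction).  The rim ring is a set of
twelve *measurement fiducials* on a tilted ellipse placed so that (a) the
landmark-based height equals the target H exactly and (b) the ½H section
of the carved socket has A-P extent equal to the target R (the section
circle radius R/2 sits √(r²−R²/4) above the cup centre).  The fiducials do
not lie on the carved (pre-reamed) surface — they encode what a clinician
would digitize on the native socket, which the reaming has replaced.  Two
2.5-mm wall patches at the ring's anterior/posterior extremes are kept out
of the windows so R stays measurable; a requested f_Q beyond the guarded
capacity of its quadrant (reachable only by hand-built parameters, not
cohort draws) drops the guard for that quadrant, trading R accuracy for
the requested deficiency.

Feasibility: R targets above ~38.5 mm are rejected — the ring's extremes
would rise above the cup opening plane and could not be carved.  An all-f=1
request removes the entire wall; the cup then seats tangent to the flat
window floor and the measured TUCR is ~1 minus a sub-0.005 tangent patch.

**Cohort generator.**  H ~ N(31.99, 4.09) and R ~ N(25.23, 4.82) mm,
truncated at ±3 SD within [15, 50] and [15, 38.5] respectively.  The
deficiency fractions are drawn from a Gaussian copula: latent standard
normals with correlation 0.5 between the P-S and P-I coordinates (enough
to demonstrate the positive P-SUCR–P-IUCR association qualitatively,
without claiming to reproduce its magnitude), each mapped through its own
[0, 0.8]-truncated normal marginal.  The marginal parent parameters are
solved so the *truncated* mean and SD of each segmental ratio (f_Q times
the quadrant's area share w_Q) match the reference cohort moments.  The
draw ceiling of 0.8 keeps every sampled hip below the guard-patch capacity.

Two feasibility limits are accepted and visible in the emulated moments:
the anterior-superior quadrant holds only ~15 % of the cup area under this
quadrant geometry, so the reference A-SUCR spread (SD 0.0427) is not
representable by a truncated normal on the available support — the A-S mean
is matched exactly and its SD is ~25 % short, which also leaves the cohort
TUCR SD ~10–15 % below the reference 0.1003.  The reference per-quadrant
distributions are in any case free parameters of the generator, not
estimates of the patient cohort.

**What the phantom does not emulate:** real cortical/trabecular texture,
false-acetabulum anatomy, segmentation noise, landmark digitization error,
inter-patient pelvis shape variation beyond the H/R/f parameters, and any
femoral-side structure.  Passing the recovery tests therefore demonstrates
the *pipeline's* correctness on geometry with known truth — not the
clinical accuracy of coverage prediction on patient CTs.

## Numerical choices

* All coordinates in millimetres; 0-based vertex indices; STL round-trips
  within 1e-6 mm.
* Planes are normalized at construction; the distance formula still divides
  by √(a²+b²+c²) so raw coefficients work too.
* Ray-parity edge tolerance 1e-9 mm² on the 2-D edge functions; degenerate
  hits re-cast along a seeded random direction (≤ 8 attempts).
* Seating uses the level-3 direction sample restricted to the dome cap;
  placement defaults: step 0.1 mm, tolerance 0.2 mm, 50 iterations, 120-mm
  search box.
* Quadrant tie-break: anterior/superior side at |signed distance| < 1e-9.
* The pipeline is deterministic given (config, seed); cohort child seeds
  derive from the master seed and stay below 2³¹.

## Problem sizes used in validation

The test suite validates parameter recovery on a 20-hip cohort (segmental
UCRs within 0.01, H and R within 0.5 mm, cup centre within 0.2 mm) and
rigid-motion invariance over 10 random motions; `scripts/acceptance.py`
simulates a 90-hip cohort for the moment estimates (the generating
distributions are the reference conditions; a larger cohort only tightens
the estimate of the same conditions).

## Known limitations

* The "posterior-superior migration" of the rotation centre reported for
  undersized sockets has no unambiguous analogue in the phantom (its rim
  ring is a fiducial ellipse, not a native socket surface), so it is
  documented here rather than asserted as a test.
* The marching-cubes rim edge erodes ~0.4 mm of the 90° socket-rim wedge,
  so a phantom with *zero* requested deficiency still measures a TUCR of
  ~0.01 concentrated at the rim (per-segment < 0.005); windowed phantoms
  absorb this in the window calibration.
* K-S normality p-values are anti-conservative (estimated parameters).
* The eggshell measurement counts bone within ε regardless of which side
  of the shell it lies on; with a 0.01-mm shell this is immaterial.
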