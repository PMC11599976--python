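# Methods

This note documents the measurement model, the synthetic validation
phantom, the numerical choices and the known limitations of `femur3d`.

## Coordinate conventions and the measured frame

All computations are intrinsic: no scanner axes are used anywhere.  The
measured frame is built from the bone itself:

* the **anatomical axis** â points proximal (disambiguated by the head
  seed);
* the **distal joint line** (transcondylar tangent) points lateral; its
  projection orthogonal to â is the **mediolateral** unit vector m̂;
* the **craniocaudal** vector is ĉ = â × m̂ for a right femur and
  −(â × m̂) for a left one, so anteversion is positive for either side.

The frontal plane has normal ĉ, the axial plane normal â.  With n̂ the
head–neck direction (pointing into the head):

* aLDFA = ∠(â, ĵ) projected into the frontal plane, ĵ the lateral
  joint-line direction — 90° plus the frontal varus angle;
* FNA = ∠(n̂, −â) projected into the frontal plane;
* FTA = atan2(n̂·ĉ, n̂·(−m̂)) — the signed axial angle of the neck from
  the medial direction, positive cranial (anteversion), negative caudal
  (retroversion; surfaced, never clamped).

These projection definitions reproduce the ranges reported for canine
femurs (aLDFA ≈ 89–114°, FNA ≈ 117–143°, FTA ≈ 8–50°).

## Pipeline stages and parameters

**Shell cleaning.**  Segmented cortical bone often contains an inner
(endosteal/medullary) shell.  Only the connected component with the
largest surface area is kept — area rather than vertex count, because
inner and outer shells may be meshed at different resolutions.

**Anatomical axis.**  Cross-sections are taken perpendicular to the
current axis estimate over 25–75 % of projected bone length in 2 % steps
(defaults; `MeasureConfig.span`, `.step`).  The mid-diaphyseal span avoids
epiphyseal flare and limits procurvatum bias.  Per level, the section loop
containing the previous level's centroid is kept (largest perimeter at the
first level); loop centroids are arc-length weighted so they do not depend
on mesh resolution.  The axis is re-fit (total least squares) and the
mesh re-sliced until the direction changes by < 0.1° (≤ 5 rounds).  At
least 5 usable sections are required.

**Head fit.**  From the seed click (must lie within 5 mm of the surface)
a local radius estimate is formed by growing a ball until a well-posed
sphere fit exists; the initial support is the vertex cap within 0.4× that
radius of the seed.  The fit then alternates sphere fitting (algebraic
initialisation + geometric Gauss–Newton refinement, radius profiled out as
the mean center distance) with inlier re-selection: vertices whose
orthogonal distance to the current sphere is within
max(`inclusion_tol`·r, 3σ) — σ a robust (MAD-based) scale of the support
residuals, capped at 0.15 r — restricted to the connected surface patch
containing the seed.  `inclusion_tol` defaults to 0.025 (2.5 % of the
radius); iteration stops at a support fixpoint or 50 iterations; support
below 50 vertices is an error.  The noise floor in the band keeps the
selection connected on rough surfaces while still shedding neck and
acetabular vertices, whose residuals grow quickly away from the head
equator.

**Neck.**  The neck is cut by a sphere concentric with the fitted head at
`neck_scale`·r (default 1.25; auto-escalated 1.10→1.60 in 0.05 steps if no
loop is found).  Loops below 25 % of the largest loop's perimeter are
discarded as noise artifacts; among the rest, the loop whose centroid
direction best matches the head-to-shaft direction is the neck.  The neck
*center* is the center of a least-squares circle fitted to the loop (plane
by PCA, algebraic circle fit in-plane).  On noisy surfaces this is the
single most important robustness choice in the pipeline: the raw
arc-length centroid of a zigzagging loop wanders by several tenths of a
millimetre — enough for ~3° of torsion error at this lever arm — while the
circle-fit center stays within a few hundredths.  For clean surfaces the
two coincide.

**Condyles.**  Candidate vertices are the distal 20 % of projected bone
length (`distal_fraction`).  Because the condyles protrude caudally, the
caudal direction is bootstrapped as the (axis-orthogonalized) offset of
the distal-region centroid from the anatomical axis, and refined once from
the provisional sphere centers.  The region is split medially/laterally by
the plane containing the axis and the craniocaudal estimate; each subset
is restricted to its articular portion (outward vertex normal with a
positive component along distal+caudal) and fitted with an
inlier-reselecting sphere fit (band max(0.05 r, 3σ), ≤ 4 rounds) that
sheds distal-shaft vertices.  Support below 100 vertices is an error.
Medial/lateral labels come from the required side flag; the side is never
auto-detected, matching how an operator uses the tool.

**Joint line.**  The distocaudal common tangent of the two condylar
spheres: with the probe direction d̂ = unit(distal + caudal) made
orthogonal to the current line direction, tangent points are
cᵢ + rᵢ·d̂ and the direction is re-estimated until it changes by < 0.01°
(≤ 10 iterations).  For unequal radii the construction reproduces the
closed-form tilt asin(Δr/d) exactly (the 3D angle; its frontal projection
is scaled by the in-plane component of the probe).

Convergence tolerances (0.1° axis, 0.01° joint line, iteration caps 5/10/50)
are far below the 2° validation tolerance, so they never dominate the
error budget.

## The synthetic phantom

The generator emulates the gross anatomy the measurement relies on, with
every angle known exactly from the constructive primitives:

* shaft: a tube of radius 6 mm along a circular arc (default 160 mm chord,
  8° procurvatum) in the sagittal plane, bulging cranially;
* neck: a capsule (radius 0.55× head radius, length 24 mm) leaving the
  proximal shaft in the direction that realises the target FNA (frontal)
  and FTA (axial);
* head: an 11 mm sphere at the neck tip;
* condyles: two 14 mm spheres, 30 mm apart, caudally offset by 0.45× their
  radius, with their separation direction tilted in the frontal plane by
  (aLDFA − 90°).

Defaults approximate a mid-size dog within the cohort's 2.1–57 kg span.
The surface is the zero level set of the signed-distance union sampled at
0.8 mm (constrained to ≤ shaft_radius/4) and extracted with marching
cubes — implicit union rather than boolean mesh operations, because it
guarantees the watertight single shell the cleaning and region-growing
stages assume.  Optional seeded Gaussian vertex noise (sd `noise_sd`)
emulates segmentation roughness.  Left femurs are exact mirrors of the
right-side construction.

The ground-truth anatomical axis is defined as the chord through the 25 %
and 75 % arc-length points of the shaft curve — the same mid-diaphyseal
span the estimator uses — because oracle and estimator must share a
definition for parameter recovery to be meaningful.  Ground-truth angles
are obtained by running the *measurement* frame/projection code on the
constructive primitives, so the two sides of every recovery comparison use
one set of conventions (self-consistent to < 1e-6°, and equal to the spec
targets to < 0.2°, the residual being arc-chord placement effects).

**What the phantom does not model** — and hence what passing recovery
tests do not establish: the greater trochanter, the trochlear groove,
cortical thickness, osteophytes and joint remodelling, segmentation
artifacts other than isotropic vertex noise, asymmetric condyle radii, and
the acetabulum (the head fit's exclusion behaviour is exercised only
against the neck junction).  Performance on pathological clinical CT
meshes must be judged with the QC diagnostics (fit residuals, support
counts, rendered sphere overlays), not inferred from the phantom.

## Validation conditions

`tests/test_acceptance.py` checks, at the sizes named:

* parameter recovery on the 60-femur grid aLDFA ∈ {85, 95, 104, 114} ×
  FTA ∈ {8, 13, 27, 37, 50} × FNA ∈ {120, 135, 143}, noise-free within 2°
  and with 0.3 mm vertex noise within 3° (measured worst cases in this
  environment: ≈ 0.5° and ≈ 1.0°);
* rigid-motion invariance (10 random poses), seed invariance (10 head
  clicks) and mirror symmetry, all within 0.5°;
* exact sphere-fit and two-sphere-tangent oracles to 1e-6;
* the planner worked examples and the exact cohort recounts.

`scripts/acceptance.py` recomputes the same families of quantities on a
12-spec grid (plus 5 poses) to stay fast; the test suite carries the full
grid.

## Surgical planner

Band semantics follow the published rules exactly: normal frontal
alignment is *strictly* 90° < aLDFA < 102° (the boundary values trigger a
DFO recommendation), physiological torsion is 18° ≤ FTA ≤ 35° inclusive
(only values strictly outside trigger an FDO).  FNA has no published
decision threshold and gates nothing.  Correction magnitudes are measured
minus target, with targets defaulting to the band midpoints (96°, 26.5°);
the `paper-postop` profile presets the cohort's achieved post-operative
means (94.6°, 25.7°) instead.  Cases within 2° of any bound carry a
`borderline` annotation rather than a different decision — the planner
flags deformity components and deliberately does not map combined
deformities to staged-surgery strategies.

## Cohort records

The two packaged tables are transcribed row-by-row, including
non-included contralateral low-grade limbs; a limb is one of the 47
included limbs exactly when it has a row in the outcomes table, and for
unilateral rows the operated side is inferred as the higher-grade luxation
entry (ties broken by the lame side, then right).  Stored outcome labels
are data; `classify_outcome` is an independent re-derivation of the stated
rule cascade, and disagreements are reported, not reconciled (the
full/acceptable definitions genuinely overlap at lameness 1/5 with minor
complications; the cascade resolves the overlap to *full*).  Narrative
counts that match no recount of the tables under either denominator
(raw entries vs included limbs) — the luxation-grade distribution, the
acceptable-outcome count, the demographic medians — are flagged by
`discrepancies()` and are never forced.

## Known limitations

* A single whole-shaft anatomical axis serves both aLDFA and FNA; using
  separate proximal/distal axes is a defensible alternative that would
  shift both angles slightly on strongly procurved bones.
* FNA is measured in frontal projection, not as a 3D angle.
* The neck-section offset (1.25×) and head-fit inclusion tolerance are
  calibrated on the phantom only; on clinical meshes the QC block and the
  configurable knobs (`neck_scale`, `inclusion_tol`, section span) are the
  intended recourse, mirroring the parameter toolbar of interactive CAD
  implementations.
* Mechanical-axis angles (mLDFA etc.) and tibial measurements are not
  computed.
* STL files carry no units; millimetres are assumed by contract.
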