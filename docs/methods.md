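# Methods

## The measurement model

The pipeline treats the left atrial (LA) wall as the compartment between
two closed triangulated surfaces: the endocardial shell (blood-pool /
myocardium interface) and the epicardial shell (myocardium / epicardial
fat interface).  Both shells are inputs, in mm world coordinates; the CT
volume carries calibrated Hounsfield Units and a voxel-to-mm affine, with
the 0-based voxel index mapping to the voxel *center*.

**Wall thickness.**  LAWT at an endocardial vertex is the Euclidean
distance to its projection on the epicardial surface.  "Projection" is
implemented as the *nearest point on the epicardial surface*
(point-to-triangle minimisation): it is symmetric, robust to noisy
vertex normals, and coincides with the normal-ray definition on
concentric shells.  An optional `mode="ray"` casts along the outward
endocardial vertex normal instead (falling back to the nearest point
where the ray misses).  Where several nearest points exist (medial
situations) the minimum distance is unique even though the point is not;
only the distance is stored.  The summary thickness is the
*area-weighted* vertex average (lumped one-third triangle areas), which
makes it invariant to mesh refinement; a plain vertex mean is not.
Colour bins are half-open intervals with boundaries going to the
upper-named bin: red < 1 ≤ yellow < 2 ≤ green < 3 ≤ blue < 4 ≤ purple
(mm).

**Wall mask.**  A voxel belongs to the wall iff its center lies inside
the epicardial shell and not inside the endocardial shell.  Membership is
evaluated at voxel centers with no supersampling and no partial-volume
correction: a voxel is counted entirely or not at all.  Containment is
computed slice by slice: the mesh is sectioned at each z level of the
grid, the closed section curves become polygons, and an even–odd
point-in-polygon test marks interior centers (this handles nested
cross-sections, e.g. slices through a tube).  Volumes require an
axis-aligned affine; the reader accepts any affine but mask construction
refuses rotated grids.

**Exclusions.**  The appendage and the distal pulmonary veins are not
part of the analysed wall.  Each PV ostium plane (point + vein-ward unit
normal, stored in the landmark file) removes wall voxels more than 5 mm
on its vein side; the appendage ostium plane removes everything on its
appendage side.  Because a plane is unbounded, both tests are confined to
a radial guard of twice the ostium loop radius around the ostium axis.

**Fat classification.**  Wall voxels with HU in [−194, −5] are inFAT;
the subranges are dense inFAT = [−194, −50] and fat–myocardium admixture
= (−50, −5].  The published subranges are both inclusive at −50 HU, which
would double-count the boundary; assigning the boundary voxel to the
dense class keeps the two classes disjoint with union exactly [−194, −5],
so inFAT volume = dense + admixture holds as exact voxel arithmetic.
All three cut-points are configurable (`HuThresholds`).

**Summary metrics.**  Class volume = voxel count × voxel volume.  Mean
class HU is the arithmetic voxel mean (accumulated in float64); an empty
class reports a *missing* mean, never 0, because 0 HU is a valid tissue
value.  LA cavity volume is the enclosed volume of the endocardial mesh
(divergence theorem) — a shell property independent of the voxel grid —
while wall volume is the voxel-count volume of the analysed mask.  Six
normalised metrics divide each class volume by the LA volume and by the
wall volume; the identity (normalised × denominator = raw) holds to
float precision by construction.  Fat outside the epicardial shell
(epicardial adipose tissue) is never counted.

## 19-segment parcellation

The LA shell is partitioned into 19 named segments after excluding the
appendage, the mitral valve and the veins beyond 5 mm: posterior wall
(1–4), floor (5 left, 6 right), septal wall (7), anterior wall (8–11),
left lateral wall (12), left/right carinae (13/14), LIPV/LSPV antra
(15/16), ridge (17), RIPV/RSPV antra (18/19).

All boundaries derive deterministically from the landmark file, which
supplies a body frame (center + left / anterior / superior unit axes),
four labeled PV ostium loops with planes, the appendage ostium and the
mitral annulus.  The manual anchoring step of clinical workflows is
thereby externalised into the landmark file.  Labels are assigned by a
pure per-point classifier evaluated at face centroids, in fixed
precedence order:

1. exclusion zones (appendage side of the LAA plane, > 5 mm vein side of
   a PV plane within the radial guard, mitral cap);
2. PV antra: the retained 0–5 mm vein collars;
3. carinae: bands of half-width 0.8 × the mean ipsilateral ostium loop
   radius around the chord joining the two ipsilateral ostium centers;
4. ridge: the analogous band around the chord from the LSPV ostium to
   the appendage ostium;
5. posterior wall: the region bounded above by the line through the
   superior edges of the superior PV ostium loops, below by the line
   through the inferior edges of the inferior PV loops, and laterally by
   the medial edges of the two PV columns;
6. floor: below the posterior wall on the posterior half, split
   left/right at the frame center;
7. septal wall: right of the right PV column;
8. left lateral wall: left of the left PV column, posterior/inferior to
   the appendage ostium;
9. anterior wall: the remainder (including the dome).

The interior splits of the posterior (4) and anterior (4) walls use
equal-width intervals of the left–right frame coordinate between the PV
columns.  The exact placement of these internal lines is a convention —
published figures show a roughly even grid — and a classifier on the
landmark frame was preferred over geodesic boundary curves plus flood
fill because it is a total function (every face gets exactly one label,
so the partition property holds by construction), deterministic, and
equivariant under rigid motions of mesh + landmarks, which the test suite
checks directly.  The trade-off is that boundaries are planar in the
landmark frame rather than geodesic on the surface; on smooth atrial
geometries the difference is confined to a band of roughly one face size
around each boundary.

Wall voxels inherit the segment of the nearest non-excluded epicardial
face center (KD-tree query; ties resolve to the lowest face index), so
segment wall volumes sum exactly to the total wall volume.  Voxels are
labeled from the *epicardial* parcellation since fat is bounded
laterally by that shell.  Regional quantities follow: relative inFAT
percentage = 100 · V_fat(s)/ΣV_fat (missing when total fat is zero, with
a warning), regional volume percentage = 100 · V_wall(s)/ΣV_wall.
Cohort-level summaries average per-patient percentages within groups.

## Synthetic phantoms

Phantoms supply ground truth for every downstream quantity.

* `concentric_spheres` (r, R): shells are subdivision-4 icospheres, all
  volumes analytic.
* `ellipsoid_shell`: endocardial shell an anisotropically scaled
  icosphere; epicardial shell its constant-thickness outward normal
  offset.
* `la_like`: an ellipsoidal body (default semi-axes 32 × 27 × 25 mm,
  cavity ≈ 96 mL, matching a mildly dilated atrium) unioned with four PV
  tubes (radius 5 mm, 12 mm long) and an appendage stub (radius 4.5 mm),
  built as a signed-distance field; the endocardial surface is the zero
  level set and the epicardial surface the +t level set (constant wall
  thickness t, default 2 mm), extracted by marching cubes at 0.8 mm
  pitch.  PV/appendage ostium planes are the analytic tube–body junction
  planes; ostium and annulus loops are mesh-vertex polylines snapped to
  the plane sections; the landmark frame is the construction frame.

Voxel HU equal the level of the region containing the voxel center —
contrast blood pool +350 HU, myocardium +40 HU, background −1000 HU,
optional epicardial fat layer −100 HU — plus i.i.d. Gaussian noise
(default sd 10 HU), all driven by one seed.  These tissue levels are
typical contrast-enhanced CT values; the analysis thresholds constrain
only the fat ranges, so the exact levels are configurable.  The sampling
grid is shifted by a fixed sub-voxel offset so no voxel center sits
exactly on an analytic surface, keeping voxel-count arithmetic exact on
noise-free phantoms.

Fat deposits are grown by breadth-first voxel accretion from a
deterministic seed voxel (nearest the target region centroid) over the
eroded wall mask — so deposits sit strictly between the shells — within
the requested anatomical segment when landmarks exist.  The recorded true
volume is the voxel count × voxel volume, within one voxel volume of the
request.  Planted voxels receive HU drawn uniformly from a range strictly
inside the class interval (defaults: dense −130…−70 HU, admixture
−45…−10 HU) and are *not* re-noised, so the planted support never
straddles a class boundary and the truth manifest's class assignment is
exact; the surrounding tissue keeps its noise.

The cohort generator draws per-patient metrics independently per group:
fat volumes log-normal (parameterised by median and quartiles), BMI, age,
HU means, LA volume, LAWT and wall volume normal, sex Bernoulli.  Its
default location/scale parameters are the study-arm values the cohort is
meant to emulate (controls with lower BMI and lower fat volumes,
persistent AF highest), and a null specification with identical groups is
provided for calibration runs.

**What the phantoms do not emulate:** CT physics (beam hardening,
motion, anisotropic PSF), realistic atrial shape variation, spatially
correlated noise, and partial-volume mixing at tissue interfaces (a
voxel is one tissue plus noise).  Passing tests therefore demonstrate
the correctness of the geometry, classification, bookkeeping and
statistics — not segmentation robustness on clinical images, where shell
quality dominates.

## Numerical choices

* Nearest point on a surface: exact two-phase search — k nearest face
  centroids (KD-tree) give an upper bound, then every face whose centroid
  lies within that bound plus the largest face circumradius is checked
  with exact point-to-triangle distances.
* Inside/outside for arbitrary points: sign of the outward normal of the
  face carrying the nearest point; adequate for smooth closed shells.
* Shell validation: closed 2-manifold required; winding normalised to
  outward (positive enclosed volume); the endocardial shell must not
  protrude outside the epicardial shell (tolerance 1e-6 mm, error names
  the offending vertex).
* Degenerate inputs: identical shells give zero thickness and an empty
  wall mask; an empty fat class reports missing mean HU and zero volume;
  zero wall volume makes normalisation an error; zero total fat makes
  relative percentages missing with a warning, not an exception.
* Statistics: Shapiro–Wilk at α = 0.05 per group decides the summary and
  test family (the normal/non-normal dichotomy needs *some* gate; this
  one is conventional and overridable via `force_family`); pairwise
  non-parametric post-hoc tests are two-group Kruskal–Wallis (equivalent
  to Mann–Whitney up to tie handling) with Bonferroni multiplier 3;
  ANCOVA is OLS `metric ~ group + covariates` with a type-II F-test on
  the group factor (single factor, no interaction); a constant covariate
  is dropped so the model reduces exactly to one-way ANOVA; collinear
  covariates are an error.

## Problem sizes

Default test/report geometry: 0.5 mm isotropic voxels; sphere phantoms
span ~102³ voxels, the LA-like phantom ~208³ (≈ 9·10⁶ voxels, ≈ 69 000
epicardial faces).  Statistical calibration uses 2000 simulated null
cohorts of n = (30, 30, 20).  A full LA-like phantom build plus mapping
and parcellation runs in well under a minute on one CPU.

## Known limitations

* Thickness is measured endocardium → epicardium only, as defined; it is
  not symmetrised.
* Voxel-center membership means sub-voxel wall features are quantised;
  walls thinner than two voxels trigger a partial-volume warning at
  phantom construction.
* The ellipsoid signed distance is a first-order normalisation, so the
  la_like wall thickness is constant only to ~1 %; concentric spheres
  are exact and are used for the analytic thickness checks.
* Plane-based exclusions assume reasonably straight proximal veins; a
  sharply curved vein could evade the radial guard.
* Voxel labels from nearest-face inheritance disagree with the point
  classifier in a one-face-wide band along segment boundaries; regional
  percentages of deposits hugging a boundary carry a corresponding
  tolerance (tested at 2 percentage points).
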