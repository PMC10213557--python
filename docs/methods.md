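# Methods

This note documents the models, estimators and numerical choices behind
`primordium3d`, what the synthetic-data generator does and does not
emulate, and the known limitations. All lengths are µm, areas µm²,
volumes µm³; volumes are (z, y, x) index-ordered with voxel centers at
((k+0.5)·dz, (j+0.5)·dy, (i+0.5)·dx).

## Data model and conventions

The unit of input is a `LabeledVolume`: a segmented 3D image with one
positive integer label per cell and 0 for background, plus physical voxel
sizes. One grid face (`base_plane`, default the minimum-z face) is treated
as tissue continuation rather than exterior, because organ crops terminate
in tissue there; this face is excluded wherever "exterior" matters (L1
detection, exterior wall patches, radial directions).

## Tissue annotation

Cell adjacency uses 6-connectivity (face contact only); diagonal contacts
are treated as segmentation artifacts. Edge areas are face counts × face
area, and edges below `min_contact_area` (default 1 µm²) are dropped.
Layers are graph distance to the virtual exterior node: L1 touches the
exterior, L2 touches L1, L3 touches L2, everything deeper (or unreachable)
is L4. The apical axis is the principal axis of the exterior-surface point
cloud oriented away from the base plane, falling back to the grid axis when
the cloud's top two eigenvalues are within 20% of each other (flat domes
are laterally near-isotropic). The central L2 cell maximizes centroid
height on that axis, with near-ties (< 0.5 µm) broken by distance to the
axis line; the central L3 cell is the adjacent L3 cell whose offset
direction best aligns with the central cell's basal-ward major ellipsoid
axis. Contact classes are breadth-first distance from the central L2 cell,
truncated at 2.

## Surface areas without staircase bias

Counting raw voxel faces overestimates oblique surfaces by up to √3, and
smoothing a mesh until the staircase disappears shaves genuine sharp
corners by 5–15% — either error corrupts sphericity. Areas are therefore
computed by projecting each boundary face onto a Gaussian-smoothed normal
field (σ = 1.5 voxels): Σ face_area·|face_normal·m|. The projection is
exact for planar staircases of any orientation; where the local plane-fit
RMS of face centers exceeds ~0.35 voxels — the signature of a genuinely
turning surface rather than a staircase — the correction is blended out so
sharp edges keep their full area. Calibration on phantoms: digital ball
(r = 20 voxels) area +0.8%, cube area −0.05%; sphericity 0.993 (ball) and
0.8064 (cube; closed form (π/6)^⅓ ≈ 0.806). A cell's total surface area is
the sum of its per-neighbor wall patches (plus the exterior patch), making
interface areas additive by construction. Smoothed iso-surface meshes
(Gaussian σ = 1 voxel, marching cubes, Taubin smoothing) are still built
for visualization and organ-scale geometry.

## Fitting ellipsoid

Second central moments of the voxel-center cloud, plus the per-voxel
variance d²/12 per grid axis (so a box of side s yields exactly s²/12);
semi-axis_i = √(5λ_i), exact for a solid uniform ellipsoid. All reported
shape quantities (normalized axes, two-axis anisotropy c/(a+c)) are
scale-invariant, so the semi-axis convention does not affect comparisons.
The ellipticity formulas e_p = (c−b)/c and e_o = (b−a)/b are this package's
definitions: bounded [0, 1), zero on the sphere, monotone in elongation and
flattening. Commercial packages report quantities with the same names but
unpublished formulas; values are comparable qualitatively, not numerically.

## Junction wall angle (continuity)

The geometric signature of a recent division is that the free walls of the
two daughters continue smoothly across the new wall. For a cell pair and
each shared side region, the measurement automates the manual three-point
procedure (one point at the center of each wall, one at their junction):
J = centroid of the voxel set where the three regions meet, P_up / P_low =
area-weighted centroids of the two wall patches, angle = ∠(P_up, J, P_low).
Raw centroids on voxel data are too noisy for this to work (a half-voxel
offset of J bends a perfectly continuous wall by 15–20°), so the points are
denoised with geometric safeguards, each needed on real tessellations:

- wall patches are restricted to the band flanking the junction (up to
  6 voxels, widened to keep ≥ 40 faces per patch) — on large cells walls
  curve and wrap, and only the band near the junction carries the signal;
- wall centroids are projected onto their own fitted patch planes;
- J is snapped to the *nearer* patch plane when the patches are
  near-parallel (< 20° apart). Snapping to any averaged plane would place
  J midway between two offset parallel walls and make a step read as
  collinear; the nearer-plane snap preserves the step;
- for genuine folds (≥ 20°), J is projected onto the crease (the
  intersection line of the two patch planes), with the move bounded by
  3 voxels against ill-conditioned fits;
- both rays are projected perpendicular to the junction-line direction so
  in-plane skew of irregular wall polygons does not read as a fold;
- sides are declared unusable (and skipped) when their junction set is
  two-dimensional (middle principal spread > 2 voxels), when the junction
  centroid falls off the set by > 2.5 voxels, or when a ray's lever arm
  collapses below half a voxel (corner contacts) — in each case the angle
  would be fabricated by geometry unrelated to continuity.

The exterior side context is split per face orientation (each lateral side
of a pair measured separately), excluding orientations parallel to the
pair's own interface (caps and step treads are not flanking walls). The
reported per-pair angle is the mean over qualifying sides. On coplanar
stacked-box fixtures the angle is ≥ 178°; laterally offsetting the lower
box by 10/20/30% of its width bends the stepped walls monotonically
(169°/158°/149°). On synthetic domes, freshly planted divisions read
174–180° and ordinary neighbor pairs below ~150°.

## Division inference

Candidate pairs are adjacent same-layer pairs plus L2–L3 pairs (the
pairing a periclinal L2 division produces); a pair is called recent when
its continuity angle reaches the threshold (default 160° — the paper-scale
separation is visual, so the threshold is a config knob and every call
records its angle). For side contexts the scan uses only cells of the
pair's own layers: in a layered tissue the walls against the layer above
and below lie on smooth layer interfaces and are continuous for *every*
pair, so only the lateral walls discriminate. Each recent pair carries the
shortest-wall prediction, the o-p angle α = arccos|n̂_obs·n̂_pred| folded to
[0°, 90°], the orientation class (wall normal within 30° of the local
radial = periclinal, beyond 60° = anticlinal, else oblique), and the
daughter volume ratio.

The shortest-wall search evaluates the planar cross-section through the
mask centroid over 500 quasi-uniform (Fibonacci) half-sphere directions
with two passes of golden-section refinement in the tangent plane.
Cross-section area uses Gaussian-slab counting: each voxel contributes
exp(−d²/2σ²) with σ equal to the one-voxel support along the normal;
this suppresses the lattice aliasing that corrugates hard-thresholded
slab counts with spurious oblique minima, and is exact for axis-aligned
sections. Against a 10×-denser direction scan the refined search agrees
to ≤ 0.1% in area and ≤ ~1° in direction on well-conditioned ellipsoids;
the direction is intrinsically ill-determined when two section axes are
near-equal (any normal is then acceptable, as for a ball).

The ovule Type is the continuity call on the central L2–L3 pair: Type 2
iff the angle reaches the threshold (a missing central L3 cell is Type 1,
flagged). Daughter volume ratios (max/min ≥ 1) are clustered with the
globally optimal 1D k-means.

## Organ shape

The organ outline is the hole-filled foreground. The bounding box is
principal-axis-oriented, with extents measured on the smoothed iso-surface
mesh (voxel-center extents are off by an orientation-dependent fraction of
a voxel; the smoothed surface sits on the true boundary for flat faces of
any orientation). Aspect ratio = A/(A+B+C) ∈ (0, ⅓], the organ's height
share. Mean curvature per vertex uses the chord identity κ = 2Σh/Σ|p|²
over all mesh vertices within the metric neighborhood (40 µm; 30 µm when
the bounding diameter is under 80 µm — the cutoff for "small" organs is
this package's choice), where h is the height of each neighbor below the
tangent plane: the estimate is exactly 1/R on a sphere, exactly 0 on a
plane, and an organ-scale-smoothed mean curvature in between; base-cap
vertices are masked. The apex curvature summary is the mean over the
apical 20% of unmasked vertices. The cell–organ shape coupling uses
Spearman rank correlation with a permutation p (exact enumeration up to
n = 7, otherwise ≥ 10,000 seeded draws): rank correlation is robust to the
stage-clustered, non-Gaussian structure of the pairs.

## Staging and statistics

Stages are found by globally optimal 1D k-means (dynamic programming over
contiguous partitions of the sorted values — deterministic, no seeding;
verified ≤ the best of 100 seeded Lloyd runs on every tested input). The
pipeline clusters *log* central-L2 volumes: the volume roughly doubles per
stage, so clusters are equidistant and well-separated on the log scale,
whereas linear-scale k-means on such data trades the wide top cluster
against merging the two smallest in a substantial fraction of samples.
Reported cluster means remain arithmetic (µm³). The elbow suggestion is
the deepest k whose log-WSS drop is at least 60% of the largest drop
(splitting a real cluster shrinks log-WSS by a large step; splitting noise
collapses the steps); a near-flat curve (log-curvature < 0.8, about the
value produced by the k⁻² decay of a single Gaussian blob) flags the
suggestion low-confidence. The default number of stages is 4,
overridable.

Mann–Whitney U is exact (full enumeration) for tie-free samples up to
n = 20 pooled, seeded-permutation (≥ 20,000 resamples) for small tied
samples, and normal-approximated with tie and continuity corrections
otherwise; Fisher's exact test and the Pearson χ² (no continuity
correction) wrap the standard implementations and are verified against
brute-force hypergeometric/closed-form oracles in the test suite. The
three χ² classes are pooled tertiles. Significance codes follow the
standard ladder *< 0.05, **< 0.01, ***< 0.001, ****< 0.0001. No
multiple-testing correction is applied across the summary grid; raw
p-values are reported, as is conventional for these descriptive tables.

## Synthetic ovule generator

The generator emulates the geometric and statistical structure the
analysis consumes, not microscopy: a superellipsoid dome
{(x/Rx)² + (y/Ry)² + (z/H)ⁿ ≤ 1, z ≥ 0} is voxelized (pointed at n = 2,
squared at n = 6), peeled into layers by depth from the free surface
(defaults 5/8/7 µm for L1/L2/L3 with an L4 core — epidermal-scale cells at
the study's organ sizes), and each layer is partitioned among
farthest-point-placed seeds by additively weighted nearest-seed assignment
(power-diagram-like, label-image native, full coverage guaranteed). One L2
seed sits on the dome axis; its weight is tuned by bisection (≤ 30
iterations, attained within ±0.3%) to a target central-cell volume.
Default cohort conditions: 4 stages × 10 ovules, central-L2 volume means
500/1000/2000/4000 µm³ with 10% log-normal spread, dome heights 26–44 µm,
0.5 µm voxels (coarser than the 0.3 µm acquisition the method family is
used at, chosen so the default suites run in minutes; junction-angle
geometry needs ≥ ~6 voxels across a daughter cell, which 0.5 µm provides).

Planted divisions split a cell by a plane through the point dividing its
extent (or, optionally, its volume quantile) at fraction f along the
division normal: periclinal = local radial direction (the mean outward
normal of the exterior cap over the query point), anticlinal ⊥ to it,
oblique at 45°. A cleanup pass keeps the basal daughter off the layer
above (a periclinal wall meets the outer wall at its rim). Wall age is
emulated by jitter: each daughter's free walls are displaced by an
independent band-limited Gaussian field (σ = 2 voxels) of the requested
amplitude, applied as volume-preserving voxel transfers with neighboring
cells (equal counts in and out per round, so cell *size* is untouched by
wall age). Calibration within this package: jitter 0 leaves walls
continuous (junction angles 174–180° on domes, ≥ 178° on box fixtures);
jitter 3 µm reliably breaks continuity below the 160° threshold. The Type 2
fraction per stage (defaults 0.7 / 0.4 / 0 / 0) and the daughter-ratio
mixture (symmetric ≈ 1.0 and asymmetric ≈ 2.3 components) are the planted,
recoverable truths; mothers of divided central cells are grown so the
apical daughter lands on the stage's volume target.

What the generator does not emulate: wall-signal synthesis, microscopy
noise, segmentation errors, mechanical growth, or the ~120° wall
equilibria of real mature tissue junctions (power-diagram walls of
same-layer neighbors meet the smooth layer interfaces tangentially, which
makes old same-layer pairs look more continuous toward the layer surfaces
than real tissue would — the reason division detection restricts itself to
lateral side contexts). Passing recovery tests therefore demonstrates the
correctness and calibration of the geometric inference on idealized
tissue, not robustness to segmentation artifacts.

## Validation problem sizes

The default test and acceptance runs use: phantoms of 12–25 voxel radius;
a 40-ovule cohort (10 per stage) with division detection on the 20
early-stage ovules plus 2 undivided late-stage negative controls; 10
convex fixtures for the shortest-wall oracle with a 5,000-direction dense
scan; 50 random inputs × 100 Lloyd seeds for the k-means optimality check.
Measured recovery at these sizes (seeds 0–2): staging accuracy
0.975–1.0 with elbow k = 4; division detection sensitivity 1.0 and
specificity ≥ 0.999; periclinal classification 0.90–1.0; volume-ratio
cluster means within 3% of the planted (1.0, 2.3).

## Known limitations

- The continuity angle needs daughter cells several voxels across; at
  1 µm voxels on 5–8 µm cells the three-point geometry is under-resolved.
- The shortest-wall direction is reported even when near-degenerate
  (ball-like mothers); consumers should treat α accordingly.
- Apical/basal wall ratios inherit the interface-area correction's ~5–15%
  tolerance on strongly curved walls.
- The annotation assumes a single dome with one apical axis; fused or
  strongly tilted multi-organ crops need pre-splitting.
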