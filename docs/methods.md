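# Methods

This note documents the models, algorithms and numerical choices behind
`seg2fem`, the assumptions they rest on, and what the synthetic phantoms do
and do not establish about real spine MRI data.

## Problem setting

Patient-specific finite-element (FE) models of vertebrae and intervertebral
discs (IVDs) can be built directly from labeled MRI segmentation masks by
the *filling* approach: extract a triangulated surface per body, smooth it,
fill it with tetrahedra, and attach loads, constraints and materials.  Two
features make spine models difficult:

1. **Anisotropic resolution.**  Clinical spine MRI is acquired at roughly
   1 × 1 mm in-plane with 2.5–3.5 mm slices, so marching-cubes surfaces
   carry stair-step terraces.  Smoothing must remove these at the disc
   contact surfaces without erasing genuine anatomy (endplate rims,
   osteophyte-like features) elsewhere.
2. **Contact.**  If the disc and vertebra meshes do not share nodes on the
   contact surface, the simulation needs a contact formulation (penalty or
   Lagrange), which costs time and stability.  The pipeline instead makes
   the contact surfaces *share nodes bitwise*, so adjacent bodies can be
   tied or assembled without any contact model.

## Pipeline

Per subject: mask cleanup → per-body surface extraction → selective
vertebra smoothing → adaptive IVD smoothing → tetrahedral filling →
quadratic (10-node) conversion → interface node sets → FE model → static
solve → per-body report.  A failure at any stage is recorded with a
category (disconnected volumes, small segmentation volume, hole,
non-manifold edges, self-intersecting faces, mapping error,
non-convergence, in that attribution priority) and the run continues with
the remaining bodies.

### Mask cleanup

Connected components of each label smaller than 4 voxels (26-connectivity
by default; configurable) are removed — these partial-volume islands
otherwise produce sharp spikes during smoothing.  Components **at** the
threshold are kept (strictly-below removal); the convention is
configurable because the rule is stated in the literature only as a
threshold count.  Endplate labels, when present, are merged into the
adjacent disc label before extraction so each disc yields one surface.

### Surface extraction

Marching cubes on the binary mask at iso-level 0.5, ascending gradient,
step size 1 (every voxel layer sampled), with vertices mapped to world mm
through the NIfTI affine.  The mask is padded by one background voxel so
bodies touching the grid boundary still close.  Output orientation is
normalized to outward (positive enclosed volume).

### Smoothing

Both protocols use the umbrella operator: a Laplacian step moves a vertex
toward its 1-ring centroid by a factor; Taubin smoothing alternates a
shrink step (λ > 0) and an inflate step (μ < 0), which suppresses the
volume loss of pure Laplacian smoothing.

* **Vertebrae (selective).**  Repair → detect *interface vertices* (vertex
  whose nearest-vertex distance to an adjacent disc surface is strictly
  below a per-level threshold) → Laplacian-smooth only those vertices
  (10 iterations, weight 0.5) → Taubin over the whole mesh (10 iterations,
  λ = 0.5, μ = −0.53).  Vertex/face counts never change.  The contact
  regions become smooth while circumferential stair steps — anatomy the
  protocol deliberately does not touch — remain.
* **IVDs (adaptive).**  Preprocess with Taubin, a gentle whole-mesh
  Laplacian, repair, and a *calibrated dilation*: each vertex moves along
  its area-weighted normal by an offset chosen so the enclosed volume
  returns to the raw value within 1 %, bounded by 0.5 mm.  Then every
  interface vertex is **replaced by the nearest vertex of the adjacent,
  already-smoothed vertebra** — a bitwise coordinate copy.  A final Taubin
  pass over a 2-ring border region relaxes the seam while all snapped
  vertices stay frozen, and exact-duplicate vertices (two disc vertices
  snapped to the same target) are merged, preserving the shared
  coordinate.

Parameter notes:

| Parameter | Default | Why |
|---|---|---|
| interface threshold | 0.6 mm (labels ≤ 10), 0.8 mm (above) | anatomical contact gap by spinal level; the smaller cervical anatomy gets the tighter bound.  The per-level table is a configurable stand-in — in practice these thresholds are tuned by visual inspection. |
| Laplacian weight / iterations | 0.5 / 10 | standard umbrella step; enough to flatten terrace steps of one slice height |
| Taubin λ, μ, iterations | 0.5, −0.53, 10 | classic pass-band pair; near-volume-neutral |
| IVD preprocess Laplacian iterations | 3 (pipeline default) | discs are only 1–2 slices thick; 10 whole-mesh sweeps shrink them ≈ 11 %, beyond what the bounded dilation recovers.  3 sweeps keep total drift ≈ 5 %. |
| dilation bound | 0.5 mm | half the in-plane voxel; prevents the compensation from inventing geometry |

Interface detection is vertex-to-vertex (not vertex-to-surface) because
snapping is defined on vertices; the same metric keeps detection and
snapping consistent.  A vertebra's interface subsets against both adjacent
discs are selected jointly, then smoothed in one subset pass.

### Tetrahedral filling

The filling contract that matters downstream is *surface vertex
retention*: every surface vertex must appear in the volume mesh at its
exact coordinates, because (a) interface node sets are recovered later by
rounded-coordinate matching and (b) the bitwise shared-node property must
survive volume meshing.  The mesher:

1. lays out an interior lattice at the target edge length (default 1 mm,
   the global seed size; minimum admissible edge 0.1 mm), jittered
   deterministically by ±0.15 edge to break the lattice's cospherical
   degeneracies, and keeps points inside the surface with ≥ 0.7 edge
   clearance from it;
2. Delaunay-tessellates surface vertices + lattice points;
3. keeps tetrahedra whose centroid lies inside the surface (parity ray
   casting, vectorized by 2-D binning; query points carry an irrational
   sub-µm offset so rays never hit edges exactly);
4. drops flat slivers with volume < 2·10⁻³ · (RMS edge)³ — in practice
   ≈ 10⁻⁴ of the body volume, far below the 0.5 % conservation budget,
   but decisive for stiffness conditioning;
5. runs a few fixed-boundary Laplacian sweeps over interior nodes,
   reverting any step that would invert an element.

Quadratic conversion inserts one midpoint node per unique edge (10-node
layout: 4 corners, then midpoints of edges 1-2, 2-3, 3-1, 1-4, 2-4, 3-4).
Since midpoints are exact edge midpoints, element geometry stays affine.

**Quality metric.**  Aspect ratio = longest / shortest of the six element
edges, computed on corner nodes (midpoints cannot change it).  Elements
with ratio > 5 are *poor*; meshes are conventionally expected to stay
below 10 % poor elements, and the cohort acceptance checks use the
stricter ≤ 2 % label-wise mean observed for this pipeline class.

### FE model assembly

Interface surface vertices are matched to volume nodes by comparing
coordinates rounded to 3 decimals (µm precision — far below element size,
far above double-precision noise); an unmatched vertex is a hard error
because it means meshing broke the retention contract.  Each body gets:

* superior/inferior node sets (the two contact surfaces);
* one reference node per set — the member closest to the set centroid,
  ties broken toward the lowest node id;
* a kinematic coupling tying the superior set rigidly to its reference
  node;
* a flexion moment of 7.5 N·m (stored as 7500 N·mm — model units are mm,
  N, MPa) on the reference node's rotational components, about the axis
  orthogonal to the slice-stacking and anterior–posterior directions
  (configurable);
* full restraint of the inferior set.  Solid-element nodes physically
  carry three translational DoF; fixing all translations of every member
  node also restrains the surface's rigid rotations, which realizes the
  six-DoF boundary condition at solver level;
* a linear elastic isotropic material.  Defaults (vertebra E = 10 GPa,
  ν = 0.3; disc E = 10 MPa, ν = 0.45) are configuration placeholders in
  the literature's range, not calibrated values.

Models serialize to the ABAQUS/CalculiX `.inp` keyword dialect (C3D4 /
C3D10 element blocks, named node sets encoding the body name, coupling,
boundary, concentrated moment on DoF 4–6, ≤ 16 data entries per line) and
round-trip bit-exactly through the bundled reader.

### Static solver

Small-strain isoparametric elasticity: linear tetrahedra are
constant-strain (volume-exact integration); quadratic tetrahedra use the
4-point interior Gauss rule.  The kinematic coupling is realized by DoF
elimination with the small-rotation rigid map u_i = u_ref + θ × (x_i −
x_ref); elimination keeps the reduced operator symmetric positive definite
once supports are applied, unlike Lagrange multipliers.  The linearized
coupling matches the single linear static step — finite rotations would
need a corotational update, which is out of scope.

Reduced systems up to 60 k DoF are solved by sparse LU; larger ones by
conjugate gradients with Jacobi preconditioning to rtol 10⁻¹⁰ (memory
bounded; typically ~1500 iterations on a phantom vertebra).  Singular or
non-finite systems produce a `converged=False` result with diagnostics
instead of an exception — non-convergence is data, mirroring how failed
simulations are tallied in cohort studies.  Per-element stress is the
quadrature average; the von Mises equivalent is the reporting scalar.

Verification oracles (all in the test suite): patch test to 10⁻⁸ for both
element orders, bar fixture vs F·L/(E·A) within 1 %, beam fixture vs
M·L/(E·I) within 5 % (ν ≈ 0 so plane sections hold and the rigid end plate
introduces no constraint error), equilibrium of reactions against the
applied 7.5 N·m to 10⁻⁸, and exact satisfaction of the coupling constraint
equation.

## Synthetic phantoms

`phantom` generates labeled voxel stacks emulating what a spine
segmentation network produces: vertebral bodies as superellipse-section
cylinders (exponent 2.5; optional posterior lobe standing in for the
arch), discs as flatter blobs between them, at 1 × 1 mm in-plane and 3 mm
slice spacing by default.  Labels follow the convention of one integer per
spinal level (4–25 for vertebrae; a disc between levels v and v+1 carries
100 + v and the sidecar name `ivd_v_v+1`).  Jitter perturbs radii, centres
and section exponent per level, reproducibly from the seed.  Defaults
describe a cervical-scale stack (10 mm semi-axis, 16 mm body height, 6 mm
disc height) — 6 mm guarantees two voxel slices per disc at 3 mm spacing,
keeping the smallest body safely above the 200-voxel
small-segmentation-volume threshold under ±10 % jitter.

Injectable defects reproduce the failure modes seen in real segmentation
masks: a sub-threshold voxel island (removed by cleanup), a genuine second
component, and an internal cavity (which surfaces as a nested mesh
component and is classified as a hole).  Surface-level self-intersection
is injected by the pipeline's testing hook, since it cannot arise from a
voxel mask directly.

**What the phantoms do not show.**  They are convex-ish, smoothly varying
bodies without posterior elements by default, without MR intensity
artifacts, segmentation noise along the boundary, or touching labels with
interdigitating surfaces.  Passing the cohort checks therefore
demonstrates that the *algorithms* (cleanup, selective/adaptive smoothing,
shared-node snapping, constrained filling, node-set recovery, solving)
behave correctly on anisotropic stair-stepped geometry — not that real
patient anatomy will always mesh below the same quality bounds.

## Cohort statistics

Quality is evaluated label-wise: the per-label mean percentage of poor
elements over all successful models of that label; failed models are
excluded from the means and tallied by failure category.  Desk-scale
problem sizes used by the acceptance checks: 30 subjects × (3 vertebrae +
2 discs) at 1 mm target edge (≈ 25–35 k linear tets per vertebra), and 50
randomized single-vertebra phantoms; both cohorts finish in about a minute
on one core.

## Known limitations

* Homogeneous isotropic materials; no cortical shell, no biphasic or
  fiber-reinforced disc, no nucleus/annulus split (tetrahedra are filled
  isotropically).
* Linearized kinematics throughout; the 7.5 N·m moment on a soft disc
  produces rotations at the edge of small-rotation validity — results are
  pipeline-verification output, not biomechanics.
* The Delaunay-carve filler guarantees vertex retention but not exact
  facet recovery; for strongly non-convex bodies (deep concavities thinner
  than the lattice spacing) boundary fidelity degrades before the 0.5 %
  volume check would catch it.  Phantom and endplate-type geometry is well
  inside its comfort zone.
* Stage timings are recorded per body for reporting but are
  hardware-dependent and deliberately untested.
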