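# Methods

## The refinement model

A displacement vector field (DVF) `u` on the reference grid follows the
pull-back convention: the vector stored at fixed-space point `x` points to
the corresponding moving-space point `x + u(x)`, so warping resamples the
moving image there. This is the only convention consistent with both
warping later-phase images onto the reference and with prescribing FEM
boundary conditions on the *reference* organ surface; file formats do not
record the convention, so it is fixed here package-wide.

Refinement treats the organ as a homogeneous isotropic linear-elastic solid
in static equilibrium with no body forces, loaded purely through prescribed
surface displacements. The surface motion is taken from the initial
registration (sampled trilinearly at the surface-mesh nodes); the interior
is whatever linear elasticity says it must be. Assumptions worth keeping in
mind:

* **Linear kinematics.** Strains of tens of percent are outside the small-
  strain regime; the model is used here the way it is used clinically, as a
  physically-regularized interpolant of surface motion, not as a contact
  simulation.
* **Homogeneity.** One (E, ν) per organ. Under full-surface Dirichlet
  conditions the stiffness matrix is linear in E on both sides of the
  reduced system, so E cancels *exactly* — only the Poisson ratio shapes
  the interior solution. This is why the refinement is robust to the large
  uncertainty in absolute soft-tissue stiffness, and it is verified to
  1e-8 in the tests.
* **Element.** 4-node constant-strain tetrahedra. At ν = 0.40 volumetric
  locking is mild; no mitigation is applied, and ν ≥ 0.45 should be used
  with caution. The affine patch test (exact reproduction of affine
  boundary data) passes to solver precision on every mesh the pipeline
  generates.

Defaults ν = 0.40 and E = 0.27 MPa are standard solid-soft-tissue
(prostate-like) constants; units are mm and MPa throughout, consistent
because only displacements are consumed (stress is never reported).

The solver eliminates Dirichlet DOFs (prescribed nodes carry their values
exactly), factorizes the reduced SPD matrix with sparse LU below 2·10⁵
unknowns and falls back to Jacobi-preconditioned CG above; the
factorization is cached so repeated solves on one organ (one per
deformation stage) reuse it. Per-element deformation Jacobians
det(I + ∇u) are reported after every solve and a warning is due if any is
non-positive.

## Meshing

The organ surface comes from marching cubes on the Gaussian-smoothed
(σ = 1 voxel) mask at iso-level 0.5, followed by Taubin smoothing
(λ = 0.5, ν = −0.53, 10 iterations). Two calibrations keep the surface
faithful and cheap: the marching-cubes step size is raised until at most
8000 triangles remain (a decimation stand-in; sub-voxel surface error at
desk-scale grids), and the vertices are rescaled about their centroid so
the enclosed volume equals the voxel-counted mask volume, cancelling the
systematic shrinkage of iso-surfacing plus Taubin smoothing (about 1–2 %
for convex organs, more at coarser steps).

Volume meshing is a native Delaunay backend: scipy's Delaunay
triangulation of the surface vertices, any requested feature points, and a
jittered interior lattice; tetrahedra whose centroid falls outside the
surface (generalized winding number, numba-accelerated) are discarded and
the rest are oriented positively. The lattice pitch is refined until the
mean tetrahedron volume is at or below the target — by default 0.9× the
image voxel volume, the sizing rule that keeps piecewise-linear
interpolation of the solution sub-voxel accurate. The Dirichlet node set
is the union of the surviving surface vertices and every node on a
boundary face of the final mesh: tet filtering near the surface can expose
interior lattice nodes, and an unconstrained boundary node would break the
patch test (affine stress has nonzero boundary traction).

Per-tet quality measures: signed volume, radius ratio (3·r_in/R_circ),
edge ratio (min/max edge), min/max dihedral angle, volume–edge measure
(6√2·V/ℓ_rms³), and aspect ratio (ℓ_max/(2√6·r_in)); all equal 1 (70.529°
for dihedrals) on the regular tetrahedron, which the tests pin to 1e-9.
Known limitation: Delaunay over scattered boundary vertices produces some
slivers (near-zero radius ratio); they are harmless to the direct solver
and to interpolation accuracy at this scale but would matter for iterative
solvers on much larger meshes.

Scattering the nodal solution to the grid locates each organ voxel center
in its containing tet (KD-tree over centroids, barycentric containment at
tolerance −1e-9) and interpolates the four nodal vectors — exact for
linear fields. Mask voxels caught between the voxelized contour and the
smoothed surface use the barycentric extrapolation of the best candidate
tet; beyond one voxel from any node the nearest node's value is used, and
both cases are counted in the scatter report. Voxels outside the organ
keep the initial field bit-for-bit (hard switch at the mask; the surface
agreement of the two fields keeps the seam small).

## The synthetic phantom

The generator emulates a multi-stage deformable pelvis phantom: an
ellipsoidal organ (semi-axes 22.1 × 19.25 × 25.35 mm, i.e. half of
44.2 × 38.5 × 50.7 mm outer dimensions) holding a bright, gently bowed
tube (radius 3 mm) as an internal-accuracy surrogate, on a 64³ grid at
1 mm isotropic spacing. That resolution is the package's study condition:
it holds the full organ with margin in a desk-scale volume while keeping
the sub-voxel mesh-sizing rule meaningful.

The stage-`i` ground truth is a radial Gaussian balloon push

    u(x; i) = a_i · exp(−‖x−c‖² / 2σ²) · min(‖x−c‖/(σ/2), 1) · (x−c)/‖x−c‖

with a linear amplitude schedule a_i = (i/10)·a_max, σ = 12 mm and
a_max = 6 mm. The linear core ramp removes the direction singularity at
the push center (material at the center of a balloon does not translate),
keeping the field Lipschitz so the fixed-point inversion converges. The
push center sits 6 mm *outside* the anterior organ surface: pressing from
outside indents the near surface while the far side barely moves, so the
organ is net-compressed and the mean organ Jacobian decreases
monotonically with stage (≈ 0.997 → 0.975 at the defaults) — the
phenomenology of a balloon squeezing a solid organ. The amplitude bound
a_max < σ√e guarantees positivity of the analytic Jacobian; it is also
checked numerically at generation (min J ≈ 0.91 at stage 10).

Deformed images are built by resampling the reference texture at the
inverse map, computed by damped fixed-point iteration (relaxation 0.5,
tolerance 1e-3 mm, ≤ 50 iterations), so the generated field is exactly the
pull-back DVF the pipeline consumes; warping a deformed stage back by its
ground truth recovers the reference to < 2 % normalized RMS over the organ
interior. The texture is a band-limited Gaussian random field (blob scale
3 voxels, fixed seed) for the feature-rich variant, smoothed by 0.7 voxel
to emulate partial-volume/PSF blur; `mask_interior` produces the
feature-poor variant by overriding the organ interior (after 1-voxel
erosion, so the boundary contrast survives for surface matching) with its
mean intensity. The phantom does not model imaging physics — no noise
spectra, bias fields, or modality-specific contrast — so passing tests
demonstrate the mechanics and the pipeline, not robustness to scanner
artifacts.

`corrupt_dvf` is the stand-in for an intensity-based registration on the
feature-poor variant: smooth vector noise (correlation length 8 mm)
windowed to zero within 3 mm of the organ surface (outside the trilinear
support of any surface node, so sampled surface displacements stay exact)
and ramping to full strength 7 mm deep. The windowed perturbation is
scaled so its 95th-percentile magnitude inside the organ equals `amp_mm`
(default 4 mm): the parameter states how wrong a typical badly-constrained
interior voxel is, matching the several-mm interior discrepancies such
registrations leave in feature-free organs. At stage 0 (no deformation) no
corruption is applied — an identity registration has nothing to get wrong.

Because the surface boundary conditions are exact, the refined field is
independent of the corruption; its residual error against the ground truth
is pure model discrepancy (elastic interior vs. Gaussian push), growing
with stage amplitude to ≈ 0.07 mm median / ≈ 1.3 mm 95th-percentile at
stage 10. "Interior" in all recovery statistics means the organ mask
eroded by 3 voxels, excluding the shell where the exact surface conditions
dominate both fields.

## Evaluation battery

Definitions fixed here because the literature varies: Hausdorff distance
is the symmetric max of the two directed boundary-voxel maxima; mean
surface distance the average of the two directed means; boundary voxels
are the mask minus its 6-connected erosion, with Euclidean distances in mm
respecting anisotropic spacing. The Jacobian gradient uses central
differences (one-sided at grid borders). TRD fractions default to the 1.5
and 2.0 mm report cuts. All of these are tested against brute-force
O(n²)/counting oracles to 1e-9 on random 20³ grids.

## Reproducibility and problem sizes

Every stochastic component (texture, mesh-lattice jitter, corruption) is
driven by explicit seeds; a fixed experiment seed gives byte-identical
summary tables. The study-scale experiment (64³ phantom, ten stages,
~10 000-node mesh, one factorization reused across stages) runs in a few
minutes on one CPU; the examples use a 48³ phantom for quicker turnaround.

## Known limitations

* Single-organ refinement; no shared-interface multi-organ models, no
  IM↔FEM alternation, no heterogeneous per-element material maps.
* Constant-strain tets with no locking mitigation near ν → 0.5.
* Delaunay-based fill assumes a star-shaped-ish organ for exact volume
  capture; strongly concave organs rely on the centroid-containment filter
  and the nearest-tet extrapolation shell.
* Oblique image orientations beyond axis permutations/flips, DICOM series
  and 2-D inputs are out of scope.
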