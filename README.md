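# bmdir — biomechanical refinement of deformable-registration fields

Intensity-based deformable image registration (DIR) aligns two images by
optimizing image similarity plus a generic smoothness term. Inside
intensity-homogeneous organs — soft tissue on CT, contrast-suppressed MR,
CBCT, ultrasound — there are no features for the similarity term to lock
onto, so the *interior* of the estimated displacement vector field (DVF) is
governed by the regularizer and can be badly wrong even when the organ
surface is matched perfectly. That matters wherever voxel-wise
correspondence is consumed downstream: dose accumulation and adaptive
planning in radiotherapy, contour propagation, longitudinal response
assessment.

`bmdir` refines such a DVF one organ at a time with a biomechanical model:

1. extract the organ surface from its mask (marching cubes + Taubin
   smoothing, volume-calibrated against the voxel count);
2. fill it with a quality-checked tetrahedral mesh whose mean element
   volume stays below the image voxel volume;
3. sample the initial DVF at the surface nodes as Dirichlet boundary
   conditions;
4. solve the linear-elastic equilibrium **div σ(u) = 0**,
   σ = λ tr(ε) I + 2με, ε = ½(∇u + ∇uᵀ), for the interior node
   displacements (soft-tissue defaults ν = 0.40, E = 0.27 MPa; under
   full-surface Dirichlet conditions E cancels exactly, so only ν matters);
5. scatter the nodal solution back to the voxel grid by barycentric
   interpolation; voxels outside the organ keep the initial field.

The package also ships the evaluation battery used to QA such refinements —
Dice overlap, symmetric Hausdorff and mean surface distance, Jacobian maps
det(I + ∇u), target registration discrepancy (TRD) between two fields, and
landmark TRE — plus a synthetic multistage deformable phantom (an organ
with an internal tube, graded balloon-push stages, analytic ground-truth
DVFs) so the whole pipeline is testable end to end with no external data.

## Worked example

`examples/03_refine_dvf.py` deforms a small phantom (stage 5, 4 mm balloon
push), corrupts the ground-truth DVF in the organ interior while keeping
the surface exact — a stand-in for a feature-starved intensity
registration — and refines it:

```
mesh: 5456 nodes / 22331 tets, solver residual 2.1e-15
corrupted: median interior error 1.222 mm, p95 3.024 mm, tube DSC 0.568, interior Jacobian SD 0.3376
  refined: median interior error 0.135 mm, p95 0.913 mm, tube DSC 0.882, interior Jacobian SD 0.0069
```

Reading: the corrupted field misplaces a typical interior voxel by 1.2 mm
and the warped internal tube barely overlaps its reference contour
(Dice 0.57). Rebuilding the interior from surface motion alone cuts the
median error by ~9× and restores the tube overlap to 0.88, and the far
smoother Jacobian (SD 0.34 → 0.007) indicates a physically plausible,
fold-free deformation. `examples/04_full_experiment.py` repeats this for
every deformation stage and prints the summary table.

## Command line

```bash
bmdir phantom --config spec.yaml --out phantom/      # synthetic phantom stages
bmdir mesh --mask organ.nii.gz --out mesh.vtk        # surface + tet mesh
bmdir refine --dvf init.nii.gz --mask organ.nii.gz --out refined.nii.gz
bmdir metrics --fixed-mask a.nii.gz --moving-mask b.nii.gz \
              --dvf d.nii.gz --report report.json
bmdir experiment --out results/ --seed 0             # multistage recovery study
```

Volumes are NIfTI (scalar or 3-component vector) or NRRD; landmarks are CSV
with columns `label,fx,fy,fz,mx,my,mz` in physical mm.

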