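"""Biomechanically refine a corrupted displacement field inside an organ.

The initial field is the phantom's ground truth degraded in the organ
interior (emulating an intensity-based registration with no interior
features to lock onto) while kept exact at the surface.  Refinement
rebuilds the interior from the surface motion via a linear-elastic FEM
(nu = 0.40, E = 0.27 MPa) and should recover most of the lost accuracy:
the median interior error collapses and the warped internal tube overlaps
its reference contour again.
"""

import numpy as np
from scipy import ndimage

from bmdir import (PhantomSpec, RefinementConfig, corrupt_dvf, dice,
                   generate_phantom, jacobian_map, refine, warp_mask)

spec = PhantomSpec(shape=(48, 48, 48), semi_axes=(14.0, 12.0, 16.0),
                   tube_radius_mm=2.5, tube_bow_mm=2.0, push_sigma_mm=9.0, push_standoff_mm=5.0,
                   a_max_mm=4.0, n_stages=5, texture_seed=3)
stages = generate_phantom(spec)
stage = stages[-1]                       # the largest deformation
organ = stage.organ_ref

corrupted = corrupt_dvf(stage.dvf_gt, organ, amp_mm=3.0, corr_len_mm=7.0,
                        surface_margin_mm=2.5, seed=1)
result = refine(corrupted, organ, RefinementConfig())
print(f"mesh: {result.mesh.n_nodes} nodes / {result.mesh.n_tets} tets, "
      f"solver residual {result.solution.residual:.1e}")

interior = ndimage.binary_erosion(organ.voxels.astype(bool), iterations=3)
for name, dvf in (("corrupted", corrupted), ("refined", result.dvf)):
    err = np.linalg.norm(dvf.voxels - stage.dvf_gt.voxels, axis=-1)[interior]
    dsc = dice(stage.tube_ref, warp_mask(stage.tube_def, dvf))
    jstd = jacobian_map(dvf, organ.same_grid(interior))["std"]
    print(f"{name:>9}: median interior error {np.median(err):.3f} mm, "
          f"p95 {np.percentile(err, 95):.3f} mm, "
          f"tube DSC {dsc:.3f}, interior Jacobian SD {jstd:.4f}")
print("\nrefined < corrupted on every count: the elastic interior driven by "
      "the exact surface\nmotion is far closer to the ground truth than the "
      "feature-starved initial field.")
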