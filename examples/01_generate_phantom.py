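"""Generate a multistage deformable phantom and inspect its ground truth.

Builds a small ellipsoidal organ with an internal bright tube, deformed
through graded balloon-push stages, and prints per-stage displacement and
Jacobian statistics: the mean displacement grows linearly with the stage
amplitude while the mean Jacobian inside the organ falls below 1 — the
organ is progressively compressed by the push.
"""

import numpy as np

from bmdir import PhantomSpec, generate_phantom, jacobian_map

spec = PhantomSpec(shape=(48, 48, 48), semi_axes=(14.0, 12.0, 16.0),
                   tube_radius_mm=2.5, tube_bow_mm=2.0, push_sigma_mm=9.0, push_standoff_mm=5.0,
                   a_max_mm=4.0, n_stages=5, texture_seed=3)
stages = generate_phantom(spec)
organ = stages[0].organ_ref
sel = organ.voxels.astype(bool)

print(f"organ: {organ.count} voxels ({organ.volume_mm3:.0f} mm^3), "
      f"tube: {stages[0].tube_ref.count} voxels")
print(f"{'stage':>5} {'amplitude mm':>13} {'mean |u| mm':>12} "
      f"{'mean J':>8} {'min J':>8}")
for st in stages:
    j = jacobian_map(st.dvf_gt, organ)
    print(f"{st.index:>5} {spec.amplitude(st.index):>13.2f} "
          f"{st.dvf_gt.magnitude()[sel].mean():>12.3f} "
          f"{j['mean']:>8.4f} {j['min']:>8.4f}")
print("\nmin J > 0 everywhere: the ground-truth deformation never folds.")
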