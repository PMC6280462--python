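"""Mesh an organ mask: marching-cubes surface + tetrahedral volume fill.

The mean tetrahedron volume is kept slightly below the image voxel volume
so that piecewise-linear interpolation of the FEM solution stays sub-voxel
accurate, and the mesh volume is checked against the voxel-counted organ
volume.
"""

import numpy as np

from bmdir import BinaryMask, extract_surface, tetrahedralize

# a 10 mm ball in a 1 mm grid
n = 27
idx = np.stack(np.meshgrid(*[np.arange(n)] * 3, indexing="ij"), axis=-1)
center = (n - 1) / 2.0
mask = BinaryMask(np.linalg.norm(idx - center, axis=-1) <= 10.0, (1, 1, 1))

surface = extract_surface(mask, smoothing_iters=10)
print(f"surface: {len(surface.vertices)} vertices, "
      f"{len(surface.triangles)} triangles, "
      f"area {surface.area():.0f} mm^2 (sphere: {4 * np.pi * 100:.0f}), "
      f"volume {surface.enclosed_volume():.0f} mm^3 "
      f"(sphere: {4 / 3 * np.pi * 1000:.0f})")

mesh = tetrahedralize(surface, target_mean_volume_mm3=0.9 * mask.voxel_volume)
vols = mesh.volumes()
print(f"mesh: {mesh.n_nodes} nodes, {mesh.n_tets} tets "
      f"({len(mesh.surface_node_ids)} on the surface)")
print(f"total volume {vols.sum():.0f} mm^3 vs mask {mask.volume_mm3:.0f} mm^3 "
      f"({100 * abs(vols.sum() - mask.volume_mm3) / mask.volume_mm3:.2f}% off)")
print(f"mean tet volume {vols.mean():.3f} mm^3 (voxel = 1.0)")

q = mesh.quality
print("\nquality (min / mean over tets):")
for col in ("radius_ratio", "edge_ratio", "volume_edge"):
    print(f"  {col:<14} {q[col].min():.3f} / {q[col].mean():.3f}")
print(f"  dihedral range {q['min_dihedral_deg'].min():.1f} - "
      f"{q['max_dihedral_deg'].max():.1f} deg (regular tet: 70.53)")
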