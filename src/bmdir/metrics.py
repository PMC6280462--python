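"""Registration QA metrics: overlap, surface distances, Jacobian, TRD, TRE.

Definitions fixed here (the literature varies):

* Hausdorff distance is symmetric: the max of the two directed maxima of
  boundary-voxel distances.
* Mean surface distance is the average of the two directed mean distances.
* Boundary voxels are the mask minus its 6-connected erosion; distances are
  Euclidean in mm, respecting anisotropic spacing.
* The Jacobian determinant is det(I + grad u) with central differences
  (one-sided at the grid border).  Values below 1 indicate local
  contraction, above 1 dilation, and non-positive values folding.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, DisplacementField, LandmarkSet, sample_dvf

__all__ = [
    "MetricsReport",
    "dice",
    "surface_distances",
    "jacobian_map",
    "trd",
    "tre",
    "evaluate_masks",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|)."""
    _check_grids(a, b)
    na, nb = a.count, b.count
    if na == 0 and nb == 0:
        raise ValueError("Dice undefined for two empty masks")
    inter = int(np.logical_and(a.voxels, b.voxels).sum())
    return 2.0 * inter / (na + nb)


def boundary_voxels(mask: BinaryMask) -> np.ndarray:
    """Indices (n, 3) of boundary voxels: mask minus its 6-connected erosion."""
    m = mask.voxels.astype(bool)
    inner = ndimage.binary_erosion(m, structure=_STRUCT6, border_value=0)
    return np.argwhere(m & ~inner)


def surface_distances(a: BinaryMask, b: BinaryMask) -> tuple[float, float]:
    """(Hausdorff, mean surface distance) between mask boundaries, in mm."""
    _check_grids(a, b)
    if a.count == 0 or b.count == 0:
        raise ValueError("surface distances undefined for an empty mask")
    ba, bb = boundary_voxels(a), boundary_voxels(b)
    d_ab = _directed(ba, bb, a.spacing)   # each a-boundary voxel -> nearest b
    d_ba = _directed(bb, ba, a.spacing)
    hausdorff = max(float(d_ab.max()), float(d_ba.max()))
    msd = 0.5 * (float(d_ab.mean()) + float(d_ba.mean()))
    return hausdorff, msd


def _directed(src_idx: np.ndarray, dst_idx: np.ndarray, spacing) -> np.ndarray:
    """Distance (mm) from each src boundary voxel to the nearest dst one."""
    from scipy.spatial import cKDTree
    sp = np.asarray(spacing)
    tree = cKDTree(dst_idx * sp)
    d, _ = tree.query(src_idx * sp, workers=-1)
    return d


def jacobian_map(dvf: DisplacementField, mask: BinaryMask | None = None) -> dict:
    """Jacobian-determinant map of det(I + grad u) with summary statistics.

    Returns ``{"map", "mean", "min", "max", "std"}`` where the statistics
    are taken over the mask (or the whole grid if no mask is given).
    """
    if any(n < 3 for n in dvf.shape):
        raise ValueError("Jacobian needs at least 3 voxels per axis")
    u = dvf.voxels
    sp = dvf.spacing
    G = np.empty(dvf.shape + (3, 3))
    for comp in range(3):
        gx, gy, gz = np.gradient(u[..., comp], sp[0], sp[1], sp[2])
        G[..., comp, 0] = gx
        G[..., comp, 1] = gy
        G[..., comp, 2] = gz
    J = np.linalg.det(np.eye(3) + G)
    sel = mask.voxels.astype(bool) if mask is not None else np.ones(dvf.shape, bool)
    vals = J[sel]
    return {"map": J, "mean": float(vals.mean()), "min": float(vals.min()),
            "max": float(vals.max()), "std": float(vals.std())}


def jacobian_profile(jac_map: np.ndarray, axis: int, slice_index: int,
                     line_index: int) -> np.ndarray:
    """Extract a 1-D Jacobian profile from an axial slice (QA plotting aid)."""
    sl = np.take(jac_map, slice_index, axis=2)
    return np.take(sl, line_index, axis=1 - axis)


def trd(dvf_a: DisplacementField, dvf_b: DisplacementField,
        mask: BinaryMask | None = None,
        thresholds_mm=(1.5, 2.0)) -> dict:
    """Target registration discrepancy between two DVFs.

    Per-voxel ``||u_a - u_b||`` (mm) inside the mask, its cumulative
    histogram, and the fraction of voxels above each threshold (defaults
    1.5 and 2.0 mm).
    """
    if not dvf_a.grid_matches(dvf_b):
        raise ValueError("DVF grids do not match")
    diff = np.linalg.norm(dvf_a.voxels - dvf_b.voxels, axis=-1)
    sel = mask.voxels.astype(bool) if mask is not None else np.ones(diff.shape, bool)
    vals = diff[sel]
    edges = np.linspace(0, max(vals.max(), 1e-9), 65)
    counts, edges = np.histogram(vals, bins=edges)
    cum = np.cumsum(counts) / max(len(vals), 1)
    frac_above = {float(t): float(np.mean(vals > t)) for t in thresholds_mm}
    return {"map": np.where(sel, diff, 0.0), "values": vals,
            "hist_edges": edges, "cumulative": cum, "frac_above": frac_above}


def tre(landmarks: LandmarkSet, dvf: DisplacementField) -> dict:
    """Target registration error per landmark (mm) with mean ± SD.

    ``TRE_k = ||(fixed_k + u(fixed_k)) - moving_k||``; with a zero field
    this is the raw landmark displacement.
    """
    lo = np.array(dvf.origin)
    hi = lo + (np.array(dvf.shape) - 1) * np.array(dvf.spacing)
    if np.any(landmarks.fixed < lo - 1e-9) or np.any(landmarks.fixed > hi + 1e-9):
        raise ValueError("a fixed landmark lies outside the DVF grid")
    u = sample_dvf(dvf, landmarks.fixed)
    err = np.linalg.norm(landmarks.fixed + u - landmarks.moving, axis=1)
    return {"per_landmark": dict(zip(landmarks.labels, err.tolist())),
            "mean": float(err.mean()), "sd": float(err.std())}


@dataclasses.dataclass
class MetricsReport:
    """Bundle of the evaluation battery for one mask pair / DVF."""

    dsc: float
    hausdorff_mm: float
    mean_surface_distance_mm: float
    jacobian: dict | None = None
    trd_summary: dict | None = None
    tre_summary: dict | None = None

    def to_dict(self) -> dict:
        out = {"dsc": self.dsc, "hausdorff_mm": self.hausdorff_mm,
               "mean_surface_distance_mm": self.mean_surface_distance_mm}
        if self.jacobian is not None:
            out["jacobian"] = {k: v for k, v in self.jacobian.items() if k != "map"}
        if self.trd_summary is not None:
            out["trd"] = {"frac_above": self.trd_summary["frac_above"]}
        if self.tre_summary is not None:
            out["tre"] = self.tre_summary
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate_masks(reference: BinaryMask, warped: BinaryMask,
                   dvf: DisplacementField | None = None,
                   jacobian_mask: BinaryMask | None = None,
                   landmarks: LandmarkSet | None = None) -> MetricsReport:
    """Full overlap/distance report for a warped structure vs its reference."""
    hd, msd = surface_distances(reference, warped)
    jac = jacobian_map(dvf, jacobian_mask) if dvf is not None else None
    tre_s = tre(landmarks, dvf) if (landmarks is not None and dvf is not None) else None
    return MetricsReport(dice(reference, warped), hd, msd, jacobian=jac,
                         tre_summary=tre_s)


def _check_grids(a: BinaryMask, b: BinaryMask) -> None:
    if not a.grid_matches(b):
        raise ValueError("masks are not on the same grid")
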