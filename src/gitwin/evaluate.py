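"""Scoring a candidate deformation (from any DIR tool) against ground truth.

The digital twin provides the ground-truth displacement field and the
deformed anatomy for every phase; a registration algorithm under test
provides a candidate field between phase 0 and (typically) the phase of
maximum deformation. This module computes the geometric, deformation and
dosimetric accuracy measures used for that comparison:

* TRE — target registration error at surface/inner-shell sample points,
  ``||u_gt(x) - u_cand(x)||`` with trilinear field sampling;
* DSC / HD95 — overlap and 95th-percentile symmetric surface distance of the
  warped organ masks (spacing-aware, computed on boundary voxels);
* log-Jacobian summary of either field;
* DWE — dose-warping error: signed relative difference of the dose
  accumulated (direct dose mapping, averaged over phases) through candidate
  vs ground-truth deformations, reported as a mean percent over an ROI;
* voxel-level RMSE of ``||u_cand - u_gt||`` binned by ground-truth motion
  magnitude or by dose level, plus a voxelwise error heat-map volume.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .dvf import invert_field, warp
from .surface import ShellStack
from .volio import DisplacementField, LabelMask, VolumeGrid

__all__ = [
    "EvalPoints",
    "tre",
    "dsc",
    "hd95",
    "dwe",
    "accumulate_dose",
    "rmse_binned",
    "error_heatmap",
    "shell_eval_points",
]

DOSE_FLOOR_GY = 0.5  # accumulated-dose floor below which DWE voxels are excluded


@dataclasses.dataclass
class EvalPoints:
    """World-mm sample points from the organ surface and inner shells."""

    points: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)


def shell_eval_points(
    stack: ShellStack, grid_uv: tuple[int, int] = (40, 36), max_p: float = 0.99
) -> EvalPoints:
    """Sample every shell with p < max_p (the centerline shell is excluded:
    its points are degenerate in v)."""
    n_u, n_v = grid_uv
    u = np.linspace(0.0, 1.0, n_u)
    v = np.linspace(0.0, 1.0, n_v, endpoint=False)
    pts = [
        shell.evaluate(u, v).reshape(-1, 3)
        for shell, p in zip(stack.shells, stack.radial_factors)
        if p < max_p
    ]
    if len(pts) < 2:
        raise ValueError("need at least two shell levels for evaluation points")
    return EvalPoints(points=np.concatenate(pts))


def _sample(field: DisplacementField, pts: np.ndarray) -> np.ndarray:
    idx = field.world_to_index(pts)
    shape = np.array(field.shape)
    if np.any(idx < -0.5) or np.any(idx > shape - 0.5):
        raise ValueError("evaluation point outside the field grid")
    out = np.empty_like(pts)
    for c in range(3):
        out[:, c] = ndimage.map_coordinates(
            field.data[..., c], idx.T, order=1, mode="nearest"
        )
    return out


def tre(
    points: EvalPoints, gt: DisplacementField, cand: DisplacementField
) -> dict:
    """Target registration error at each point: distance between the two
    mapped positions ``(x + u_gt) - (x + u_cand)``. Symmetric in gt/cand."""
    gt.require_same_grid(cand, "candidate field")
    err = np.linalg.norm(
        _sample(gt, points.points) - _sample(cand, points.points), axis=1
    )
    return {
        "mean_mm": float(err.mean()),
        "sd_mm": float(err.std()),
        "max_mm": float(err.max()),
        "per_point_mm": err,
    }


def dsc(a: LabelMask, b: LabelMask) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|); two empty masks -> 1."""
    a.require_same_grid(b, "mask")
    na, nb = a.num_foreground, b.num_foreground
    if na + nb == 0:
        return 1.0
    inter = int(np.count_nonzero((a.data > 0) & (b.data > 0)))
    return 2.0 * inter / (na + nb)


def _boundary_points_mm(mask: LabelMask) -> np.ndarray:
    m = mask.data.astype(bool)
    eroded = ndimage.binary_erosion(m)
    idx = np.argwhere(m & ~eroded)
    return mask.origin + idx * mask.spacing


def hd95(a: LabelMask, b: LabelMask) -> float:
    """95th percentile of the pooled symmetric boundary-to-boundary nearest
    distances (mm), linear-interpolated percentile."""
    a.require_same_grid(b, "mask")
    if a.num_foreground == 0 or b.num_foreground == 0:
        raise ValueError("hd95 requires two nonempty masks")
    pa, pb = _boundary_points_mm(a), _boundary_points_mm(b)
    d_ab, _ = cKDTree(pb).query(pa)
    d_ba, _ = cKDTree(pa).query(pb)
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))


def accumulate_dose(dose: VolumeGrid, fields: list[DisplacementField]) -> VolumeGrid:
    """Direct dose mapping: mean over phases of the dose resampled through
    each phase's deformation."""
    acc = np.zeros(dose.shape)
    for f in fields:
        f.require_same_grid(dose, "dose")
        acc += warp(dose, f, kind="dose").data
    return VolumeGrid(data=acc / len(fields), spacing=dose.spacing, origin=dose.origin)


def dwe(
    accum_dir: VolumeGrid,
    accum_gt: VolumeGrid,
    roi: LabelMask,
    dose_floor: float = DOSE_FLOOR_GY,
) -> dict:
    """Dose-warping error over an ROI: signed relative difference of the two
    accumulated doses. Reported as mean percent per voxel; the raw sum of
    relative differences and the count of excluded sub-floor voxels are also
    returned."""
    accum_gt.require_same_grid(accum_dir, "accumulated dose")
    accum_gt.require_same_grid(roi, "ROI")
    if roi.num_foreground == 0:
        raise ValueError("DWE requires a nonempty ROI")
    sel = roi.data > 0
    gt_vals = accum_gt.data[sel]
    dir_vals = accum_dir.data[sel]
    ok = gt_vals > dose_floor
    if not np.any(ok):
        raise ValueError(
            f"all {int(sel.sum())} ROI voxels are below the dose floor "
            f"{dose_floor} Gy"
        )
    rel = (dir_vals[ok] - gt_vals[ok]) / gt_vals[ok]
    return {
        "mean_percent": float(rel.mean() * 100.0),
        "sum_relative": float(rel.sum()),
        "n_voxels": int(ok.sum()),
        "n_below_floor": int((~ok).sum()),
    }


def rmse_binned(
    gt: DisplacementField,
    cand: DisplacementField,
    bin_by: str = "motion",
    aux: VolumeGrid | None = None,
    edges: np.ndarray | None = None,
    roi: LabelMask | None = None,
) -> list[dict]:
    """RMSE of ||u_cand - u_gt|| per bin of GT motion magnitude (mm) or of
    dose (Gy). Empty bins are omitted. Default motion bins are 1 mm wide from
    0 to the max GT magnitude; default dose bins are 10 Gy wide."""
    gt.require_same_grid(cand, "candidate field")
    if bin_by == "motion":
        key = gt.magnitude()
        if edges is None:
            top = max(float(key.max()), 1.0)
            edges = np.arange(0.0, np.ceil(top) + 1.0)
    elif bin_by == "dose":
        if aux is None:
            raise ValueError("dose binning requires a dose volume")
        gt.require_same_grid(aux, "dose")
        key = np.asarray(aux.data, dtype=float)
        if edges is None:
            edges = np.arange(0.0, np.ceil(key.max() / 10.0) * 10.0 + 10.0, 10.0)
    else:
        raise ValueError(f"bin_by must be 'motion' or 'dose', got {bin_by!r}")
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    err = np.linalg.norm(cand.data - gt.data, axis=-1)
    if roi is not None:
        gt.require_same_grid(roi, "ROI")
        sel = roi.data > 0
        key, err = key[sel], err[sel]
    else:
        key, err = key.ravel(), err.ravel()
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (key >= lo) & (key < hi)
        n = int(in_bin.sum())
        if n == 0:
            continue
        rows.append(
            {
                "bin_lo": float(lo),
                "bin_hi": float(hi),
                "n_voxels": n,
                "rmse_mm": float(np.sqrt(np.mean(err[in_bin] ** 2))),
            }
        )
    return rows


def error_heatmap(gt: DisplacementField, cand: DisplacementField) -> VolumeGrid:
    """Voxelwise ||u_cand - u_gt|| (mm) as a volume for heat-map export."""
    gt.require_same_grid(cand, "candidate field")
    err = np.linalg.norm(cand.data - gt.data, axis=-1)
    return VolumeGrid(data=err, spacing=gt.spacing, origin=gt.origin)


def load_candidate(field: DisplacementField, convention: str = "forward") -> DisplacementField:
    """Adapt an externally produced DVF to the forward-map convention.

    Tools that emit backward (pull) fields are converted by fixed-point
    inversion of the stored field.
    """
    if convention == "forward":
        return field
    if convention == "backward":
        inv, _ = invert_field(field)
        return inv
    raise ValueError(f"convention must be forward|backward, got {convention!r}")
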