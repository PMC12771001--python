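"""Synthetic curved-tube organ phantoms, intensity volumes and toy dose maps.

A phantom is a solid tube swept along a smooth 3D path (C-arc, torus arc,
straight segment) with a possibly tapering radius, rasterized on a regular
grid. The analytic path is kept alongside the mask, serving as ground truth
for centerline recovery and for analytically deformed reference masks; no
patient data is required anywhere in the test pipeline.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy.spatial import cKDTree

from .volio import LabelMask, VolumeGrid

__all__ = [
    "PhantomSpec",
    "TubePath",
    "make_tube_mask",
    "make_phantom_image",
    "make_dose_map",
    "preset",
    "PRESETS",
]


@dataclasses.dataclass
class TubePath:
    """Dense polyline sampling of an analytic tube axis with per-point radius.

    ``points`` are world-mm positions ordered along the path; ``radius`` is the
    local tube radius in mm (tapering allowed); ``arc_length`` is cumulative mm.
    """

    points: np.ndarray  # (n, 3) mm
    radius: np.ndarray  # (n,) mm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.radius = np.broadcast_to(
            np.asarray(self.radius, dtype=float), (len(self.points),)
        ).copy()
        if np.any(self.radius <= 0):
            raise ValueError("tube radius must be positive everywhere")

    @property
    def arc_length(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "points_mm": self.points.tolist(),
                    "radius_mm": self.radius.tolist(),
                    "arc_length_mm": self.arc_length.tolist(),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "TubePath":
        with open(path) as fh:
            d = json.load(fh)
        return cls(points=np.array(d["points_mm"]), radius=np.array(d["radius_mm"]))


@dataclasses.dataclass
class PhantomSpec:
    """Recipe for one synthetic tubular organ on a regular grid."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    path: TubePath
    lumen_fraction: float = 0.6  # lumen radius as a fraction of tube radius
    background_level: float = 100.0
    wall_level: float = 400.0
    lumen_level: float = 50.0
    noise_sd: float = 10.0
    seed: int = 0

    @property
    def origin(self) -> np.ndarray:
        return np.zeros(3)


def _grid_points(shape, spacing, origin) -> np.ndarray:
    axes = [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.stack([gx, gy, gz], axis=-1)


def distance_and_radius_to_path(
    pts_mm: np.ndarray, path: TubePath
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distance of each query point to the path polyline, plus the local tube
    radius and arc length at the nearest path sample."""
    tree = cKDTree(path.points)
    dist, idx = tree.query(pts_mm.reshape(-1, 3))
    shape = pts_mm.shape[:-1]
    return (
        dist.reshape(shape),
        path.radius[idx].reshape(shape),
        path.arc_length[idx].reshape(shape),
    )


def make_tube_mask(spec: PhantomSpec) -> LabelMask:
    """Rasterize the solid tube: voxels within the local radius of the path."""
    shape = np.asarray(spec.shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    lo = spec.origin
    hi = spec.origin + (shape - 1) * spacing
    margin = spec.path.radius
    if np.any(spec.path.points - margin[:, None] < lo) or np.any(
        spec.path.points + margin[:, None] > hi
    ):
        raise ValueError("tube exits the grid: path + radius does not fit inside")
    if np.max(spec.path.radius) < 0.5 * np.min(spacing):
        raise ValueError(
            f"sub-voxel tube: max radius {np.max(spec.path.radius):.3g} mm < half "
            f"the finest spacing {np.min(spacing):.3g} mm"
        )
    pts = _grid_points(spec.shape, spacing, spec.origin)
    dist, rad, _ = distance_and_radius_to_path(pts, spec.path)
    data = (dist <= rad).astype(np.uint8)
    if data.sum() == 0:
        raise ValueError("tube rasterized to an empty mask")
    return LabelMask(data=data, spacing=spacing, origin=spec.origin)


def make_phantom_image(mask: LabelMask, spec: PhantomSpec) -> VolumeGrid:
    """Three-level (background / wall / lumen) intensity volume with seeded noise."""
    if tuple(mask.shape) != tuple(spec.shape):
        raise ValueError(f"mask shape {mask.shape} does not match spec {spec.shape}")
    pts = _grid_points(spec.shape, mask.spacing, mask.origin)
    dist, rad, _ = distance_and_radius_to_path(pts, spec.path)
    data = np.full(mask.shape, spec.background_level, dtype=float)
    inside = mask.data > 0
    data[inside] = spec.wall_level
    data[inside & (dist <= spec.lumen_fraction * rad)] = spec.lumen_level
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)
    return VolumeGrid(data=data, spacing=mask.spacing, origin=mask.origin)


def make_dose_map(
    grid: VolumeGrid, center: np.ndarray, peak: float, sigma: float
) -> VolumeGrid:
    """Isotropic Gaussian dose blob; the maximum equals ``peak`` (Gy) at the
    voxel nearest to ``center``."""
    if peak <= 0:
        raise ValueError("dose peak must be positive")
    pts = _grid_points(grid.shape, grid.spacing, grid.origin)
    d2 = ((pts - np.asarray(center, dtype=float)) ** 2).sum(axis=-1)
    dose = np.exp(-d2 / (2.0 * sigma**2))
    dose *= peak / dose.max()
    return VolumeGrid(data=dose, spacing=grid.spacing, origin=grid.origin)


def register_to_path(path: TubePath, line_points: np.ndarray) -> tuple[float, bool]:
    """Locate a recovered centerline on the ground-truth path.

    Returns (arc_origin, reverse): the path arc length corresponding to the
    recovered line's first point, and whether the recovered line runs against
    the path's stored direction. Used to express the motion model's
    arc-length coordinate (zero at the chosen start endpoint) in the analytic
    path's parameterization.
    """
    tree = cKDTree(path.points)
    arc = path.arc_length
    a_start = float(arc[tree.query(line_points[0])[1]])
    a_end = float(arc[tree.query(line_points[-1])[1]])
    return a_start, a_end < a_start


def make_deformed_tube_mask(
    spec: PhantomSpec,
    wave_fn,
    arc_origin: float = 0.0,
    reverse: bool = False,
    radius_floor: float = 0.25,
) -> LabelMask:
    """Analytically deformed tube: the local radius r(L) becomes
    ``max(r(L) + wave_fn(L_eff), radius_floor)`` where ``L_eff`` is the arc
    length measured from ``arc_origin`` (reversed if ``reverse``).

    Serves as the independent reference for the warped-mask self-consistency
    check of the forward pipeline: the motion model is purely radial, so the
    deformed organ is again a tube around the same path with a modulated
    radius profile.
    """
    spacing = np.asarray(spec.spacing, dtype=float)
    pts = _grid_points(spec.shape, spacing, spec.origin)
    dist, rad, arc = distance_and_radius_to_path(pts, spec.path)
    L_eff = (arc_origin - arc) if reverse else (arc - arc_origin)
    new_rad = np.maximum(rad + wave_fn(L_eff), radius_floor)
    data = (dist <= new_rad).astype(np.uint8)
    return LabelMask(data=data, spacing=spacing, origin=spec.origin)


# --------------------------------------------------------------------------
# Named presets


def _c_arc_path(
    center: np.ndarray,
    arc_radius: float,
    theta0: float,
    theta1: float,
    r_start: float,
    r_end: float,
    z: float,
    n: int = 800,
) -> TubePath:
    th = np.linspace(theta0, theta1, n)
    pts = np.stack(
        [
            center[0] + arc_radius * np.cos(th),
            center[1] + arc_radius * np.sin(th),
            np.full(n, z),
        ],
        axis=-1,
    )
    rad = np.linspace(r_start, r_end, n)
    return TubePath(points=pts, radius=rad)


def _stomach_preset(seed: int) -> PhantomSpec:
    # C-arc, radius tapering 12 -> 6 mm, 96^3 grid at 2 mm (192 mm cube).
    # Tube kept >= A/sqrt(3) + 2 voxels (~13 mm) from the grid edge so the
    # voxelized DVF support never clips for the default amplitude A = 16 mm.
    path = _c_arc_path(
        center=np.array([96.0, 96.0, 0.0]),
        arc_radius=52.0,
        theta0=np.deg2rad(200.0),
        theta1=np.deg2rad(340.0),
        r_start=12.0,
        r_end=6.0,
        z=96.0,
    )
    return PhantomSpec(shape=(96, 96, 96), spacing=(2.0, 2.0, 2.0), path=path, seed=seed)


def _bowel_preset(seed: int) -> PhantomSpec:
    # Three-quarter planar torus arc, constant radius 8 mm.
    path = _c_arc_path(
        center=np.array([96.0, 96.0, 0.0]),
        arc_radius=55.0,
        theta0=np.deg2rad(10.0),
        theta1=np.deg2rad(280.0),
        r_start=8.0,
        r_end=8.0,
        z=96.0,
        n=1600,
    )
    return PhantomSpec(shape=(96, 96, 96), spacing=(2.0, 2.0, 2.0), path=path, seed=seed)


def _small_stomach_preset(seed: int) -> PhantomSpec:
    # Desk-scale variant of the stomach arc for quick tests: 64^3 at 2 mm.
    path = _c_arc_path(
        center=np.array([64.0, 64.0, 0.0]),
        arc_radius=32.0,
        theta0=np.deg2rad(200.0),
        theta1=np.deg2rad(340.0),
        r_start=10.0,
        r_end=6.0,
        z=64.0,
    )
    return PhantomSpec(shape=(64, 64, 64), spacing=(2.0, 2.0, 2.0), path=path, seed=seed)


PRESETS = {
    "stomach": _stomach_preset,
    "bowel": _bowel_preset,
    "stomach-small": _small_stomach_preset,
}


def preset(name: str, seed: int = 0) -> PhantomSpec:
    """Return a named phantom recipe ("stomach", "bowel", "stomach-small")."""
    try:
        return PRESETS[name](seed)
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
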