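"""Tubular organ surfaces: radial section casting and B-spline tube fitting.

At each equidistant centerline station the organ cross-section is sampled by
casting ``J`` equally spaced rays in the plane orthogonal to the centerline
tangent; each ray stops at its first crossing of the mask boundary, located
sub-voxel by linearly interpolating the mask's signed Euclidean distance.
The boundary points become the control net of a tube surface: a tensor-product
B-spline (a NURBS with all weights 1), clamped and cubic along the organ (u),
cubic and closed by control-point wrapping around the section (v).

Section frames are rotation-minimizing (parallel transport of the initial
normal), not Frenet frames, so the control net never twists at inflection
points of the centerline.

Inner shells carry the surface deformation into the organ interior: the shell
at radial factor ``p`` has control points ``(1-p)*P + p*center_i``, so ``p=0``
is the organ surface and ``p=1`` degenerates to the centerline.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy import ndimage
from scipy.interpolate import BSpline

from .centerline import Centerline
from .volio import LabelMask

__all__ = [
    "SectionalCurve",
    "NurbsSurface",
    "ShellStack",
    "signed_distance",
    "cast_sections",
    "fit_nurbs",
    "interpolate_shell",
    "make_shell_stack",
]


@dataclasses.dataclass
class SectionalCurve:
    """One organ cross-section: center, tangent, and J boundary points."""

    center: np.ndarray  # (3,) mm
    tangent: np.ndarray  # (3,) unit
    boundary_points: np.ndarray  # (J, 3) mm
    radii: np.ndarray  # (J,) mm
    arc_length: float  # station L_i along the centerline, mm


def _parallel_transport_frames(line: Centerline) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-minimizing (normal, binormal) frames along the centerline."""
    tangents = line.tangents()
    n = len(tangents)
    normals = np.empty((n, 3))
    t0 = tangents[0]
    seed = np.eye(3)[int(np.argmin(np.abs(t0)))]  # axis least aligned with t0
    v = seed - np.dot(seed, t0) * t0
    normals[0] = v / np.linalg.norm(v)
    for i in range(1, n):
        v = normals[i - 1] - np.dot(normals[i - 1], tangents[i]) * tangents[i]
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            raise ValueError(f"frame transport degenerated at station {i}")
        normals[i] = v / nv
    binormals = np.cross(tangents, normals)
    return normals, binormals


def signed_distance(mask: LabelMask) -> np.ndarray:
    """Signed Euclidean distance (mm): positive inside, negative outside."""
    inside = ndimage.distance_transform_edt(mask.data, sampling=mask.spacing)
    outside = ndimage.distance_transform_edt(1 - mask.data, sampling=mask.spacing)
    return inside - outside


def _sample_sdf(sdf: np.ndarray, mask: LabelMask, pts_mm: np.ndarray) -> np.ndarray:
    idx = mask.world_to_index(pts_mm)
    return ndimage.map_coordinates(
        sdf, idx.reshape(-1, 3).T, order=1, mode="constant", cval=-1e6
    ).reshape(pts_mm.shape[:-1])


def cast_sections(
    mask: LabelMask,
    line: Centerline,
    rays_per_section: int = 36,
    max_radius: float | None = None,
) -> list[SectionalCurve]:
    """Cast radial rays perpendicular to the centerline at every station.

    Each ray is marched outward from the center in fine sub-voxel steps until
    the interpolated signed distance first changes sign; the zero crossing is
    refined linearly. The first boundary crossing is kept even for non-convex
    sections.
    """
    if rays_per_section < 8:
        raise ValueError("rays_per_section must be >= 8")
    sdf = signed_distance(mask)
    normals, binormals = _parallel_transport_frames(line)
    tangents = line.tangents()
    arcs = line.arc_length
    if max_radius is None:
        max_radius = float(np.linalg.norm((np.array(mask.shape) - 1) * mask.spacing))
    step = 0.25 * float(np.min(mask.spacing))
    radii_march = np.arange(0.0, max_radius + step, step)
    angles = 2.0 * np.pi * np.arange(rays_per_section) / rays_per_section
    sections: list[SectionalCurve] = []
    for i, center in enumerate(line.points):
        if _sample_sdf(sdf, mask, center[None])[0] <= 0:
            raise ValueError(
                f"centerline station {i} at {center} lies outside the mask"
            )
        dirs = (
            np.cos(angles)[:, None] * normals[i] + np.sin(angles)[:, None] * binormals[i]
        )  # (J, 3)
        pts = center + radii_march[None, :, None] * dirs[:, None, :]  # (J, n, 3)
        vals = _sample_sdf(sdf, mask, pts)  # (J, n)
        neg = vals <= 0.0
        if not np.all(neg.any(axis=1)):
            raise ValueError(
                f"a ray from station {i} exited the grid before crossing the boundary"
            )
        first = neg.argmax(axis=1)  # first sample at/outside boundary
        if np.any(first == 0):
            raise ValueError(
                f"degenerate section at station {i}: center on the mask boundary"
            )
        # linear zero crossing between samples first-1 and first
        v0 = vals[np.arange(rays_per_section), first - 1]
        v1 = vals[np.arange(rays_per_section), first]
        frac = v0 / (v0 - v1)
        radii = (radii_march[first - 1] + frac * step).astype(float)
        boundary = center + radii[:, None] * dirs
        sections.append(
            SectionalCurve(
                center=center.copy(),
                tangent=tangents[i],
                boundary_points=boundary,
                radii=radii,
                arc_length=float(arcs[i]),
            )
        )
    return sections


@dataclasses.dataclass
class NurbsSurface:
    """Tensor-product B-spline tube (all NURBS weights 1).

    ``control_points`` has shape (I, J, 3): I sectional curves along the organ
    (u direction, clamped cubic), J points around each closed section (v
    direction, cubic, periodic by wrapping). ``centers`` and ``arc_lengths``
    keep the sectional-curve geometry needed by the motion model and shells.
    """

    control_points: np.ndarray  # (I, J, 3)
    centers: np.ndarray  # (I, 3)
    arc_lengths: np.ndarray  # (I,)
    degree_u: int = 3
    degree_v: int = 3

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        self.arc_lengths = np.asarray(self.arc_lengths, dtype=float)
        I, J = self.control_points.shape[:2]
        if I < self.degree_u + 1:
            raise ValueError(
                f"need at least {self.degree_u + 1} sections for degree "
                f"{self.degree_u} in u, got {I}"
            )
        if J < self.degree_v + 1:
            raise ValueError(f"need at least {self.degree_v + 1} points per section")

    @property
    def num_sections(self) -> int:
        return self.control_points.shape[0]

    @property
    def points_per_section(self) -> int:
        return self.control_points.shape[1]

    def knots_u(self) -> np.ndarray:
        I, k = self.num_sections, self.degree_u
        interior = np.linspace(0.0, 1.0, I - k + 1)
        return np.concatenate([np.zeros(k), interior, np.ones(k)])

    def _wrapped_v(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Closed v direction: wrap the first ``degree_v`` control columns and
        use a uniform knot vector; the valid parameter range maps the seam
        smoothly (C^{degree-1} periodic continuity)."""
        k = self.degree_v
        cp = np.concatenate([self.control_points, self.control_points[:, :k]], axis=1)
        n = cp.shape[1]
        t = np.arange(-k, n + 1, dtype=float)  # uniform
        lo, hi = 0.0, float(n - k)  # one full turn of the closed curve
        return cp, t, np.array([lo, hi])

    def evaluate(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Evaluate the surface on the tensor grid u x v -> (len(u), len(v), 3).

        u and v are in [0, 1]; v = 0 and v = 1 give the same point (closed
        section).
        """
        u = np.atleast_1d(np.asarray(u, dtype=float))
        v = np.atleast_1d(np.asarray(v, dtype=float))
        if np.any((u < 0) | (u > 1)) or np.any((v < 0) | (v > 1)):
            raise ValueError("surface parameters must lie in [0, 1]")
        tu = self.knots_u()
        ku = self.degree_u
        uu = np.clip(u, 0.0, 1.0 - 1e-12)  # clamped end handled by basis
        Bu = BSpline.design_matrix(uu, tu, ku, extrapolate=False).toarray()
        cp, tv, (lo, hi) = self._wrapped_v()
        vv = lo + np.clip(v, 0.0, 1.0) * (hi - lo)
        vv = np.clip(vv, lo, hi - 1e-12)
        Bv = BSpline.design_matrix(vv, tv, self.degree_v, extrapolate=False).toarray()
        # tensor contraction: (nu, I) x (I, J, 3) x (nv, J)
        return np.einsum("ui,ijc,vj->uvc", Bu, cp, Bv)


def fit_nurbs(sections: list[SectionalCurve], degree_u: int = 3, degree_v: int = 3) -> NurbsSurface:
    """Assemble the tube surface whose control net is the boundary points."""
    if len(sections) < degree_u + 1:
        raise ValueError(
            f"need at least {degree_u + 1} sections for a degree-{degree_u} tube, "
            f"got {len(sections)}"
        )
    J = sections[0].boundary_points.shape[0]
    if any(s.boundary_points.shape[0] != J for s in sections):
        raise ValueError("all sections must have the same number of boundary points")
    return NurbsSurface(
        control_points=np.stack([s.boundary_points for s in sections]),
        centers=np.stack([s.center for s in sections]),
        arc_lengths=np.array([s.arc_length for s in sections]),
        degree_u=degree_u,
        degree_v=degree_v,
    )


def interpolate_shell(surface: NurbsSurface, p: float) -> NurbsSurface:
    """Shell at radial factor p: control points pulled linearly toward the
    section centers; p=0 is the surface itself, p=1 the centerline."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"radial factor p must be in [0, 1], got {p}")
    cp = (1.0 - p) * surface.control_points + p * surface.centers[:, None, :]
    return NurbsSurface(
        control_points=cp,
        centers=surface.centers,
        arc_lengths=surface.arc_lengths,
        degree_u=surface.degree_u,
        degree_v=surface.degree_v,
    )


@dataclasses.dataclass
class ShellStack:
    """Organ surface plus inner shells at increasing radial factors."""

    shells: list[NurbsSurface]
    radial_factors: np.ndarray

    def __post_init__(self) -> None:
        self.radial_factors = np.asarray(self.radial_factors, dtype=float)
        if len(self.shells) != len(self.radial_factors):
            raise ValueError("one radial factor per shell required")


def make_shell_stack(
    surface: NurbsSurface, radial_factors=(0.0, 0.25, 0.5, 0.75, 1.0)
) -> ShellStack:
    return ShellStack(
        shells=[interpolate_shell(surface, p) for p in radial_factors],
        radial_factors=np.asarray(radial_factors, dtype=float),
    )


def surface_to_json(surface: NurbsSurface, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "control_points_mm": surface.control_points.tolist(),
                "centers_mm": surface.centers.tolist(),
                "arc_lengths_mm": surface.arc_lengths.tolist(),
                "degree_u": surface.degree_u,
                "degree_v": surface.degree_v,
            },
            fh,
        )


def surface_from_json(path) -> NurbsSurface:
    with open(path) as fh:
        d = json.load(fh)
    return NurbsSurface(
        control_points=np.array(d["control_points_mm"]),
        centers=np.array(d["centers_mm"]),
        arc_lengths=np.array(d["arc_lengths_mm"]),
        degree_u=int(d["degree_u"]),
        degree_v=int(d["degree_v"]),
    )
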