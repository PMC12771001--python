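"""Analytical peristaltic motion applied to tube-surface control points.

The contraction wave travels along the organ's centerline: a control point at
arc-length station ``L_i`` and time ``t`` is displaced radially (toward or
away from its section center) by

    F_PS(L_i, t) = (1/sqrt(3)) * A * sin(2*pi*(L_i - c*t)/lambda)

optionally attenuated by an exponential dispersion ``D(u) = exp(-alpha*u)``
in the spatial (u = L_i) or temporal (u = t) domain. With ``alpha = 0`` the
wave is non-dispersive — the configuration used for high-magnitude GI motion.

Displacement is applied along the unit radial direction from the section
center to the control point, so the amplitude parameter ``A`` is in mm.
A contraction is clamped so no point crosses its section center: the deformed
radius never drops below a small positive floor.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .surface import NurbsSurface

__all__ = [
    "MotionParams",
    "STOMACH_PARAMS",
    "LARGE_BOWEL_PARAMS",
    "peristaltic_wave",
    "dispersion",
    "deform_controls",
    "synthesize_sequence",
    "DeformedSurfaceSequence",
]

#: minimal post-deformation section radius (mm); prevents self-intersection
RADIUS_FLOOR_MM = 0.25


@dataclasses.dataclass
class MotionParams:
    """Traveling-wave parameters for one organ.

    amplitude_mm (A), wavelength_mm (lambda) and speed_mm_s (c) set the wave;
    alpha sets the exponential attenuation (1/mm in the spatial domain, 1/s in
    the temporal domain; 0 disables dispersion). ``n_phases`` motion phases are
    synthesized at ``phase_times`` seconds; by default the phases span exactly
    one wave period ``lambda/c`` so the first and last phase coincide.
    """

    amplitude_mm: float = 16.0
    wavelength_mm: float = 55.0
    speed_mm_s: float = 5.0
    alpha: float = 0.0
    dispersion_domain: str = "none"  # "spatial" | "temporal" | "none"
    n_phases: int = 21
    phase_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.amplitude_mm < 0:
            raise ValueError("amplitude A must be >= 0")
        if self.wavelength_mm <= 0:
            raise ValueError("wavelength lambda must be > 0")
        if self.speed_mm_s <= 0:
            raise ValueError("wave speed c must be > 0")
        if self.alpha < 0:
            raise ValueError("attenuation alpha must be >= 0")
        if self.n_phases < 1:
            raise ValueError("n_phases must be >= 1")
        if self.dispersion_domain not in ("spatial", "temporal", "none"):
            raise ValueError(
                f"dispersion_domain must be spatial|temporal|none, got "
                f"{self.dispersion_domain!r}"
            )
        if self.phase_times is None:
            period = self.wavelength_mm / self.speed_mm_s
            if self.n_phases == 1:
                self.phase_times = np.array([0.0])
            else:
                self.phase_times = np.linspace(0.0, period, self.n_phases)
        else:
            self.phase_times = np.asarray(self.phase_times, dtype=float)
            if len(self.phase_times) != self.n_phases:
                raise ValueError("phase_times length must equal n_phases")
            if self.phase_times[0] != 0.0 or np.any(np.diff(self.phase_times) <= 0):
                raise ValueError("phase_times must be strictly increasing from 0")

    @property
    def period_s(self) -> float:
        return self.wavelength_mm / self.speed_mm_s


STOMACH_PARAMS = MotionParams(amplitude_mm=16.0, wavelength_mm=55.0, speed_mm_s=5.0)
LARGE_BOWEL_PARAMS = MotionParams(amplitude_mm=16.0, wavelength_mm=40.0, speed_mm_s=8.0)


def peristaltic_wave(arc_length_mm, t: float, params: MotionParams):
    """Signed radial wave displacement (mm) at arc length L_i and time t."""
    L = np.asarray(arc_length_mm, dtype=float)
    return (
        params.amplitude_mm
        / np.sqrt(3.0)
        * np.sin(2.0 * np.pi * (L - params.speed_mm_s * t) / params.wavelength_mm)
    )


def dispersion(u, alpha: float):
    """Exponential wave attenuation exp(-alpha*u); u is arc length or time."""
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("dispersion argument must be >= 0")
    return np.exp(-alpha * u)


def _dispersion_factors(params: MotionParams, arc_lengths: np.ndarray, t: float):
    """(D_s, D_t) per section; the inactive domain contributes exactly 1."""
    if params.alpha == 0 or params.dispersion_domain == "none":
        ones = np.ones_like(arc_lengths)
        return ones, 1.0
    if params.dispersion_domain == "spatial":
        return dispersion(arc_lengths, params.alpha), 1.0
    return np.ones_like(arc_lengths), float(dispersion(t, params.alpha))


def deform_controls(
    net: NurbsSurface, params: MotionParams, t: float
) -> tuple[NurbsSurface, int]:
    """Displace every control point radially by F_PS * D_s * D_t.

    Returns the deformed surface and the number of clamped points (points
    whose contraction would have pushed them past the section center).
    """
    cp = net.control_points
    centers = net.centers[:, None, :]  # (I, 1, 3)
    radial = cp - centers
    r = np.linalg.norm(radial, axis=-1)  # (I, J)
    if np.any(r <= 0):
        raise ValueError("control point coincides with its section center")
    d = radial / r[..., None]
    ds, dt = _dispersion_factors(params, net.arc_lengths, t)
    f = peristaltic_wave(net.arc_lengths, t, params) * ds * dt  # (I,)
    new_r = r + f[:, None]
    clamped = int(np.count_nonzero(new_r < RADIUS_FLOOR_MM))
    new_r = np.maximum(new_r, RADIUS_FLOOR_MM)
    deformed = NurbsSurface(
        control_points=centers + new_r[..., None] * d,
        centers=net.centers,
        arc_lengths=net.arc_lengths,
        degree_u=net.degree_u,
        degree_v=net.degree_v,
    )
    return deformed, clamped


@dataclasses.dataclass
class DeformedSurfaceSequence:
    """One deformed control net per motion phase (shared knots/degrees)."""

    phases: list[NurbsSurface]
    phase_times: np.ndarray
    clamped_counts: list[int]

    def __len__(self) -> int:
        return len(self.phases)


def synthesize_sequence(net: NurbsSurface, params: MotionParams) -> DeformedSurfaceSequence:
    """Deform the control net at every phase time; deterministic."""
    phases, clamps = [], []
    for t in params.phase_times:
        deformed, n_clamped = deform_controls(net, params, float(t))
        phases.append(deformed)
        clamps.append(n_clamped)
    return DeformedSurfaceSequence(
        phases=phases, phase_times=params.phase_times.copy(), clamped_counts=clamps
    )
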