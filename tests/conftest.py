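"""Shared fixtures: small analytic tube phantoms and pipeline products.

Everything is generated programmatically; session scope keeps the heavier
phantom/pipeline constructions shared across test modules.
"""

import numpy as np
import pytest

from gitwin import centerline as cl
from gitwin import dvf as dvfmod
from gitwin import phantoms
from gitwin import surface as surf
from gitwin.motion import MotionParams, synthesize_sequence
from gitwin.volio import LabelMask, VolumeGrid


def straight_tube_spec(
    radius: float = 5.0,
    length: tuple[float, float] = (10.0, 50.0),
    shape=(60, 32, 32),
    spacing=(1.0, 1.0, 1.0),
    noise_sd: float = 0.0,
    seed: int = 1,
) -> phantoms.PhantomSpec:
    """Axis-aligned cylinder along x at the grid's transverse center."""
    n = 400
    # tube axis on a voxel center (perfect inter-voxel symmetry is a known
    # degenerate input for 3D thinning)
    yc = (shape[1] // 2) * spacing[1]
    zc = (shape[2] // 2) * spacing[2]
    pts = np.stack(
        [np.linspace(length[0], length[1], n), np.full(n, yc), np.full(n, zc)], axis=-1
    )
    return phantoms.PhantomSpec(
        shape=shape,
        spacing=spacing,
        path=phantoms.TubePath(points=pts, radius=np.full(n, radius)),
        noise_sd=noise_sd,
        seed=seed,
    )


@pytest.fixture(scope="session")
def cylinder_spec():
    return straight_tube_spec()


@pytest.fixture(scope="session")
def cylinder_mask(cylinder_spec):
    return phantoms.make_tube_mask(cylinder_spec)


@pytest.fixture(scope="session")
def cylinder_line(cylinder_spec, cylinder_mask):
    return cl.extract_centerline(
        cylinder_mask, cylinder_spec.path.points[0], cylinder_spec.path.points[-1],
        step=2.0,
    )


@pytest.fixture(scope="session")
def cylinder_sections(cylinder_mask, cylinder_line):
    return surf.cast_sections(cylinder_mask, cylinder_line, rays_per_section=36)


@pytest.fixture(scope="session")
def cylinder_surface(cylinder_sections):
    return surf.fit_nurbs(cylinder_sections)


@pytest.fixture(scope="session")
def small_twin():
    """Forward pipeline on the desk-scale stomach arc: one heavy build shared
    by the DVF, evaluation and acceptance tests."""
    spec = phantoms.preset("stomach-small", seed=3)
    mask = phantoms.make_tube_mask(spec)
    line = cl.extract_centerline(mask, spec.path.points[0], spec.path.points[-1], step=2.0)
    sections = surf.cast_sections(mask, line, rays_per_section=36)
    surface = surf.fit_nurbs(sections)
    params = MotionParams()
    sequence = synthesize_sequence(surface, params)
    r_max = float(max(s.radii.max() for s in sections))
    factors = np.linspace(0.0, 1.0, max(5, int(np.ceil(r_max / 2.0)) + 1))
    stack = surf.make_shell_stack(surface, factors)
    support = dvfmod.make_support(mask, params.amplitude_mm / np.sqrt(3.0) + 4.0)
    n_u = int(np.ceil(line.total_length / 2.0)) + 1
    n_v = max(36, int(np.ceil(2 * np.pi * r_max / 2.0)))
    return {
        "spec": spec,
        "mask": mask,
        "line": line,
        "surface": surface,
        "params": params,
        "sequence": sequence,
        "factors": factors,
        "stack": stack,
        "support": support,
        "grid_uv": (n_u, n_v),
    }


@pytest.fixture(scope="session")
def small_twin_field(small_twin):
    """Ground-truth DVF of the phase with maximal mean organ displacement."""
    tw = small_twin
    best, best_mean = None, -1.0
    # pick the max-deformation phase from the control nets (cheap proxy)
    for k in range(len(tw["sequence"].phases)):
        d = np.abs(
            tw["sequence"].phases[k].control_points - tw["surface"].control_points
        ).mean()
        if d > best_mean:
            best, best_mean = k, d
    def_stack = surf.make_shell_stack(tw["sequence"].phases[best], tw["factors"])
    field, info = dvfmod.ground_truth_dvf(
        tw["stack"], def_stack, tw["mask"], tw["support"], tw["grid_uv"],
        phase_index=best,
    )
    return {"phase": best, "field": field, "info": info}


def make_grid(shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0), value=0.0) -> VolumeGrid:
    return VolumeGrid(
        data=np.full(shape, value, dtype=float), spacing=spacing, origin=(0, 0, 0)
    )


def make_mask(data, spacing=(1.0, 1.0, 1.0), origin=(0, 0, 0)) -> LabelMask:
    return LabelMask(data=np.asarray(data, dtype=np.uint8), spacing=spacing, origin=origin)
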