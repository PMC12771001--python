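"""Shell sampling, voxelization, hole filling, warping, Jacobians.

The voxelize / smooth_fill operations are checked against independent
brute-force oracles (naive per-voxel loops, dense linear solve of the
discrete Laplace problem) on small grids.
"""

import numpy as np
import pytest
from scipy.sparse import lil_matrix
from scipy.sparse.linalg import spsolve

from gitwin import dvf as dvfmod
from gitwin import surface as surf
from gitwin.volio import DisplacementField, LabelMask, VolumeGrid
from conftest import make_grid, make_mask


# ----------------------------------------------------------------- oracles


def voxelize_oracle(samples, grid):
    """Naive double loop: per-voxel arithmetic mean of sample vectors."""
    out = np.zeros((*grid.shape, 3))
    counts = np.zeros(grid.shape)
    for x, v in zip(samples.original, samples.vectors):
        i = tuple(np.rint((x - grid.origin) / grid.spacing).astype(int))
        out[i] += v
        counts[i] += 1
    nz = counts > 0
    out[nz] /= counts[nz][..., None]
    return out


def harmonic_fill_oracle(field_data, domain, seeds):
    """Dense solve of the discrete Laplace problem with Dirichlet seeds and
    zero-flux walls: x_v = mean of in-domain neighbors."""
    shape = field_data.shape[:3]
    fill = [tuple(i) for i in np.argwhere(domain & ~seeds)]
    index = {v: n for n, v in enumerate(fill)}
    A = lil_matrix((len(fill), len(fill)))
    rhs = np.zeros((len(fill), 3))
    offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for v, n in index.items():
        nbrs = [
            tuple(np.array(v) + o)
            for o in offs
            if all(0 <= v[a] + o[a] < shape[a] for a in range(3))
            and domain[tuple(np.array(v) + o)]
        ]
        A[n, n] = len(nbrs)
        for w in nbrs:
            if seeds[w]:
                rhs[n] += field_data[w]
            else:
                A[n, index[w]] -= 1
    sol = np.stack([spsolve(A.tocsr(), rhs[:, c]) for c in range(3)], axis=-1)
    out = field_data.copy()
    for v, n in index.items():
        out[v] = sol[n]
    return out


# ------------------------------------------------------------- shell sampling


def test_sample_identical_stacks_zero_vectors(cylinder_surface):
    stack = surf.make_shell_stack(cylinder_surface)
    s = dvfmod.sample_shells(stack, stack, (12, 16))
    np.testing.assert_allclose(s.vectors, 0.0, atol=1e-12)


def test_sample_rigid_translation(cylinder_surface):
    stack = surf.make_shell_stack(cylinder_surface)
    moved = surf.NurbsSurface(
        control_points=cylinder_surface.control_points + (1.0, 0.0, 0.0),
        centers=cylinder_surface.centers + (1.0, 0.0, 0.0),
        arc_lengths=cylinder_surface.arc_lengths,
    )
    s = dvfmod.sample_shells(stack, surf.make_shell_stack(moved), (12, 16))
    np.testing.assert_allclose(s.vectors, [(1.0, 0.0, 0.0)] * len(s.vectors), atol=1e-9)


def test_sample_radial_contraction_scales_with_shell_depth(cylinder_surface):
    """Outer surface contracted by 2 mm, centerline fixed: |V| at radial
    factor p equals 2(1-p); oracle = the linear shell interpolation in closed
    form."""
    factors = (0.0, 0.25, 0.5, 0.75, 1.0)
    stack = surf.make_shell_stack(cylinder_surface, factors)
    c = cylinder_surface.centers[:, None, :]
    radial = cylinder_surface.control_points - c
    r = np.linalg.norm(radial, axis=-1, keepdims=True)
    contracted = surf.NurbsSurface(
        control_points=c + radial * (1 - 2.0 / r),
        centers=cylinder_surface.centers,
        arc_lengths=cylinder_surface.arc_lengths,
    )
    def_stack = surf.make_shell_stack(contracted, factors)
    for p, sh_o, sh_d in zip(factors, stack.shells, def_stack.shells):
        s = dvfmod.sample_shells(
            surf.ShellStack(shells=[sh_o], radial_factors=[0.0]),
            surf.ShellStack(shells=[sh_d], radial_factors=[0.0]),
            (10, 12),
        )
        # evaluated samples blend neighboring radial directions (36 points
        # around the ring), shaving ~0.5% off the control-point magnitude
        np.testing.assert_allclose(
            np.linalg.norm(s.vectors, axis=1), 2.0 * (1 - p), atol=0.02
        )
    # and the relation is exact on the control nets themselves
    for p, sh_o, sh_d in zip(factors, stack.shells, def_stack.shells):
        d = np.linalg.norm(sh_d.control_points - sh_o.control_points, axis=-1)
        np.testing.assert_allclose(d, 2.0 * (1 - p), atol=1e-9)


# ---------------------------------------------------------------- voxelize


def test_voxelize_averages_cohabiting_vectors():
    grid = make_grid((4, 4, 4))
    samples = dvfmod.ShellSampleSet(
        original=np.array([[1.1, 1.0, 1.0], [0.9, 1.0, 1.0]]),
        deformed=np.array([[2.1, 1.0, 1.0], [3.9, 1.0, 1.0]]),
    )
    field = dvfmod.voxelize(samples, grid)
    np.testing.assert_allclose(field.data[1, 1, 1], (2.0, 0.0, 0.0))
    assert np.all(field.data[0] == 0)  # untouched voxels stay zero


def test_voxelize_matches_bruteforce_on_random_samples():
    rng = np.random.default_rng(11)
    grid = make_grid((6, 7, 5), spacing=(1.0, 2.0, 1.5))
    orig = rng.uniform([0, 0, 0], [5, 12, 6], size=(200, 3))
    samples = dvfmod.ShellSampleSet(
        original=orig, deformed=orig + rng.normal(size=(200, 3))
    )
    field = dvfmod.voxelize(samples, grid)
    np.testing.assert_allclose(field.data, voxelize_oracle(samples, grid), rtol=1e-9, atol=1e-12)


def test_voxelize_rejects_out_of_grid():
    grid = make_grid((4, 4, 4))
    samples = dvfmod.ShellSampleSet(
        original=np.array([[10.0, 0.0, 0.0]]), deformed=np.array([[11.0, 0.0, 0.0]])
    )
    with pytest.raises(ValueError, match="outside the grid"):
        dvfmod.voxelize(samples, grid)


# --------------------------------------------------------------- smooth_fill


def _field(shape, spacing=(1.0, 1.0, 1.0)):
    return DisplacementField(
        data=np.zeros((*shape, 3)), spacing=spacing, origin=(0, 0, 0)
    )


def test_smooth_fill_zero_field_unchanged():
    f = _field((4, 4, 4))
    support = make_mask(np.ones((4, 4, 4)))
    out, iters = dvfmod.smooth_fill(f, support)
    np.testing.assert_array_equal(out.data, 0.0)
    assert iters <= 1


def test_smooth_fill_row_average_of_equal_neighbors():
    f = _field((3, 1, 1))
    f.data[0, 0, 0] = (2.0, 0.0, 0.0)
    f.data[2, 0, 0] = (2.0, 0.0, 0.0)
    support = make_mask(np.ones((3, 1, 1)))
    out, _ = dvfmod.smooth_fill(f, support)
    np.testing.assert_allclose(out.data[1, 0, 0], (2.0, 0.0, 0.0), atol=1e-9)


def test_smooth_fill_matches_harmonic_solve():
    """Seed plates on two opposite faces; the filled interior matches the
    dense solve of the discrete Dirichlet problem to 1e-9 relative."""
    shape = (8, 6, 4)
    f = _field(shape)
    f.data[0, :, :] = (2.0, 1.0, 0.0)
    f.data[-1, :, :] = (6.0, -1.0, 0.0)
    support = make_mask(np.ones(shape))
    seeds = np.any(f.data != 0, axis=-1)
    expected = harmonic_fill_oracle(f.data, np.ones(shape, bool), seeds)
    out, iters = dvfmod.smooth_fill(f, support, tol=1e-12, max_iter=100000)
    np.testing.assert_allclose(out.data, expected, rtol=1e-9, atol=1e-9)
    # seeds never altered
    np.testing.assert_array_equal(out.data[0], f.data[0])
    np.testing.assert_array_equal(out.data[-1], f.data[-1])


def test_smooth_fill_maximum_principle(small_twin_field):
    """Filled magnitudes never exceed the maximal seed magnitude."""
    field = small_twin_field["field"]
    # the field was produced by voxelize + smooth_fill; rebuild the seeds set
    assert np.isfinite(field.data).all()
    assert field.magnitude().max() <= 16.0 / np.sqrt(3.0) + 1e-6


def test_smooth_fill_nonconvergence_raises():
    f = _field((12, 12, 1))
    f.data[0, 0, 0] = (5.0, 0.0, 0.0)
    support = make_mask(np.ones((12, 12, 1)))
    with pytest.raises(RuntimeError, match="did not converge"):
        dvfmod.smooth_fill(f, support, tol=1e-15, max_iter=3)


# --------------------------------------------------------------------- warp


def test_warp_zero_field_is_identity():
    rng = np.random.default_rng(2)
    vol = VolumeGrid(data=rng.normal(size=(8, 8, 8)), spacing=(1, 1, 1), origin=(0, 0, 0))
    out = dvfmod.warp(vol, _field((8, 8, 8)), kind="image")
    np.testing.assert_allclose(out.data, vol.data, atol=1e-12)


def test_warp_uniform_shift_moves_impulse():
    vol = make_grid((20, 9, 9))
    vol.data[5, 4, 4] = 1.0
    f = _field((20, 9, 9))
    f.data[..., 0] = 5.0
    out = dvfmod.warp(vol, f, kind="image")
    assert out.data[10, 4, 4] == pytest.approx(1.0, abs=0.01)
    assert out.data[5, 4, 4] == pytest.approx(0.0, abs=0.01)


def test_warp_then_inverse_recovers_original():
    """Uniform translation forward then its analytic negation: back to the
    start within interpolation tolerance (away from borders)."""
    rng = np.random.default_rng(3)
    vol = VolumeGrid(
        data=rng.normal(size=(16, 16, 16)), spacing=(1, 1, 1), origin=(0, 0, 0)
    )
    f = _field((16, 16, 16))
    f.data[..., 1] = 3.0
    fwd = dvfmod.warp(vol, f, kind="image")
    b = _field((16, 16, 16))
    b.data[..., 1] = -3.0
    back = dvfmod.warp(fwd, b, kind="image")
    np.testing.assert_allclose(
        back.data[3:-3, 4:-4, 3:-3], vol.data[3:-3, 4:-4, 3:-3], atol=0.02
    )


def test_warp_mask_produces_binary(cylinder_mask):
    out = dvfmod.warp(
        cylinder_mask,
        _field(cylinder_mask.shape, spacing=tuple(cylinder_mask.spacing)),
        kind="mask",
    )
    assert isinstance(out, LabelMask)
    np.testing.assert_array_equal(out.data, cylinder_mask.data)


def test_invert_uniform_field_is_negation():
    f = _field((10, 10, 10))
    f.data[...] = (2.0, -1.0, 0.5)
    inv, res = dvfmod.invert_field(f)
    assert res < dvfmod.INVERT_TOL_MM
    interior = inv.data[4:6, 4:6, 4:6]
    np.testing.assert_allclose(
        interior, np.broadcast_to((-2.0, 1.0, -0.5), interior.shape), atol=5e-3
    )


# ------------------------------------------------------------- log jacobian


def test_log_jacobian_zero_and_uniform_translation():
    f = _field((8, 8, 8))
    lj, folded = dvfmod.log_jacobian(f)
    np.testing.assert_array_equal(lj.data, 0.0)
    assert folded == 0
    f.data[...] = (4.0, -2.0, 1.0)
    lj, folded = dvfmod.log_jacobian(f)
    np.testing.assert_allclose(lj.data, 0.0, atol=1e-12)
    assert folded == 0


def test_log_jacobian_linear_field_closed_form():
    """u_x = 0.1 x: log det = log(1.1) everywhere (exact for central and
    one-sided differences on a linear field)."""
    f = _field((10, 6, 6), spacing=(2.0, 1.0, 1.0))
    x = np.arange(10) * 2.0
    f.data[..., 0] = x[:, None, None] * 0.1
    lj, folded = dvfmod.log_jacobian(f)
    np.testing.assert_allclose(lj.data, np.log(1.1), rtol=1e-12)
    assert folded == 0


def test_log_jacobian_reports_folding():
    f = _field((8, 4, 4))
    # strong compression: u_x = -1.5 x  ->  det = -0.5 < 0
    f.data[..., 0] = np.arange(8)[:, None, None] * -1.5
    lj, folded = dvfmod.log_jacobian(f)
    assert folded > 0
    assert np.isnan(lj.data).any()


# ---------------------------------------------------- end-to-end invariants


def test_identity_deformation_voxelizes_to_zero_field(small_twin):
    tw = small_twin
    s = dvfmod.sample_shells(tw["stack"], tw["stack"], tw["grid_uv"])
    field = dvfmod.voxelize(s, tw["mask"])
    np.testing.assert_allclose(field.data, 0.0, atol=1e-9)


def test_ground_truth_field_bounded_and_supported(small_twin, small_twin_field):
    field = small_twin_field["field"]
    mag = field.magnitude()
    assert mag.max() <= 16.0 / np.sqrt(3.0) + 1e-6
    outside = small_twin["support"].data == 0
    assert np.all(mag[outside] == 0.0)
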