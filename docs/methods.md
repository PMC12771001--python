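# Methods

## Coordinate conventions

All volumes live on axis-aligned regular grids: array axes are (x, y, z),
voxel indices are 0-based, the world coordinate (mm) of voxel `i` is
`origin + i·spacing`, and world coordinates are voxel centers. Displacement
fields store millimeters along world axes, never voxel units, so anisotropic
spacing (e.g. 1×1×2 mm or 0.78×0.78×5 mm clinical grids) needs no special
casing. NIfTI files whose rotation matrix is not the identity are rejected:
oblique acquisitions must be resampled upstream. DVFs are written as 4D
NIfTI with three components and vector intent; this storage format is our
choice.

## Centerline extraction

The organ mask is thinned with Lee-style 3D topology-preserving
skeletonization (scikit-image). Skeleton voxels become graph nodes with
26-connectivity edges. Because a skeleton may contain cycles (masks with
through-holes), the component is first pruned to a spanning tree: edges are
ranked by the mean interior depth (distance transform) of their endpoints
and a maximum-depth spanning tree is kept, so each cycle drops its
shallowest edge — the one most likely to be a spurious shortcut near the
organ wall. Ties break lexicographically on voxel indices, making the
extraction bit-reproducible. In the tree, the path between the two
user-chosen endpoints (given in world mm and snapped to the nearest
skeleton voxel) is unique and found by breadth-first search; all side
branches are discarded. The retained path is resampled at equidistant arc
lengths (default step: twice the maximal in-plane spacing; endpoints kept;
the last segment may be shorter).

A practical caveat: 3D thinning can return an empty skeleton for masks with
*exact* inter-voxel mirror symmetry (an upstream edge case of the thinning
algorithm). The package raises a clear error in that case; any realistic
organ mask is asymmetric.

## Tube surface and shells

At each centerline station, 36 rays (configurable, ≥ 8) are cast in the
plane orthogonal to the local tangent. Section frames are
rotation-minimizing — the first normal is parallel-transported along the
line — rather than Frenet frames, which flip at inflection points and would
twist the control net. Each ray records its *first* crossing of the mask
boundary, located sub-voxel by linear interpolation of the mask's signed
Euclidean distance along the ray (march step: a quarter of the finest
spacing); folds beyond the first crossing of a non-convex section are
ignored. A station on or outside the boundary is a hard error.

The boundary points are used directly as the control net of a
tensor-product B-spline tube: cubic and clamped along the organ (u), cubic
and closed by wrapping the first three control columns around the section
(v). All weights are 1 (the B-spline special case of a NURBS); degrees and
weights are our choice. Inner shells at radial factor `p ∈ [0, 1]` move
every control point linearly toward its section center, so `p=0` is the
organ surface and `p=1` collapses onto the centerline; shell radii are
strictly decreasing in `p` for positive-radius tubes.

## Motion model

The traveling peristaltic wave `F(L_i, t) = (A/√3)·sin(2π(L_i − c·t)/λ)`
displaces each control point along its unit radial direction; the `1/√3`
factor is applied verbatim as printed in the source model. Optional
exponential dispersion `exp(−α·u)` attenuates the wave in arc length
(`u = L_i`, α in 1/mm) or time (`u = t`, α in 1/s); α = 0 (the default)
models high-magnitude non-dispersive motion and makes both factors exactly
1. The radial direction is normalized, so `A` is in millimeters and the
per-point displacement is bounded by `A/√3 ≈ 0.577·A`.

Phase times default to `t_k = k·(λ/c)/(n_phases−1)` with `n_phases = 21`:
the phases span exactly one wave period, so the first and last nets
coincide — a testable property. A contraction that would push a control
point past its section center is clamped so the deformed radius never drops
below 0.25 mm (preventing surface self-intersection; clamp counts are
logged). With stomach defaults the wave amplitude (9.24 mm) exceeds the
thin end of a tapering organ, so clamping is expected, not exceptional.

## Displacement fields

Original and deformed shell stacks are evaluated on one uniform (u, v) grid
per shell; per-sample vectors `V = X′ − X` are binned into the voxel
containing the *original* position, with collisions averaged arithmetically.
Default densities put roughly one sample per voxel: u and v steps equal to
the finest spacing, and enough shells that consecutive shell radii differ by
at most one voxel; the fraction of organ voxels that received a sample is
logged per phase.

Unsampled voxels inside the support region are then filled by synchronous
(Jacobi-style) sweeps in which each empty voxel takes the mean of its
6-neighbors that currently hold a nonzero vector; seed voxels are never
modified, and iteration stops when the mean per-voxel update falls below
0.001 mm. In regions enclosed by seeds this converges to the discrete
harmonic interpolant of the seed values, and filled magnitudes obey the
discrete maximum principle (never exceeding the largest seed magnitude).
The support region is the union of animated organ masks dilated by the
maximal expected surface excursion (`A/√3` plus two voxels) — wide enough
that the swept region of the moving surface is always covered, while
keeping motion organ-local (whole-body mean displacements stay in the
0.01–0.1 mm range).

The stored field is a forward (push-forward) map. Warping resamples through
the approximate inverse, obtained by the damped fixed point
`v ← v + ω(−u(y+v) − v)` with `ω = 0.5`, up to 200 iterations or a mean
update below 0.002 mm, computed only inside a bounding box of the field's
support padded by the maximal displacement. The damping matters: with
stomach-scale amplitudes on thin organs the radial expansion gradient
approaches 1 and the undamped iteration oscillates instead of converging.
Images and dose maps are pulled back with trilinear interpolation; masks
are warped by pulling back their signed distance and thresholding at zero,
which places the warped boundary sub-voxel instead of snapping it to voxel
centers. The log-Jacobian map is `log det(I + ∇u)` with central differences
(one-sided at the grid faces); non-positive determinants are reported as
NaN and counted as folding.

## Evaluation

A candidate DVF (any external DIR tool's output, ingested in the forward
convention; backward fields are inverted on load) is compared against the
ground truth of the phase with the largest mean organ displacement:

* **TRE** — `‖u_gt(x) − u_cand(x)‖` at surface and inner-shell sample
  points, trilinear field sampling; symmetric in its arguments.
* **DSC / HD95** — overlap and 95th-percentile symmetric surface distance
  of the warped organ masks; HD95 uses boundary voxels, spacing-aware
  distances, and linear-interpolated percentiles; two empty masks have
  DSC 1 by convention.
* **DWE** — dose is accumulated by direct dose mapping (the mean over
  phases of the dose resampled through each phase's field). The printed
  error formula is a bare sum of per-voxel relative differences; we report
  its mean (percent per voxel, comparable across ROI sizes) and also emit
  the raw sum. Voxels whose reference accumulated dose falls below a 0.5 Gy
  floor are excluded and counted, avoiding division blow-ups.
* **Binned RMSE** — RMSE of `‖u_cand − u_gt‖` per bin of ground-truth
  motion magnitude (default 1 mm bins from 0) or of dose (default 10 Gy
  bins), plus a voxelwise error heat-map volume for visualization.

## Synthetic phantoms

Phantoms are solid tubes swept along analytic paths — a C-arc with radius
tapering 12→6 mm on a 96³ grid at 2 mm ("stomach"), a three-quarter torus
arc of radius 8 mm ("bowel"), and a desk-scale 64³ variant — with
three-level (lumen/wall/background) intensities, seeded Gaussian noise, and
Gaussian dose blobs. The analytic path is stored next to the mask and
serves as ground truth for centerline recovery; the analytically deformed
tube (local radius `max(r(L) + F(L,t), 0.25 mm)`) is the reference for the
forward-model self-consistency check. Tubes keep at least `A/√3` plus two
voxels of margin to the grid edge so the DVF support never clips. What the
phantoms deliberately do not emulate: realistic organ texture, non-circular
cross-sections, organ-organ contact, and respiratory baseline motion — so
passing tests demonstrate the geometric and numerical correctness of the
pipeline, not clinical realism of any particular scan.

## Known limitations

* The voxel DVF representation bounds how sharply the field can represent
  the organ boundary: averaging within boundary voxels, the outward decay
  of the neighbor-averaged fill (length scale λ/2π ≈ 8.75 mm for the
  stomach wave), and trilinear corner-cutting at the surface together bias
  the effective boundary displacement low by roughly 1 mm at 2 mm grids.
  Consequently the warped tube mask overlaps the analytically deformed tube
  at DSC ≈ 0.85 on the 2 mm stomach phantom — and even an exact analytic
  field only reaches ≈ 0.95 through the same warp stage at that resolution.
  Finer grids shrink this bias roughly linearly with spacing.
* Registration between phases is *evaluated*, never performed: no DIR
  algorithm is implemented or wrapped.
* Only peristalsis is modeled; other contraction patterns (high-amplitude
  propagating contractions, rhythmic segmentation, tonic sphincter tone)
  fit the same control-point framework but are not implemented.
* Branching organs and "bowel-bag" style masks whose skeleton is a net are
  out of scope; endpoints must be chosen by the user.
* The problem sizes used by the test suite and the acceptance script (64³
  and 96³ phantoms, full 21-phase synthesis on the latter) were chosen as
  representative desk-scale runs; larger clinical grids follow the same
  code paths.
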