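"""Synthetic fiber fields, a helical-ventricle phantom, and a DWI simulator.

Real cardiac diffusion scans are not redistributable, so every pipeline
stage is exercised against synthetic inputs:

* analytic fields (uniform, vortex, helix) with known streamline geometry,
  available both as voxel grids and as continuous closed-form fields;
* an idealized left-ventricle phantom — the wall between two half-ellipsoid
  shells truncated at the equator, carrying a fiber field whose helical
  angle grades linearly across the wall from an endocardial value (+60 deg
  by default) to an epicardial one (-60 deg), tangent to the shells by
  construction;
* a forward Stejskal-Tanner diffusion-signal simulator,
  ``S = S0 exp(-b g^T D g)``, for round-trip testing of the tensor fit.

All generators are deterministic given their spec (and seed, where noise is
requested).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import DWIStack, TensorField, VectorField, VoxelMask

#: Magnitude below which an analytic sample counts as off-support.
_EPS = 1e-12


class SynthError(ValueError):
    """Invalid synthetic-data specification."""


# ---------------------------------------------------------------------------
# Analytic fields
# ---------------------------------------------------------------------------

class AnalyticField:
    """A continuous vector field defined by a closed-form function.

    Provides the same sampling interface the tracer uses for voxel grids
    (sign-coherent, normalized, with a validity flag), so streamline
    integration can be checked against exact analytic trajectories with no
    interpolation error.
    """

    def __init__(self, fn, lo, hi):
        self.fn = fn
        self.lo = np.asarray(lo, dtype=float).reshape(3)
        self.hi = np.asarray(hi, dtype=float).reshape(3)

    def in_support(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return np.all((p >= self.lo) & (p <= self.hi), axis=1)

    def vectors_at(self, points: np.ndarray) -> np.ndarray:
        v = np.atleast_2d(self.fn(np.atleast_2d(np.asarray(points, dtype=float))))
        n = np.linalg.norm(v, axis=1)
        out = np.zeros_like(v)
        ok = n > _EPS
        out[ok] = v[ok] / n[ok, None]
        return out

    def sample_batch(self, points, refs):
        p = np.atleast_2d(np.asarray(points, dtype=float))
        r = np.atleast_2d(np.asarray(refs, dtype=float))
        v = self.vectors_at(p)
        dots = np.einsum("ij,ij->i", v, r)
        v = np.where(dots[:, None] < 0, -v, v)
        valid = self.in_support(p) & (np.linalg.norm(v, axis=1) > _EPS)
        v = np.where(valid[:, None], v, 0.0)
        return v, valid


def analytic_vortex(center=(0.0, 0.0, 0.0), half_extent=50.0) -> AnalyticField:
    """Continuous circular field ``v ~ (-y, x, 0)`` about a vertical axis."""
    c = np.asarray(center, dtype=float)

    def fn(p):
        rel = p - c
        return np.column_stack([-rel[:, 1], rel[:, 0], np.zeros(len(p))])

    h = np.full(3, float(half_extent))
    return AnalyticField(fn, c - h, c + h)


def analytic_uniform(direction=(1.0, 0.0, 0.0), half_extent=50.0) -> AnalyticField:
    d = np.asarray(direction, dtype=float)

    def fn(p):
        return np.broadcast_to(d, (len(p), 3)).copy()

    h = np.full(3, float(half_extent))
    return AnalyticField(fn, -h, h)


def make_analytic_field(kind: str, shape, spacing, params: dict | None = None):
    """Voxelized analytic test fields plus their interior mask.

    ``kind`` is one of ``uniform`` (constant vector), ``vortex``
    (normalized ``(-y, x, 0)`` about a vertical axis) or ``helix`` (vortex
    plus a constant-pitch vertical component).  The mask is the full grid
    minus a one-voxel border (edge voxels cannot be interpolated).
    """
    params = dict(params or {})
    shape = tuple(int(s) for s in shape)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if len(shape) != 3 or any(s < 3 for s in shape):
        raise SynthError("shape must be 3 axes of at least 3 voxels")
    if np.any(spacing <= 0):
        raise SynthError("spacing must be positive")
    origin = params.pop("origin", np.zeros(3))
    fld = VectorField(values=np.zeros(shape + (3,)), spacing=spacing, origin=origin)
    centers = fld.voxel_centers().reshape(-1, 3)

    if kind == "uniform":
        d = np.asarray(params.pop("direction", (1.0, 0.0, 0.0)), dtype=float)
        vecs = np.broadcast_to(d / np.linalg.norm(d), centers.shape).copy()
    elif kind in ("vortex", "helix"):
        center = np.asarray(
            params.pop("center", fld.voxel_to_world((np.asarray(shape) - 1) / 2.0)),
            dtype=float,
        )
        rel = centers - center
        tang = np.column_stack([-rel[:, 1], rel[:, 0], np.zeros(len(rel))])
        rn = np.linalg.norm(tang, axis=1)
        ok = rn > _EPS
        tang[ok] /= rn[ok, None]
        tang[~ok] = 0.0
        if kind == "helix":
            alpha = np.radians(float(params.pop("pitch_angle_deg", 45.0)))
            vecs = np.cos(alpha) * tang
            vecs[ok, 2] = np.sin(alpha)
        else:
            vecs = tang
    else:
        raise SynthError(f"unknown analytic field kind {kind!r} "
                         "(expected uniform, vortex or helix)")
    if params:
        raise SynthError(f"unknown parameters for kind {kind!r}: {sorted(params)}")

    fld.values = vecs.reshape(shape + (3,))
    flags = np.zeros(shape, dtype=bool)
    flags[1:-1, 1:-1, 1:-1] = True
    mask = VoxelMask(flags=flags, spacing=spacing, origin=origin)
    return fld, mask


# ---------------------------------------------------------------------------
# Helical-ventricle phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """An idealized left ventricle: the wall between two half-ellipsoids.

    The long axis is the grid z axis; the equator is the plane z = 0 and
    the apex points toward negative z.  The helical angle varies linearly
    with wall depth ``t`` (0 at the inner/endocardial shell, 1 at the
    outer/epicardial shell) from ``ha_endo_deg`` to ``ha_epi_deg`` — the
    healthy transmural +60 to -60 degree progression by default.
    """

    outer_radii: tuple[float, float, float] = (14.0, 14.0, 15.0)
    inner_radii: tuple[float, float, float] = (10.0, 10.0, 11.0)
    spacing: float | tuple[float, float, float] = 0.5
    ha_endo_deg: float = 60.0
    ha_epi_deg: float = -60.0

    def __post_init__(self) -> None:
        self.outer_radii = tuple(float(r) for r in self.outer_radii)
        self.inner_radii = tuple(float(r) for r in self.inner_radii)
        sp = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,))
        self.spacing = tuple(float(s) for s in sp)
        if any(r <= 0 for r in self.outer_radii + self.inner_radii):
            raise SynthError("shell radii must be positive")
        if not all(ri < ro for ri, ro in zip(self.inner_radii, self.outer_radii)):
            raise SynthError("inner radii must be strictly inside outer radii")
        if any(s <= 0 for s in self.spacing):
            raise SynthError("spacing must be positive")


def _ellipsoid_level(points: np.ndarray, radii) -> np.ndarray:
    r = np.asarray(radii, dtype=float)
    return np.sum((np.atleast_2d(points) / r) ** 2, axis=1)


def phantom_wall_depth(spec: PhantomSpec, points: np.ndarray) -> np.ndarray:
    """Wall depth t in [0, 1] of world points, by shell interpolation.

    A point's depth is the ``t`` for which it lies on the ellipsoid with
    per-axis radii ``inner + t (outer - inner)``; solved by bisection (the
    level value is strictly decreasing in t).  Values are clipped to [0, 1]
    for points slightly outside the wall (voxel-center discretization).
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    ri = np.asarray(spec.inner_radii)
    ro = np.asarray(spec.outer_radii)
    lo = np.zeros(len(p))
    hi = np.ones(len(p))
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        radii = ri[None, :] + mid[:, None] * (ro - ri)[None, :]
        level = np.sum((p / radii) ** 2, axis=1)
        too_shallow = level > 1.0  # still outside the trial shell: go deeper
        lo = np.where(too_shallow, mid, lo)
        hi = np.where(too_shallow, hi, mid)
    return 0.5 * (lo + hi)


def lv_phantom(spec: PhantomSpec):
    """Build the phantom field, mask and ground-truth wall-depth map.

    Returns ``(field, mask, wall_depth)`` where ``wall_depth`` is a 3D array
    holding t in [0, 1] inside the mask and NaN outside.  The fiber at depth
    t is ``cos(HA) c_hat + sin(HA) l_hat`` with ``c_hat`` the local
    circumferential direction (horizontal, tangent to the shell) and
    ``l_hat`` the in-surface longitudinal direction (pointing toward the
    equator), so the field is tangent to the interpolated shells by
    construction.  Voxels through which the long axis passes (apex cap)
    have no defined circumferential direction and are excluded.
    """
    sp = np.asarray(spec.spacing)
    ro = np.asarray(spec.outer_radii)
    ri = np.asarray(spec.inner_radii)
    pad = 2 * sp
    lo_corner = np.array([-ro[0], -ro[1], -ro[2]]) - pad
    hi_corner = np.array([ro[0], ro[1], 0.0]) + pad
    shape = np.ceil((hi_corner - lo_corner) / sp).astype(int)
    origin = lo_corner + sp / 2
    grid = VectorField(values=np.zeros(tuple(shape) + (3,)), spacing=sp, origin=origin)
    centers = grid.voxel_centers().reshape(-1, 3)

    inside = (
        (_ellipsoid_level(centers, ro) <= 1.0)
        & (_ellipsoid_level(centers, ri) >= 1.0)
        & (centers[:, 2] <= 0.0)
    )
    horiz = np.linalg.norm(centers[:, :2], axis=1)
    inside &= horiz > max(sp[0], sp[1])  # exclude the axis-degenerate apex cap
    if not inside.any():
        raise SynthError("phantom shells enclose no voxels; check radii vs spacing")

    pts = centers[inside]
    t = phantom_wall_depth(spec, pts)
    radii_t = ri[None, :] + t[:, None] * (ro - ri)[None, :]
    normal = pts / radii_t**2
    normal /= np.linalg.norm(normal, axis=1)[:, None]
    zhat = np.array([0.0, 0.0, 1.0])
    c_hat = np.cross(np.broadcast_to(zhat, normal.shape), normal)
    c_hat /= np.linalg.norm(c_hat, axis=1)[:, None]
    l_hat = np.cross(normal, c_hat)
    l_hat /= np.linalg.norm(l_hat, axis=1)[:, None]
    flip = l_hat[:, 2] < 0
    l_hat[flip] = -l_hat[flip]

    ha = np.radians(spec.ha_endo_deg + (spec.ha_epi_deg - spec.ha_endo_deg) * t)
    # The in-surface longitudinal direction is tilted wherever the shell is
    # sloped (l_hat_z < 1), which would understate the measured helical angle
    # of a fiber pitched at HA within the surface.  Compensate the in-surface
    # pitch gamma so the *global* helical angle (inclination from the
    # short-axis plane) equals the prescribed HA(t) profile everywhere:
    # tan(measured) = tan(gamma) * l_hat_z  =>  gamma = atan2(tan HA, l_hat_z).
    gamma = np.arctan2(np.tan(ha), l_hat[:, 2])
    fibers = np.cos(gamma)[:, None] * c_hat + np.sin(gamma)[:, None] * l_hat

    values = np.zeros(tuple(shape) + (3,))
    flags = np.zeros(tuple(shape), dtype=bool)
    depth = np.full(tuple(shape), np.nan)
    flat_idx = np.flatnonzero(inside)
    ii = np.unravel_index(flat_idx, tuple(shape))
    values[ii] = fibers
    flags[ii] = True
    depth[ii] = t

    field_out = VectorField(values=values, spacing=sp, origin=origin)
    mask = VoxelMask(flags=flags, spacing=sp, origin=origin)
    return field_out, mask, depth


def transmural_profile(polylines, spec: PhantomSpec, n_bins: int = 10):
    """Mean helical angle of phantom toolpaths, binned by wall depth.

    For each polyline the segment directions and midpoints give a mean
    measured helical angle (long axis = z, axis through the origin) and a
    mean wall depth.  Polylines are then grouped into ``n_bins`` quantile
    bins of mean wall depth (quantiles guarantee occupancy), and the
    per-bin mean helical angles are returned together with the per-polyline
    values.

    Returns ``(bin_means, mean_ha, mean_t)``.
    """
    mean_ha, mean_t = [], []
    for poly in polylines:
        pts = np.atleast_2d(np.asarray(getattr(poly, "points", poly), dtype=float))
        if len(pts) < 2:
            continue
        segs = np.diff(pts, axis=0)
        mids = 0.5 * (pts[:-1] + pts[1:])
        ok = np.linalg.norm(mids[:, :2], axis=1) > 1e-6
        if not ok.any():
            continue
        from .fields import helical_angle_batch

        ha = helical_angle_batch(segs[ok], mids[ok], (0.0, 0.0, 1.0), (0.0, 0.0, 0.0))
        mean_ha.append(float(ha.mean()))
        mean_t.append(float(phantom_wall_depth(spec, mids[ok]).mean()))
    mean_ha = np.asarray(mean_ha)
    mean_t = np.asarray(mean_t)
    edges = np.quantile(mean_t, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.digitize(mean_t, edges[1:-1]), 0, n_bins - 1)
    bin_means = np.array([
        mean_ha[bins == b].mean() if (bins == b).any() else np.nan
        for b in range(n_bins)
    ])
    return bin_means, mean_ha, mean_t


# ---------------------------------------------------------------------------
# Forward diffusion-signal simulation
# ---------------------------------------------------------------------------

def synthesize_dwi(
    tensors: TensorField,
    bvals,
    bvecs,
    s0: float | np.ndarray = 1000.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> DWIStack:
    """Stejskal-Tanner forward model: ``S = S0 exp(-b g^T D g)`` per voxel.

    Optional additive Gaussian noise with standard deviation ``noise_sd``
    uses a generator seeded by ``seed`` (tensor-fit round trips use the
    noiseless default).
    """
    bvals = np.asarray(bvals, dtype=float).reshape(-1)
    bvecs = np.asarray(bvecs, dtype=float).reshape(-1, 3)
    if np.any(bvals < 0):
        raise SynthError("b-values must be nonnegative")
    nz = bvals > 0
    if nz.any():
        norms = np.linalg.norm(bvecs[nz], axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise SynthError("b-vectors must be unit length for b > 0")
    D = tensors.tensors
    s0_grid = np.broadcast_to(np.asarray(s0, dtype=float), tensors.shape)
    # g^T D g for every voxel and gradient: (..., ngrad)
    quad = np.einsum("gi,...ij,gj->...g", bvecs, D, bvecs)
    signals = s0_grid[..., None] * np.exp(-bvals[None, None, None, :] * quad)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signals = signals + rng.normal(0.0, noise_sd, size=signals.shape)
        signals = np.clip(signals, 0.0, None)
    return DWIStack(
        signals=signals,
        bvals=bvals,
        bvecs=bvecs,
        spacing=tensors.spacing,
        origin=tensors.origin,
    )


#: A standard 6-direction gradient scheme (plus callers' b=0 volumes) that
#: spans the full symmetric-tensor space.
SIX_DIRECTIONS = np.array(
    [
        [1, 1, 0],
        [1, -1, 0],
        [1, 0, 1],
        [1, 0, -1],
        [0, 1, 1],
        [0, 1, -1],
    ],
    dtype=float,
) / np.sqrt(2.0)
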