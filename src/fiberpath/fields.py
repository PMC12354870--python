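"""Voxel vector fields, masks, and diffusion-tensor processing.

This module holds the low-level geometry that everything downstream builds
on: regular voxel grids of fiber directions, binary tissue masks,
diffusion-weighted stacks with their gradient tables, and the per-voxel
diffusion tensors fitted from them.  All world geometry is expressed in
millimetres; voxel indices are 0-based and the world coordinate of voxel
``(i, j, k)`` is ``origin + index * spacing``.

Fiber direction fields are *axial* quantities: ``v`` and ``-v`` describe the
same fiber.  Interpolation therefore sign-aligns the eight neighbouring
voxel vectors against a caller-supplied reference direction before
blending, so that antiparallel neighbours reinforce rather than cancel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

#: Blended-magnitude threshold below which an interpolated sample is treated
#: as falling off the field's support (e.g. at the edge of the tissue mask).
SUPPORT_EPS = 1e-8

#: Relative leading-eigengap threshold below which a diffusion tensor is
#: considered directionally degenerate (isotropic or planar).
DEGENERATE_EIGENGAP = 1e-9


class FieldError(ValueError):
    """Invalid field/mask construction or usage."""


class OutOfBoundsError(FieldError):
    """A sample point fell outside the interpolable interior of a grid."""


class InsufficientGradientScheme(FieldError):
    """The diffusion gradient table cannot determine a full tensor."""


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.shape != (3,):
        raise FieldError(f"{name} must be a length-3 vector, got shape {np.shape(x)}")
    return v


@dataclass
class VectorField:
    """A regular 3D grid of direction vectors.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz, 3)
        One (unnormalized allowed) direction vector per voxel.  Zero vectors
        mark voxels with no directional support (outside tissue).
    spacing : ndarray, shape (3,)
        Per-axis voxel size in mm; strictly positive.
    origin : ndarray, shape (3,)
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4 or self.values.shape[-1] != 3:
            raise FieldError(
                f"vector field values must have shape (nx, ny, nz, 3), got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise FieldError("vector field contains non-finite values")
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if np.any(self.spacing <= 0):
            raise FieldError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of world points (mm)."""
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``shape + (3,)``."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        )
        return self.voxel_to_world(idx)


@dataclass
class VoxelMask:
    """Binary tissue support on the same grid as an associated field."""

    flags: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags).astype(bool)
        if self.flags.ndim != 3:
            raise FieldError(f"mask must be 3D, got shape {self.flags.shape}")
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if np.any(self.spacing <= 0):
            raise FieldError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.flags.shape

    @property
    def n_true(self) -> int:
        return int(self.flags.sum())

    def require_nonempty(self) -> None:
        if not self.flags.any():
            raise FieldError("mask has no true voxels")

    def contains_points(self, points: np.ndarray) -> np.ndarray:
        """Membership of continuous points = membership of the nearest voxel."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        u = (pts - self.origin) / self.spacing
        idx = np.rint(u).astype(int)
        shape = np.asarray(self.shape)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        out = np.zeros(len(pts), dtype=bool)
        if inside.any():
            ii = idx[inside]
            out[inside] = self.flags[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out


@dataclass
class Image:
    """A scalar (3D) or multi-channel (4D) image on a regular grid."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (3, 4):
            raise FieldError(f"image must be 3D or 4D, got shape {self.data.shape}")
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if np.any(self.spacing <= 0):
            raise FieldError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape[:3]


@dataclass
class DWIStack:
    """Diffusion-weighted volumes plus their gradient table.

    ``signals`` has shape (nx, ny, nz, ngrad); ``bvals`` is the per-gradient
    b-value in s/mm^2 and ``bvecs`` the per-gradient unit direction
    (ngrad, 3).  At least one null-weighted (b = 0) volume is required, and
    tensor fitting additionally needs >= 6 independent nonzero directions.
    """

    signals: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).reshape(-1)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if self.signals.ndim != 4:
            raise FieldError(f"signals must be 4D, got shape {self.signals.shape}")
        n = self.signals.shape[-1]
        if self.bvals.shape != (n,) or self.bvecs.shape != (n, 3):
            raise FieldError(
                f"gradient table sizes ({self.bvals.shape}, {self.bvecs.shape}) do not "
                f"match {n} volumes"
            )
        if np.any(self.bvals < 0):
            raise FieldError("negative b-values are not allowed")
        if not np.any(self.bvals == 0):
            raise InsufficientGradientScheme("at least one b=0 volume is required")
        nz = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[nz], axis=1)
        if nz.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise FieldError("b-vectors for b>0 volumes must be unit length")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signals.shape[:3]


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors (mm^2/s) and baseline signal."""

    tensors: np.ndarray  # (nx, ny, nz, 3, 3)
    s0: np.ndarray  # (nx, ny, nz)
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        if self.tensors.ndim != 5 or self.tensors.shape[-2:] != (3, 3):
            raise FieldError(
                f"tensors must have shape (nx, ny, nz, 3, 3), got {self.tensors.shape}"
            )
        if self.s0.shape != self.tensors.shape[:3]:
            raise FieldError("s0 shape must match the tensor grid")
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    def require_symmetric(self, atol: float = 1e-10) -> None:
        if not np.allclose(self.tensors, np.swapaxes(self.tensors, -1, -2), atol=atol):
            raise FieldError("diffusion tensors must be symmetric")


# ---------------------------------------------------------------------------
# Trilinear, sign-coherent sampling
# ---------------------------------------------------------------------------

def sample_field_trilinear_batch(
    field: VectorField, points: np.ndarray, references: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sign-coherent trilinear samples at many points at once.

    Each of the 8 corner vectors is flipped, if needed, so that its dot
    product with the per-point reference direction is >= 0, then blended with
    the standard trilinear weights and normalized.

    Returns ``(vectors, valid)`` where invalid rows (outside the interpolable
    interior, or blended magnitude < ``SUPPORT_EPS``) carry a zero vector.
    A sample is in bounds only if all 8 neighbouring voxels exist; edge
    voxels are never extrapolated.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    refs = np.atleast_2d(np.asarray(references, dtype=float))
    if refs.shape != pts.shape:
        refs = np.broadcast_to(refs, pts.shape)
    u = field.world_to_voxel(pts)
    base = np.floor(u).astype(int)
    shape = np.asarray(field.shape)
    in_bounds = np.all(base >= 0, axis=1) & np.all(base <= shape - 2, axis=1)
    frac = u - base
    safe = np.where(in_bounds[:, None], base, 0)

    acc = np.zeros_like(pts)
    vals = field.values
    for bits in range(8):
        off = np.array([(bits >> 2) & 1, (bits >> 1) & 1, bits & 1])
        idx = safe + off
        v = vals[idx[:, 0], idx[:, 1], idx[:, 2]]
        dots = np.einsum("ij,ij->i", v, refs)
        v = np.where(dots[:, None] < 0, -v, v)
        w = np.prod(np.where(off[None, :] == 1, frac, 1.0 - frac), axis=1)
        acc += w[:, None] * v

    mag = np.linalg.norm(acc, axis=1)
    valid = in_bounds & (mag >= SUPPORT_EPS)
    out = np.zeros_like(acc)
    nz = valid
    out[nz] = acc[nz] / mag[nz, None]
    return out, valid


def sample_field_trilinear(
    field: VectorField, point: np.ndarray, reference_dir: np.ndarray
) -> np.ndarray:
    """Sign-coherent trilinear sample of a vector field at one world point.

    Raises :class:`OutOfBoundsError` outside the interpolable interior.
    Returns the zero vector when the blended magnitude falls below
    ``SUPPORT_EPS`` (the support boundary)."""
    p = _as_vec3(point, "point")
    r = _as_vec3(reference_dir, "reference_dir")
    vec, valid = sample_field_trilinear_batch(field, p[None, :], r[None, :])
    if not valid[0]:
        u = field.world_to_voxel(p)
        base = np.floor(u).astype(int)
        if np.any(base < 0) or np.any(base > np.asarray(field.shape) - 2):
            raise OutOfBoundsError(
                f"point {p} is outside the interpolable interior of the field"
            )
        return np.zeros(3)
    return vec[0]


# ---------------------------------------------------------------------------
# Diffusion tensor fitting
# ---------------------------------------------------------------------------

def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows of ln S = ln S0 - b g^T D g in the 6-component tensor basis."""
    b = bvals[:, None]
    g = bvecs
    return np.column_stack(
        [
            np.ones(len(bvals)),
            -b[:, 0] * g[:, 0] ** 2,
            -b[:, 0] * g[:, 1] ** 2,
            -b[:, 0] * g[:, 2] ** 2,
            -2 * b[:, 0] * g[:, 0] * g[:, 1],
            -2 * b[:, 0] * g[:, 0] * g[:, 2],
            -2 * b[:, 0] * g[:, 1] * g[:, 2],
        ]
    )


def fit_diffusion_tensors(dwi: DWIStack, mask: VoxelMask) -> TensorField:
    """Unweighted log-linear least-squares tensor fit per masked voxel.

    Solves ``ln S = ln S0 - b g^T D g`` over all gradients.  Non-positive
    signals inside the mask are clamped to a tiny positive value before the
    logarithm.  Voxels outside the mask are zeroed.
    """
    if dwi.shape != mask.shape:
        raise FieldError(f"mask shape {mask.shape} does not match DWI {dwi.shape}")
    mask.require_nonempty()
    A = _design_matrix(dwi.bvals, dwi.bvecs)
    # The b=0 rows only constrain ln S0: the directional part needs rank 6.
    nz = dwi.bvals > 0
    if not nz.any() or np.linalg.matrix_rank(A[nz, 1:]) < 6:
        raise InsufficientGradientScheme(
            "tensor fitting requires >= 6 independent nonzero gradient directions "
            "plus a null-weighted volume"
        )
    flags = mask.flags
    S = dwi.signals[flags]  # (m, ngrad)
    floor = max(float(np.max(S, initial=0.0)) * 1e-12, 1e-300)
    n_clamped = int(np.count_nonzero(S <= 0))
    if n_clamped:
        log.warning("clamped %d non-positive DWI samples before log transform", n_clamped)
    lnS = np.log(np.clip(S, floor, None))
    coef, *_ = np.linalg.lstsq(A, lnS.T, rcond=None)  # (7, m)
    s0_vals = np.exp(coef[0])
    dxx, dyy, dzz, dxy, dxz, dyz = coef[1:7]
    m = S.shape[0]
    T = np.empty((m, 3, 3))
    T[:, 0, 0] = dxx
    T[:, 1, 1] = dyy
    T[:, 2, 2] = dzz
    T[:, 0, 1] = T[:, 1, 0] = dxy
    T[:, 0, 2] = T[:, 2, 0] = dxz
    T[:, 1, 2] = T[:, 2, 1] = dyz

    tensors = np.zeros(dwi.shape + (3, 3))
    s0 = np.zeros(dwi.shape)
    tensors[flags] = T
    s0[flags] = s0_vals
    return TensorField(tensors=tensors, s0=s0, spacing=dwi.spacing, origin=dwi.origin)


def principal_direction_field(tf: TensorField, mask: VoxelMask) -> VectorField:
    """Unit principal eigenvector of each masked tensor; zero elsewhere.

    The eigenvector sign is unconstrained (fiber fields are axial).  Voxels
    whose leading eigengap is below ``DEGENERATE_EIGENGAP`` (relative) are
    marked degenerate with a zero vector, so tractography terminates there.
    """
    if tf.shape != mask.shape:
        raise FieldError(f"mask shape {mask.shape} does not match tensors {tf.shape}")
    tf.require_symmetric()
    mask.require_nonempty()
    flags = mask.flags
    T = tf.tensors[flags]
    w, v = np.linalg.eigh(T)  # ascending eigenvalues
    lead = v[:, :, 2]
    gap = w[:, 2] - w[:, 1]
    scale = np.maximum(np.abs(w[:, 2]), 1e-300)
    degenerate = gap < DEGENERATE_EIGENGAP * scale
    if degenerate.any():
        log.info("%d voxels have a degenerate principal direction", int(degenerate.sum()))
    lead = np.where(degenerate[:, None], 0.0, lead)
    values = np.zeros(tf.shape + (3,))
    values[flags] = lead
    return VectorField(values=values, spacing=tf.spacing, origin=tf.origin)


# ---------------------------------------------------------------------------
# Resampling / rescaling
# ---------------------------------------------------------------------------

def resample_and_scale(obj, target_spacing, scale=1.0):
    """Resample a grid object to a new voxel size, then rescale its world extent.

    The object is first interpolated onto a grid with ``target_spacing``
    (trilinear for images and vector fields, nearest-neighbour for masks)
    covering the same world extent, and the world geometry is then
    multiplied by the per-axis ``scale`` factor (values are unchanged by the
    scaling; only spacing and origin shrink or grow).
    """
    target = _as_vec3(np.broadcast_to(np.asarray(target_spacing, dtype=float), (3,)), "target_spacing")
    sc = _as_vec3(np.broadcast_to(np.asarray(scale, dtype=float), (3,)), "scale")
    if np.any(target <= 0):
        raise FieldError(f"target spacing must be positive, got {target}")
    if np.any(sc <= 0):
        raise FieldError(f"scale must be positive, got {sc}")

    if isinstance(obj, VectorField):
        data, is_mask = obj.values, False
    elif isinstance(obj, VoxelMask):
        data, is_mask = obj.flags.astype(float), True
    elif isinstance(obj, Image):
        data, is_mask = obj.data, False
    else:
        raise FieldError(f"cannot resample object of type {type(obj).__name__}")

    shape = np.asarray(data.shape[:3])
    spacing, origin = obj.spacing, obj.origin
    n_new = np.maximum(1, np.rint(shape * spacing / target).astype(int))
    # Align the world bounding boxes of the two grids (box corner to corner).
    new_origin = origin - spacing / 2 + target / 2
    grids = [new_origin[a] + np.arange(n_new[a]) * target[a] for a in range(3)]
    world = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1)
    coords = ((world - origin) / spacing).transpose(3, 0, 1, 2)

    order = 0 if is_mask else 1
    if data.ndim == 3:
        out = ndimage.map_coordinates(data, coords, order=order, mode="nearest")
    else:
        out = np.stack(
            [
                ndimage.map_coordinates(data[..., c], coords, order=order, mode="nearest")
                for c in range(data.shape[-1])
            ],
            axis=-1,
        )

    final_spacing = target * sc
    final_origin = new_origin * sc
    if isinstance(obj, VectorField):
        return VectorField(values=out, spacing=final_spacing, origin=final_origin)
    if isinstance(obj, VoxelMask):
        return VoxelMask(flags=out > 0.5, spacing=final_spacing, origin=final_origin)
    return Image(data=out, spacing=final_spacing, origin=final_origin)


def residual_map(original: np.ndarray, denoised: np.ndarray) -> np.ndarray:
    """Denoising residual diagnostic, ``sqrt(2 |original - denoised|)``.

    The absolute value guards the radicand against negative differences;
    this map is a visual diagnostic only and feeds nothing downstream.
    """
    a = np.asarray(original, dtype=float)
    b = np.asarray(denoised, dtype=float)
    if a.shape != b.shape:
        raise FieldError(f"shape mismatch: {a.shape} vs {b.shape}")
    log.debug("residual map uses |difference| under the square root")
    return np.sqrt(2.0 * np.abs(a - b))


# ---------------------------------------------------------------------------
# Helical angle
# ---------------------------------------------------------------------------

def helical_angle_batch(
    directions: np.ndarray,
    positions: np.ndarray,
    long_axis: np.ndarray,
    axis_point: np.ndarray,
) -> np.ndarray:
    """Vectorized :func:`helical_angle` over (n, 3) arrays; degrees in [-90, 90]."""
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    p = np.atleast_2d(np.asarray(positions, dtype=float))
    l = _as_vec3(long_axis, "long_axis")
    ln = np.linalg.norm(l)
    if ln == 0:
        raise FieldError("long_axis must be nonzero")
    l = l / ln
    a0 = _as_vec3(axis_point, "axis_point")
    if np.any(np.linalg.norm(d, axis=1) == 0):
        raise FieldError("direction must be nonzero")

    r = p - a0
    r_h = r - (r @ l)[:, None] * l
    rn = np.linalg.norm(r_h, axis=1)
    if np.any(rn < 1e-12):
        raise FieldError(
            "position lies on the long axis; the circumferential direction is undefined"
        )
    r_hat = r_h / rn[:, None]
    c_hat = np.cross(l, r_hat)
    dc = np.einsum("ij,ij->i", d, c_hat)
    dl = d @ l
    # Sign-flip the direction so its circumferential component is >= 0.
    flip = dc < 0
    dc = np.where(flip, -dc, dc)
    dl = np.where(flip, -dl, dl)
    ang = np.degrees(np.arctan2(dl, dc))
    # A purely longitudinal fiber is +90 deg regardless of axial sign.
    mag = np.linalg.norm(d, axis=1)
    ang = np.where(np.abs(dc) < 1e-12 * mag, 90.0, ang)
    return ang


def helical_angle(direction, position, long_axis, axis_point) -> float:
    """Angle of inclination between a fiber and the local short-axis plane.

    With ``r_hat`` the normalized horizontal offset of ``position`` from the
    long axis and ``c_hat = long_axis x r_hat`` the local circumferential
    direction, the fiber is sign-flipped so its circumferential component is
    >= 0 and the angle is ``atan2(d . long_axis, d . c_hat)`` in degrees.
    Purely circumferential fibers score 0, purely longitudinal ones +90.
    The result is invariant to negating or positively rescaling the fiber.
    """
    return float(
        helical_angle_batch(
            np.asarray(direction, dtype=float)[None, :],
            np.asarray(position, dtype=float)[None, :],
            long_axis,
            axis_point,
        )[0]
    )
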