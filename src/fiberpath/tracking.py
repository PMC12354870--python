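"""Seed generation and sign-coherent Runge-Kutta streamline tractography.

Streamlines are integrated with the classic fourth-order Runge-Kutta scheme
along a fiber direction field.  Because fiber fields are axial (``v`` and
``-v`` are equivalent), every stage evaluation is sign-aligned against the
direction of the previously committed step, and each seed is propagated both
forward and backward, yielding up to two streamlines per seed.

Integration is fully deterministic: identical inputs give bit-identical
polylines.  The heavy lifting happens in a batched tracer that advances all
seeds simultaneously; the public single-seed entry point shares exactly the
same code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import FieldError, VectorField, VoxelMask, sample_field_trilinear_batch

#: Slack applied to the maximum-length stopping rule (floating-point guard).
_LEN_EPS = 1e-9


class TrackingError(ValueError):
    """Invalid tractography parameters or seeds."""


@dataclass
class TractographyParams:
    """Tractography controls.

    Parameters
    ----------
    n_seed : int
        Seeds per voxel; must be a perfect cube so a uniform sub-grid exists.
    delta_s : float
        Integration step size in mm.
    l_max : float
        Maximum streamline arc length in mm.
    """

    n_seed: int = 1
    delta_s: float = 0.125
    l_max: float = 18.75

    def __post_init__(self) -> None:
        if self.n_seed < 1:
            raise TrackingError("n_seed must be >= 1")
        if self.delta_s <= 0:
            raise TrackingError("delta_s must be positive")
        if self.l_max < self.delta_s:
            raise TrackingError("l_max must be at least one step delta_s")


@dataclass
class Streamline:
    """An ordered polyline in world mm, tangent to the direction field."""

    points: np.ndarray  # (n, 3)
    seed_index: int = -1
    direction_flag: str = "forward"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3:
            raise TrackingError("streamline points must be (n, 3)")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def arc_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


def _cube_root(n_seed: int) -> int:
    r = round(n_seed ** (1.0 / 3.0))
    for cand in (r - 1, r, r + 1):
        if cand >= 1 and cand**3 == n_seed:
            return cand
    below = int(np.floor(n_seed ** (1.0 / 3.0))) ** 3
    above = (int(np.floor(n_seed ** (1.0 / 3.0))) + 1) ** 3
    raise TrackingError(
        f"n_seed must be a perfect cube so a uniform sub-grid exists; got {n_seed} "
        f"(nearest cubes: {below} and {above})"
    )


def generate_seeds(mask: VoxelMask, n_seed: int) -> np.ndarray:
    """Uniform seed points throughout the masked volume.

    A global regular grid with per-axis spacing ``voxel_size / cbrt(n_seed)``
    is laid down so that every voxel contains exactly ``n_seed`` sub-cell
    centers; only seeds whose containing voxel is masked are returned, in
    deterministic lexicographic order of their global grid index.
    """
    mask.require_nonempty()
    m = _cube_root(n_seed)
    nx, ny, nz = mask.shape
    axes = []
    for n_ax, sp, org in zip((nx, ny, nz), mask.spacing, mask.origin):
        j = np.arange(n_ax * m)
        axes.append(org + (-0.5 + (j + 0.5) / m) * sp)
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    jj = np.stack(
        np.meshgrid(*[np.arange(n_ax * m) // m for n_ax in (nx, ny, nz)], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    keep = mask.flags[jj[:, 0], jj[:, 1], jj[:, 2]]
    return pts[keep]


# ---------------------------------------------------------------------------
# Field sampling dispatch: regular grids vs analytic fields
# ---------------------------------------------------------------------------

def _sample(field, points: np.ndarray, refs: np.ndarray):
    if isinstance(field, VectorField):
        return sample_field_trilinear_batch(field, points, refs)
    return field.sample_batch(points, refs)  # analytic fields (duck typed)


def _initial_refs(field, seeds: np.ndarray) -> np.ndarray:
    """Raw (unaligned) field vector at each seed, used as the first reference."""
    if isinstance(field, VectorField):
        idx = np.rint(field.world_to_voxel(seeds)).astype(int)
        idx = np.clip(idx, 0, np.asarray(field.shape) - 1)
        return field.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    return field.vectors_at(seeds)


def _in_domain(field, mask, points: np.ndarray) -> np.ndarray:
    if mask is not None:
        return mask.contains_points(points)
    return field.in_support(points)


def _trace_batch(field, mask, seeds: np.ndarray, signs: np.ndarray, params: TractographyParams):
    """Advance all seeds simultaneously with RK4; returns a list of point arrays.

    A step is committed only if all four stage samples are valid and the
    endpoint stays inside the mask (membership of a continuous point is that
    of its nearest voxel); otherwise the streamline ends at its last
    committed point.  Steps that would push the accumulated arc length past
    ``l_max`` are discarded.
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    n = len(seeds)
    ds = params.delta_s
    max_steps = int(np.floor(params.l_max / ds + _LEN_EPS)) + 1

    refs = _initial_refs(field, seeds) * np.asarray(signs, dtype=float)[:, None]
    alive = np.linalg.norm(refs, axis=1) > 0
    alive &= _in_domain(field, mask, seeds)

    pts = np.empty((n, max_steps + 1, 3))
    pts[:, 0] = seeds
    counts = np.ones(n, dtype=int)
    lengths = np.zeros(n)
    pos = seeds.copy()

    while alive.any():
        ai = np.flatnonzero(alive)
        p = pos[ai]
        r = refs[ai]
        k1, v1 = _sample(field, p, r)
        k2, v2 = _sample(field, p + 0.5 * ds * k1, r)
        k3, v3 = _sample(field, p + 0.5 * ds * k2, r)
        k4, v4 = _sample(field, p + ds * k3, r)
        ok = v1 & v2 & v3 & v4
        delta = (ds / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        step_len = np.linalg.norm(delta, axis=1)
        newp = p + delta
        ok &= step_len > 0
        ok &= lengths[ai] + step_len <= params.l_max + _LEN_EPS
        ok &= counts[ai] <= max_steps  # buffer guard; the length rule fires first
        ok &= _in_domain(field, mask, newp)

        committed = ai[ok]
        if committed.size:
            pos[committed] = newp[ok]
            pts[committed, counts[committed]] = newp[ok]
            counts[committed] += 1
            lengths[committed] += step_len[ok]
            refs[committed] = delta[ok] / step_len[ok, None]
        alive[ai[~ok]] = False

    return [pts[i, : counts[i]].copy() for i in range(n)]


def integrate_streamline(
    field,
    mask: VoxelMask | None,
    seed,
    sign: int,
    params: TractographyParams,
) -> Streamline | None:
    """Integrate a single streamline from ``seed`` in one axial direction.

    ``sign`` (+1 or -1) selects the forward or backward branch by flipping
    the initial reference direction.  Returns ``None`` if no full RK4 step
    succeeds (degenerate seeds, seeds on the support boundary).
    """
    seed = np.asarray(seed, dtype=float).reshape(3)
    if sign not in (+1, -1):
        raise TrackingError("sign must be +1 or -1")
    if not _in_domain(field, mask, seed[None, :])[0]:
        raise TrackingError(f"seed {seed} is outside the mask")
    points = _trace_batch(field, mask, seed[None, :], np.array([sign]), params)[0]
    if len(points) < 2:
        return None
    return Streamline(points=points, seed_index=0,
                      direction_flag="forward" if sign > 0 else "backward")


def run_tractography(field, mask: VoxelMask | None, params: TractographyParams) -> list[Streamline]:
    """Bidirectional tractography from every masked seed.

    Every seed yields up to two streamlines (signs +1 and -1), kept separate
    rather than merged.  Streamlines with fewer than 2 points (a degenerate
    polyline that cannot be printed) are dropped.  Output order is
    deterministic: by seed index, forward before backward.
    """
    if isinstance(field, VectorField) and mask is None:
        raise TrackingError("a voxel mask is required for grid fields")
    if mask is not None:
        mask.require_nonempty()
        if isinstance(field, VectorField) and field.shape != mask.shape:
            raise FieldError(f"mask shape {mask.shape} does not match field {field.shape}")
        seeds = generate_seeds(mask, params.n_seed)
    else:
        raise TrackingError("run_tractography requires a mask to generate seeds")
    if len(seeds) == 0:
        raise TrackingError("no seeds fall inside the mask")

    n = len(seeds)
    both = np.vstack([seeds, seeds])
    signs = np.concatenate([np.ones(n), -np.ones(n)])
    traces = _trace_batch(field, mask, both, signs, params)
    out: list[Streamline] = []
    for i in range(n):
        for off, flag in ((0, "forward"), (n, "backward")):
            p = traces[i + off]
            if len(p) >= 2:
                out.append(Streamline(points=p, seed_index=i, direction_flag=flag))
    return out
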