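"""Sweep-exclusion thinning of dense streamline sets.

Tractography produces far more streamlines than an extrusion printer can
resolve.  Sweep exclusion reduces the set to a subset with a guaranteed
minimum inter-streamline spacing ``w_s`` (the expected printed line
diameter): starting from the longest streamline, a cylinder of radius
``w_s`` is swept along the current streamline and every remaining streamline
that intersects the cylinder is removed; the next streamline to sweep is the
remaining one nearest to the last swept, measured by the Minimum Average
Direct-Flip (MDF) distance.  The loop continues until every streamline has
been swept (kept) or removed.

All tie-breaks (equal lengths, equal MDF distances) resolve to the lowest
input index, so the procedure is deterministic given the input order.  The
KD-tree acceleration used inside :func:`sweep_exclusion` only prunes
candidate samples and cannot change the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .tracking import Streamline


class ThinningError(ValueError):
    """Invalid thinning parameters or degenerate streamlines."""


@dataclass
class SweepParams:
    """Sweep-exclusion controls.

    Parameters
    ----------
    w_s : float
        Swept-cylinder radius = target print-line spacing in mm.  Should be
        set to the expected printed line diameter.
    resample_points : int
        Point count K used for MDF distances (both streamlines are
        resampled to K equal-arc-length points).
    test_step : float or None
        Maximum sample spacing (mm) used in intersection tests; defaults to
        ``w_s / 2`` and may not exceed it (bounds the discretization error).
    """

    w_s: float
    resample_points: int = 20
    test_step: float | None = None

    def __post_init__(self) -> None:
        if self.w_s <= 0:
            raise ThinningError("w_s must be positive")
        if self.resample_points < 2:
            raise ThinningError("resample_points must be >= 2")
        if self.test_step is None:
            self.test_step = self.w_s / 2
        if not 0 < self.test_step <= self.w_s / 2:
            raise ThinningError("test_step must be in (0, w_s/2]")


@dataclass
class RemovalRecord:
    """One streamline removal: who was removed, by which sweep, and when."""

    index: int
    removed_by: int
    iteration: int


def _pts(s) -> np.ndarray:
    if isinstance(s, Streamline):
        return s.points
    return np.atleast_2d(np.asarray(s, dtype=float))


def resample_polyline(points: np.ndarray, k: int) -> np.ndarray:
    """K points at equal arc-length intervals; endpoints preserved exactly."""
    if k < 2:
        raise ThinningError("resample count must be >= 2")
    p = _pts(points)
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    total = float(seg.sum())
    if total == 0:
        raise ThinningError("cannot resample a zero-length streamline")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, k)
    out = np.column_stack([np.interp(targets, cum, p[:, a]) for a in range(3)])
    out[0], out[-1] = p[0], p[-1]
    return out


def resample_streamline(s: Streamline, k: int) -> Streamline:
    """Streamline wrapper around :func:`resample_polyline`."""
    return Streamline(points=resample_polyline(_pts(s), k),
                      seed_index=getattr(s, "seed_index", -1),
                      direction_flag=getattr(s, "direction_flag", "forward"))


def mdf_distance(a, b, k: int = 20) -> float:
    """Minimum Average Direct-Flip distance between two streamlines (mm).

    Both streamlines are resampled to ``k`` equal-arc-length points; the
    distance is the smaller of the mean pointwise Euclidean distances taken
    directly or with one streamline reversed.  Symmetric and nonnegative.
    """
    ra = resample_polyline(_pts(a), k)
    rb = resample_polyline(_pts(b), k)
    direct = float(np.mean(np.linalg.norm(ra - rb, axis=1)))
    flipped = float(np.mean(np.linalg.norm(ra - rb[::-1], axis=1)))
    return min(direct, flipped)


def _min_dist_to_polyline(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Exact point-to-segment distance from each point to a polyline."""
    P = np.atleast_2d(points)
    if len(poly) == 1:
        return np.linalg.norm(P - poly[0], axis=1)
    A = poly[:-1]
    AB = poly[1:] - A
    L2 = np.einsum("ij,ij->i", AB, AB)
    L2safe = np.where(L2 == 0, 1.0, L2)
    diff = P[:, None, :] - A[None, :, :]  # (n, m, 3)
    t = np.clip(np.einsum("nmj,mj->nm", diff, AB) / L2safe, 0.0, 1.0)
    t = np.where(L2[None, :] == 0, 0.0, t)
    closest = diff - t[:, :, None] * AB[None, :, :]
    d2 = np.einsum("nmj,nmj->nm", closest, closest)
    return np.sqrt(d2.min(axis=1))


def _test_samples(points: np.ndarray, step: float) -> np.ndarray:
    """Samples along a polyline at spacing <= step (used by intersection tests)."""
    p = _pts(points)
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    total = float(seg.sum())
    if total == 0:
        return p[:1]
    n = max(2, int(np.ceil(total / step)) + 1)
    return resample_polyline(p, n)


def tube_intersects(swept, other, w_s: float, test_step: float) -> bool:
    """Does ``other`` enter the radius-``w_s`` cylinder swept along ``swept``?

    ``other`` is sampled at spacing <= ``test_step`` and the minimum
    point-to-segment distance to the swept polyline is compared against
    ``w_s`` (strictly inside counts as an intersection).
    """
    samples = _test_samples(_pts(other), test_step)
    d = _min_dist_to_polyline(samples, _pts(swept))
    return bool(np.min(d) < w_s)


def sweep_exclusion(streamlines: list, params: SweepParams):
    """Reduce a streamline set to a printer-resolution subset.

    Returns ``(kept_indices, removals)`` where ``kept_indices`` lists input
    indices in sweep order and ``removals`` is a list of
    :class:`RemovalRecord`.  Every input streamline appears in exactly one
    of the two groups, and every kept streamline clears every earlier-kept
    streamline's polyline by at least ``w_s`` (up to the ``test_step``
    discretization of the intersection test).
    """
    if len(streamlines) == 0:
        raise ThinningError("sweep exclusion requires a nonempty streamline set")
    polys = [_pts(s) for s in streamlines]
    n = len(polys)
    lengths = np.array([np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)) for p in polys])

    # Pre-resampled representations: dense samples for the intersection test,
    # K-point versions for the MDF next-path selection.
    k = params.resample_points
    mdf_pts = np.stack([
        resample_polyline(p, k) if lengths[i] > 0 else np.repeat(p[:1], k, axis=0)
        for i, p in enumerate(polys)
    ])
    dense = [_test_samples(p, params.test_step) for p in polys]
    owners = np.concatenate([np.full(len(d), i) for i, d in enumerate(dense)])
    cloud = np.vstack(dense)
    tree = cKDTree(cloud)

    PENDING, KEPT, REMOVED = 0, 1, 2
    status = np.full(n, PENDING, dtype=np.int8)
    removals: list[RemovalRecord] = []
    kept_order: list[int] = []

    current = int(np.argmax(lengths))  # ties: lowest input index
    iteration = 0
    while True:
        iteration += 1
        status[current] = KEPT
        kept_order.append(current)
        poly = polys[current]

        # Candidate cloud samples near the swept polyline (prefilter only:
        # any point within w_s of a segment lies within |seg|/2 + w_s of its
        # midpoint, so no true intersection can be missed).
        cand: set[int] = set()
        if len(poly) == 1:
            cand.update(tree.query_ball_point(poly[0], params.w_s + 1e-9))
        else:
            mids = 0.5 * (poly[:-1] + poly[1:])
            half = 0.5 * np.linalg.norm(poly[1:] - poly[:-1], axis=1)
            for mid, h in zip(mids, half):
                cand.update(tree.query_ball_point(mid, h + params.w_s + 1e-9))
        if cand:
            ci = np.fromiter(cand, dtype=int)
            ci = ci[status[owners[ci]] == PENDING]
            if ci.size:
                d = _min_dist_to_polyline(cloud[ci], poly)
                hit_owner = np.unique(owners[ci[d < params.w_s]])
                for o in hit_owner:
                    status[o] = REMOVED
                    removals.append(RemovalRecord(index=int(o), removed_by=current,
                                                  iteration=iteration))

        pending = np.flatnonzero(status == PENDING)
        if pending.size == 0:
            break
        ref = mdf_pts[current]
        direct = np.mean(np.linalg.norm(mdf_pts[pending] - ref, axis=2), axis=1)
        flipped = np.mean(np.linalg.norm(mdf_pts[pending] - ref[::-1], axis=2), axis=1)
        d = np.minimum(direct, flipped)
        current = int(pending[np.argmin(d)])  # ties: lowest input index

    return kept_order, removals
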