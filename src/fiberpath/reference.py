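"""Brute-force reference implementations used for validation.

These are deliberately slow, transparent re-computations of quantities the
main modules obtain by smarter means; they exist so the geometric collision
test and the stochastic acyclic search can be checked against an
independent route on small inputs.  Nothing in the pipeline calls them.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .interference import DependencyGraph, PrinterGeometry, _material_radius
from .reduction import is_acyclic
from .thinning import _test_samples


def voxel_collision_oracle(
    printing,
    deposited,
    geom: PrinterGeometry,
    test_step: float | None = None,
    pitch: float | None = None,
) -> bool:
    """Voxelized occupancy version of the needle/material collision test.

    Builds a dense voxel grid over the joint bounding region and marks, per
    voxel center, membership in (a) the needle volume — the union over
    printing-path samples ``s`` of semi-infinite vertical cylinders
    ``{horizontal distance <= d_n/2, z >= s_z + tip_offset}`` — and (b) the
    material volume — the union over deposited-path samples ``q`` of
    axis-aligned spheroids with horizontal semi-axis ``d_p/2`` and vertical
    semi-axis ``h_p/2``.  Collision iff any voxel center lies in both.
    These membership rules are exactly those of the analytic pair test, so
    the two routes may disagree only within one voxel pitch of the margin.
    """
    if test_step is None:
        test_step = geom.default_test_step
    if pitch is None:
        pitch = min(geom.d_n if geom.d_n > 0 else geom.d_p, geom.h_p) / 8
    P = _test_samples(np.asarray(getattr(printing, "points", printing), float), test_step)
    Q = _test_samples(np.asarray(getattr(deposited, "points", deposited), float), test_step)

    lo = np.minimum(P.min(axis=0), Q.min(axis=0)) - max(geom.d_n, geom.d_p)
    hi = np.maximum(P.max(axis=0), Q.max(axis=0)) + max(geom.d_n, geom.d_p)
    # The needle is unbounded upward but material is not: cap at material top.
    hi[2] = Q[:, 2].max() + geom.h_p
    axes = [np.arange(lo[a], hi[a] + pitch, pitch) for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    centers = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    needle = np.zeros(len(centers), dtype=bool)
    for s in P:
        hxy = np.linalg.norm(centers[:, :2] - s[:2], axis=1)
        needle |= (hxy <= geom.d_n / 2) & (centers[:, 2] >= s[2] + geom.tip_offset)
    material = np.zeros(len(centers), dtype=bool)
    for q in Q:
        hxy = np.linalg.norm(centers[:, :2] - q[:2], axis=1)
        material |= (hxy / (geom.d_p / 2)) ** 2 + (
            (centers[:, 2] - q[2]) / (geom.h_p / 2)
        ) ** 2 <= 1.0
    return bool(np.any(needle & material))


def collision_margin(printing, deposited, geom: PrinterGeometry,
                     test_step: float | None = None) -> float:
    """Signed clearance of the analytic pair test (negative = colliding).

    The minimum over admissible sample pairs of
    ``horizontal_distance - (d_n/2 + material_radius)``; pairs whose needle
    bottom clears the bead top contribute their vertical clearance instead.
    Used to identify borderline cases where voxelized and analytic routes
    may legitimately disagree.
    """
    if test_step is None:
        test_step = geom.default_test_step
    P = _test_samples(np.asarray(getattr(printing, "points", printing), float), test_step)
    Q = _test_samples(np.asarray(getattr(deposited, "points", deposited), float), test_step)
    bottoms = P[:, 2] + geom.tip_offset
    dz = bottoms[:, None] - Q[None, :, 2]
    horiz = np.linalg.norm(P[:, None, :2] - Q[None, :, :2], axis=2)
    limit = geom.d_n / 2 + _material_radius(dz, geom)
    reach = dz < geom.h_p / 2
    gap = np.where(reach, horiz - limit, np.maximum(horiz - limit, dz - geom.h_p / 2))
    return float(gap.min())


def exhaustive_max_acyclic_subgraph(g: DependencyGraph) -> int:
    """Size of the true maximum induced acyclic subgraph by subset enumeration.

    Exponential in the vertex count; intended for graphs of <= 12 vertices.
    Subsets are scanned from largest to smallest, so the first acyclic one
    gives the optimum size.
    """
    n = len(g.vertices)
    if n > 16:
        raise ValueError("exhaustive enumeration is limited to small graphs")
    if is_acyclic(g):
        return n
    for size in range(n - 1, -1, -1):
        for keep in combinations(g.vertices, size):
            if is_acyclic(g.subgraph(keep)):
                return size
    return 0
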