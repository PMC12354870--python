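"""Needle/material collision prediction, cut planes, and dependency graphs.

During extrusion printing the needle travels along the toolpath being
deposited while earlier toolpaths already occupy space.  The needle is
modeled as a vertical cylinder of diameter ``d_n`` extending upward from the
tip; the deposited bead is modeled, sample by sample, as an axis-aligned
oblate spheroid with horizontal major axis ``d_p`` and vertical minor axis
``h_p`` (``h_p <= d_p``; a flattened bead).  Toolpath A *depends on*
toolpath B (edge A -> B, A must print after B) when printing B with A
already deposited would drive the needle through A's material.

The axis-aligned spheroid is a conservative simplification: the true bead
cross-section is perpendicular to the local path tangent, so this model can
only add safe ordering constraints, never miss one of that model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .thinning import _test_samples


class InterferenceError(ValueError):
    """Invalid geometry or graph construction."""


@dataclass
class PrinterGeometry:
    """Geometry of the extrusion system used for collision prediction.

    Parameters
    ----------
    d_n : float
        Needle diameter (mm), taken at the inner diameter.
    d_p : float
        Deposited bead width (mm) = horizontal major axis of its cross
        section; measured from a printed sample.
    h_p : float or None
        Vertical minor axis of the bead cross section (mm); defaults to
        ``d_p / 2`` (a flattened bead).
    tip_offset : float
        Height of the needle tip above the toolpath centerline (mm).
    """

    d_n: float = 0.4
    d_p: float = 0.548
    h_p: float | None = None
    tip_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.h_p is None:
            self.h_p = self.d_p / 2
        if self.d_p <= 0:
            raise InterferenceError("d_p must be positive")
        if self.d_n < 0 or self.tip_offset < 0:
            raise InterferenceError("d_n and tip_offset must be >= 0")
        if not 0 < self.h_p <= self.d_p:
            raise InterferenceError("h_p must satisfy 0 < h_p <= d_p")

    @property
    def default_test_step(self) -> float:
        """Sampling step for collision tests: min(d_n, d_p) / 4."""
        base = min(self.d_n, self.d_p) if self.d_n > 0 else self.d_p
        return base / 4


#: Printing-setup presets: quarter-scale (22 GA needle) and full-scale
#: (18 GA needle) parameter sets.
SCALE_PRESETS = {
    "1:4": dict(w_s=0.84, d_n=0.4, d_p=0.548, delta_s=0.125, l_max=18.75, n_seed=1),
    "1:1": dict(w_s=1.0, d_n=0.84, d_p=1.0, delta_s=0.5, l_max=75.0, n_seed=64),
}


@dataclass
class CutPlane:
    """A zero-thickness plane that splits crossing toolpaths.

    Toolpaths crossing the plane (within its finite extent, if given) are
    split at the exact intersection point, which is duplicated into both
    pieces so the printed seam has no gap.  Dependency-graph edges between
    opposite sides of the plane are prohibited.

    ``extent``, when given, is a pair of finite half-widths along two
    in-plane axes derived deterministically from the normal.
    """

    point: np.ndarray
    normal: np.ndarray
    extent: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise InterferenceError("cut plane normal must be nonzero")
        self.normal = n / nn
        if self.extent is not None:
            e = tuple(float(x) for x in self.extent)
            if len(e) != 2 or any(x <= 0 for x in e):
                raise InterferenceError("extent must be two positive half-widths")
            self.extent = e

    def in_plane_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic orthonormal in-plane axes (e1, e2)."""
        n = self.normal
        helper = np.zeros(3)
        helper[int(np.argmin(np.abs(n)))] = 1.0
        e1 = np.cross(n, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        return e1, e2

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.point) @ self.normal

    def within_extent(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        if self.extent is None:
            return np.ones(len(pts), dtype=bool)
        e1, e2 = self.in_plane_axes()
        rel = pts - self.point
        return (np.abs(rel @ e1) <= self.extent[0]) & (np.abs(rel @ e2) <= self.extent[1])


@dataclass
class Toolpath:
    """A printable polyline with an id and an optional cut-plane side label."""

    id: int
    points: np.ndarray
    side: int | None = None
    parent: int | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3 or len(self.points) < 1:
            raise InterferenceError("toolpath points must be a nonempty (n, 3) array")

    @property
    def arc_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


@dataclass
class DependencyGraph:
    """Directed graph over toolpath ids: edge (u, v) = u must print after v."""

    vertices: list[int] = field(default_factory=list)
    edges: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.vertices = sorted(set(int(v) for v in self.vertices))
        self.edges = {(int(u), int(v)) for (u, v) in self.edges}
        vs = set(self.vertices)
        for u, v in self.edges:
            if u == v:
                raise InterferenceError(f"self-edge on vertex {u}")
            if u not in vs or v not in vs:
                raise InterferenceError(f"edge ({u}, {v}) references unknown vertex")

    def add_edge(self, u: int, v: int) -> None:
        if u == v:
            raise InterferenceError("self-edges are not allowed")
        self.edges.add((int(u), int(v)))

    def successors(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {v: set() for v in self.vertices}
        for u, v in self.edges:
            adj[u].add(v)
        return adj

    def subgraph(self, keep) -> "DependencyGraph":
        ks = set(int(v) for v in keep)
        return DependencyGraph(
            vertices=[v for v in self.vertices if v in ks],
            edges={(u, v) for (u, v) in self.edges if u in ks and v in ks},
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(sorted(self.edges))
        return g

    @classmethod
    def from_networkx(cls, g) -> "DependencyGraph":
        return cls(vertices=list(g.nodes), edges=set(g.edges))


# ---------------------------------------------------------------------------
# Collision model
# ---------------------------------------------------------------------------

def _material_radius(dz: np.ndarray, geom: PrinterGeometry) -> np.ndarray:
    """Horizontal reach of the bead spheroid at height ``dz`` above its center.

    ``dz`` is clipped below at zero: a needle whose reachable band starts
    below the bead center sees the full half-width ``d_p / 2``.
    """
    frac = np.clip(dz / (geom.h_p / 2), 0.0, 1.0)
    return (geom.d_p / 2) * np.sqrt(np.maximum(0.0, 1.0 - frac**2))


def needle_collides(printing, deposited, geom: PrinterGeometry,
                    test_step: float | None = None) -> bool:
    """Would printing along ``printing`` strike material along ``deposited``?

    Both toolpaths are sampled at spacing <= ``test_step`` (default
    ``min(d_n, d_p)/4``).  The needle along ``printing`` is the union over
    its samples ``s`` of semi-infinite vertical cylinders
    ``{horizontal distance <= d_n/2, z >= s_z + tip_offset}``; the material
    along ``deposited`` is the union over its samples ``q`` of axis-aligned
    spheroids ``{(horiz/(d_p/2))^2 + ((z - q_z)/(h_p/2))^2 <= 1}``.  The
    test evaluates, per sample pair, the exact intersection condition of
    those two shapes: the needle bottom must sit below the bead top, and the
    horizontal gap must be smaller than ``d_n/2`` plus the bead's horizontal
    reach at the lowest reachable height.  The prediction is directional:
    swap the roles and the answer may change.
    """
    if test_step is None:
        test_step = geom.default_test_step
    P = _test_samples(np.asarray(getattr(printing, "points", printing), dtype=float), test_step)
    Q = _test_samples(np.asarray(getattr(deposited, "points", deposited), dtype=float), test_step)
    bottoms = P[:, 2] + geom.tip_offset
    dz = bottoms[:, None] - Q[None, :, 2]  # needle bottom relative to bead center
    reachable = dz < geom.h_p / 2
    if not reachable.any():
        return False
    horiz = np.linalg.norm(P[:, None, :2] - Q[None, :, :2], axis=2)
    limit = geom.d_n / 2 + _material_radius(dz, geom)
    return bool(np.any(reachable & (horiz < limit)))


# ---------------------------------------------------------------------------
# Cut plane splitting
# ---------------------------------------------------------------------------

_PLANE_EPS = 1e-12


def split_by_cut_plane(toolpaths: list[Toolpath], plane: CutPlane) -> list[Toolpath]:
    """Split toolpaths at transversal plane crossings and label the sides.

    Each crossing within the plane's finite extent cuts the toolpath; the
    exact intersection point is appended to both resulting pieces (the
    zero-thickness seam).  Side labels are +1/-1 by the sign of the signed
    distance of each piece's interior; points lying exactly in the plane
    inherit the side of their neighbours.  Returned toolpaths are re-id'd
    sequentially; ``parent`` records provenance.
    """
    out: list[Toolpath] = []
    next_id = 0
    for tp in toolpaths:
        pts = tp.points
        d = plane.signed_distance(pts)
        d = np.where(np.abs(d) < _PLANE_EPS, 0.0, d)
        pieces: list[list[np.ndarray]] = [[pts[0]]]
        for i in range(len(pts) - 1):
            d0, d1 = d[i], d[i + 1]
            crossing = (d0 > 0 > d1) or (d0 < 0 < d1)
            if crossing:
                t = d0 / (d0 - d1)
                x = pts[i] + t * (pts[i + 1] - pts[i])
                if plane.within_extent(x[None, :])[0]:
                    pieces[-1].append(x)
                    pieces.append([x.copy(), pts[i + 1]])
                    continue
            if d1 == 0 and d0 != 0:
                # A vertex exactly on the plane: close the piece here and start
                # the next one at the shared seam point if the path continues
                # to the other side (checked on the following segment).
                nxt = d[i + 2] if i + 2 < len(d) else 0.0
                if d0 * nxt < 0 and plane.within_extent(pts[i + 1][None, :])[0]:
                    pieces[-1].append(pts[i + 1])
                    pieces.append([pts[i + 1].copy()])
                    continue
            pieces[-1].append(pts[i + 1])

        # Side label per piece: sign of the first nonzero signed distance of
        # its points; pieces lying entirely in the plane take a neighbour's.
        labels: list[int | None] = []
        for piece in pieces:
            dd = plane.signed_distance(np.asarray(piece))
            dd = dd[np.abs(dd) >= _PLANE_EPS]
            labels.append(int(np.sign(dd[0])) if dd.size else None)
        for j, lab in enumerate(labels):
            if lab is None:
                neigh = [labels[jj] for jj in (j - 1, j + 1)
                         if 0 <= jj < len(labels) and labels[jj] is not None]
                labels[j] = neigh[0] if neigh else 1

        for piece, lab in zip(pieces, labels):
            arr = np.asarray(piece)
            if len(arr) >= 2:
                out.append(Toolpath(id=next_id, points=arr, side=lab, parent=tp.id))
                next_id += 1
    return out


# ---------------------------------------------------------------------------
# Dependency graph construction
# ---------------------------------------------------------------------------

def build_dependency_graph(
    toolpaths: list[Toolpath],
    geom: PrinterGeometry,
    test_step: float | None = None,
    use_sides: bool | None = None,
) -> DependencyGraph:
    """Pairwise collision testing over every ordered toolpath pair.

    Edge ``A -> B`` (A depends on B: A must print after B) is added iff
    ``needle_collides(printing=B, deposited=A)`` and, when cut-plane side
    labels are present, A and B share a side (edges across the plane are
    explicitly prohibited).  Both orientations of every pair are tested
    independently.  Bounding-box and KD-tree prefilters only skip pairs that
    provably cannot collide.
    """
    ids = [tp.id for tp in toolpaths]
    if len(set(ids)) != len(ids):
        raise InterferenceError("toolpath ids must be unique")
    if test_step is None:
        test_step = geom.default_test_step
    if use_sides is None:
        use_sides = any(tp.side is not None for tp in toolpaths)

    n = len(toolpaths)
    samples = [_test_samples(tp.points, test_step) for tp in toolpaths]
    xy = [s[:, :2] for s in samples]
    z = [s[:, 2] for s in samples]
    trees = [cKDTree(s) for s in xy]
    lo = np.array([s[:, :2].min(axis=0) for s in samples])
    hi = np.array([s[:, :2].max(axis=0) for s in samples])
    zmin = np.array([zz.min() for zz in z])
    zmax = np.array([zz.max() for zz in z])
    R = geom.d_n / 2 + geom.d_p / 2

    graph = DependencyGraph(vertices=ids)
    for a in range(n):  # deposited
        for b in range(n):  # printing
            if a == b:
                continue
            if use_sides and toolpaths[a].side is not None and toolpaths[b].side is not None \
                    and toolpaths[a].side != toolpaths[b].side:
                continue
            # Horizontal bounding boxes inflated by the maximum reach.
            if np.any(lo[b] - hi[a] > R) or np.any(lo[a] - hi[b] > R):
                continue
            # The needle bottom must dip below the bead top somewhere.
            if zmin[b] + geom.tip_offset >= zmax[a] + geom.h_p / 2:
                continue
            if _collides_indexed(trees[b], xy[b], z[b], xy[a], z[a], geom, R):
                graph.add_edge(ids[a], ids[b])
    return graph


def _collides_indexed(tree_p, xy_p, z_p, xy_q, z_q, geom: PrinterGeometry, R: float) -> bool:
    """KD-tree-accelerated version of the :func:`needle_collides` pair test."""
    neighbours = tree_p.query_ball_point(xy_q, R)
    bottoms = z_p + geom.tip_offset
    for j, idx in enumerate(neighbours):
        if not idx:
            continue
        idx = np.asarray(idx)
        dz = bottoms[idx] - z_q[j]
        reach = dz < geom.h_p / 2
        if not reach.any():
            continue
        horiz = np.linalg.norm(xy_p[idx] - xy_q[j], axis=1)
        limit = geom.d_n / 2 + _material_radius(dz, geom)
        if np.any(reach & (horiz < limit)):
            return True
    return False
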