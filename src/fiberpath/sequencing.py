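"""Toolpath ordering and G-code emission.

Given an acyclic dependency graph, a printable sequence is any topological
order.  Among those, total non-extruding travel should be small: shorter
travel means shorter prints, which matters for ink rheology and cell
viability.  The ordering here is an incremental greedy search: at every
step, among the toolpaths whose dependencies are all already placed, append
the one (and, optionally, the traversal direction) whose entry point is
closest to the current nozzle position.  This realizes a depth-first greedy
descent whose per-step cost is the added travel gap — it minimizes travel
locally, not globally (no TSP-style optimization is attempted).

G-code output is plain ``G1`` moves with configurable header/footer and
extrusion on/off command strings; pressure-controller specifics belong in
those strings.  Feeds are configured in mm/s and emitted in mm/min.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .interference import DependencyGraph, Toolpath
from .reduction import is_acyclic

log = logging.getLogger(__name__)


class SequencingError(ValueError):
    """Ordering or emission failure."""


@dataclass
class ToolpathSequence:
    """Ordered toolpath ids with per-toolpath traversal orientation.

    ``order`` is a list of ``(toolpath_id, reversed)`` pairs; ``start`` is
    the nozzle position before the first travel move.
    """

    order: list[tuple[int, bool]]
    start: np.ndarray

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float).reshape(3)
        ids = [i for i, _ in self.order]
        if len(ids) != len(set(ids)):
            raise SequencingError("every toolpath id must appear exactly once")


@dataclass
class GcodeConfig:
    """G-code emission settings (feeds in mm/s, converted to mm/min)."""

    print_feed: float = 3.0
    travel_feed: float = 10.0
    header: list[str] = field(default_factory=lambda: ["G21 ; millimeters", "G90 ; absolute"])
    footer: list[str] = field(default_factory=lambda: ["M2 ; end of program"])
    extrusion_on: str = "M101 ; extrusion on"
    extrusion_off: str = "M103 ; extrusion off"
    decimals: int = 4

    def __post_init__(self) -> None:
        if self.print_feed <= 0 or self.travel_feed <= 0:
            raise SequencingError("feeds must be positive")
        if self.decimals < 1:
            raise SequencingError("decimals must be >= 1")


def _endpoints(tp: Toolpath, reverse: bool) -> tuple[np.ndarray, np.ndarray]:
    pts = tp.points
    return (pts[-1], pts[0]) if reverse else (pts[0], pts[-1])


def default_start(toolpaths: list[Toolpath]) -> np.ndarray:
    """Axis-aligned bounding-box corner with minimum x, y and z."""
    allpts = np.vstack([tp.points for tp in toolpaths])
    return allpts.min(axis=0)


def greedy_order(
    toolpaths: list[Toolpath],
    graph: DependencyGraph,
    start=None,
    allow_reversal: bool = True,
) -> ToolpathSequence:
    """Greedy travel-minimizing topological ordering.

    At every step the candidate set contains each unplaced toolpath whose
    dependencies (graph successors) are all placed; the candidate/orientation
    pair with the smallest Euclidean travel from the current nozzle position
    to its entry point wins (ties: lowest id, then as-stored orientation).
    The nozzle then sits at that toolpath's exit point.  The result is a
    valid topological order containing every toolpath.
    """
    by_id = {tp.id: tp for tp in toolpaths}
    if set(by_id) != set(graph.vertices):
        raise SequencingError("graph vertices must match toolpath ids 1:1")
    if not is_acyclic(graph):
        raise SequencingError(
            "dependency graph contains cycles; run reduce_to_acyclic first"
        )
    if start is None:
        start = default_start(toolpaths)
    start = np.asarray(start, dtype=float).reshape(3)

    deps = graph.successors()
    placed: set[int] = set()
    remaining = set(by_id)
    pos = start
    order: list[tuple[int, bool]] = []
    while remaining:
        ready = [u for u in remaining if deps[u] <= placed]
        if not ready:  # unreachable for a DAG; defensive
            raise SequencingError("no placeable toolpath found; graph is not acyclic")
        best = None
        for u in sorted(ready):
            for rev in (False, True) if allow_reversal else (False,):
                entry, _ = _endpoints(by_id[u], rev)
                d = float(np.linalg.norm(entry - pos))
                key = (d, u, rev)
                if best is None or key < best:
                    best = key
        d, u, rev = best
        order.append((u, rev))
        placed.add(u)
        remaining.discard(u)
        _, exit_pt = _endpoints(by_id[u], rev)
        pos = exit_pt
    return ToolpathSequence(order=order, start=start)


def total_travel_distance(seq: ToolpathSequence, toolpaths: list[Toolpath]) -> float:
    """Sum of non-extruding gaps: start-to-first plus every exit-to-entry gap."""
    by_id = {tp.id: tp for tp in toolpaths}
    pos = seq.start
    total = 0.0
    for tid, rev in seq.order:
        entry, exit_pt = _endpoints(by_id[tid], rev)
        total += float(np.linalg.norm(entry - pos))
        pos = exit_pt
    return total


def write_gcode(seq: ToolpathSequence, toolpaths: list[Toolpath], cfg: GcodeConfig) -> str:
    """Emit the ordered toolpaths as G-code text.

    Per toolpath: one travel ``G1`` at the travel feed to the entry point,
    the extrusion-on command, one ``G1`` per subsequent point at the print
    feed, then the extrusion-off command.  Feeds are mm/s x 60 = mm/min;
    coordinates are fixed-point with ``cfg.decimals`` digits, so a parse of
    the file recovers them to half of the last printed decimal.
    """
    by_id = {tp.id: tp for tp in toolpaths}
    d = cfg.decimals
    travel_f = cfg.travel_feed * 60.0
    print_f = cfg.print_feed * 60.0

    def g1(p, feed):
        return f"G1 X{p[0]:.{d}f} Y{p[1]:.{d}f} Z{p[2]:.{d}f} F{feed:.{d}f}"

    lines = list(cfg.header)
    if not seq.order:
        log.warning("empty toolpath sequence: emitting header and footer only")
    for tid, rev in seq.order:
        pts = by_id[tid].points
        if rev:
            pts = pts[::-1]
        lines.append(g1(pts[0], travel_f))
        lines.append(cfg.extrusion_on)
        for p in pts[1:]:
            lines.append(g1(p, print_f))
        lines.append(cfg.extrusion_off)
    lines.extend(cfg.footer)
    return "\n".join(lines) + "\n"


def parse_gcode(text: str, cfg: GcodeConfig) -> list[np.ndarray]:
    """Recover the extruded polylines from G-code written by :func:`write_gcode`.

    Returns one (n, 3) coordinate array per extruded toolpath, in print
    order.  Used for round-trip verification.
    """
    on_line = cfg.extrusion_on.strip()
    off_line = cfg.extrusion_off.strip()
    paths: list[np.ndarray] = []
    current: list[list[float]] | None = None
    last_xyz: list[float] | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if line == on_line:
            current = [last_xyz] if last_xyz is not None else []
            continue
        if line == off_line:
            if current:
                paths.append(np.asarray(current, dtype=float))
            current = None
            continue
        if line.startswith("G1 "):
            coords = {}
            for tok in line.split()[1:]:
                if tok[0] in "XYZ":
                    coords[tok[0]] = float(tok[1:])
            if {"X", "Y", "Z"} <= set(coords):
                last_xyz = [coords["X"], coords["Y"], coords["Z"]]
                if current is not None:
                    current.append(last_xyz)
    return paths
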