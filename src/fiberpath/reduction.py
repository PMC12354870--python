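"""Acyclic reduction of toolpath dependency graphs.

A printable order exists only if the dependency graph is acyclic, so cyclic
graphs must lose toolpaths.  Finding the true maximum induced acyclic
subgraph is NP-hard (its complement is a minimum feedback vertex set), so a
two-stage reduction is used instead:

1. *Length-2 cycle pre-processing* — while any pair of mutually dependent
   toolpaths exists, remove the 2-cycle vertex with the largest product of
   in-degree and out-degree (the one most entangled in further cycles).
2. *Iterative stochastic search* — for ``N`` iterations, repeatedly locate
   a directed cycle and delete a uniformly random vertex on it until the
   graph is acyclic; keep the largest surviving subgraph over all
   iterations.

Random removal targets only vertices known to lie on a cycle, never acyclic
bystanders — strictly more effective than deleting arbitrary vertices.  A
single integer seed drives a PCG64 generator, making the whole reduction
reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .interference import DependencyGraph


class ReductionError(ValueError):
    """Invalid reduction parameters."""


@dataclass
class ReductionParams:
    """Stochastic search controls: iteration count and RNG seed."""

    n_iterations: int = 10_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ReductionError("n_iterations must be >= 1")


@dataclass
class RemovalAudit:
    """One removed vertex: which stage dropped it and at which iteration."""

    vertex: int
    stage: str
    iteration: int


@dataclass
class ConvergencePoint:
    """Best retained subgraph size observed up to a given iteration."""

    iteration: int
    best_size: int


def _successors(g: DependencyGraph) -> dict[int, set[int]]:
    return g.successors()


def _find_cycle(adj: dict[int, set[int]]) -> list[int] | None:
    """One directed cycle (vertex list) via iterative DFS, or None.

    Start vertices and neighbour expansion are iterated in sorted order so
    the located cycle is deterministic for a given graph.
    """
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {v: WHITE for v in adj}
    parent: dict[int, int] = {}
    for start in sorted(adj):
        if color[start] != WHITE:
            continue
        stack: list[tuple[int, list[int]]] = [(start, sorted(adj[start], reverse=True))]
        color[start] = GRAY
        while stack:
            v, nbrs = stack[-1]
            if nbrs:
                w = nbrs.pop()
                if w not in adj:
                    continue
                if color[w] == GRAY:
                    cycle = [w]
                    u = v
                    while u != w:
                        cycle.append(u)
                        u = parent[u]
                    cycle.reverse()
                    return cycle
                if color[w] == WHITE:
                    color[w] = GRAY
                    parent[w] = v
                    stack.append((w, sorted(adj[w], reverse=True)))
            else:
                color[v] = BLACK
                stack.pop()
    return None


def is_acyclic(g: DependencyGraph) -> bool:
    """True iff a topological order of the graph exists."""
    return _find_cycle(_successors(g)) is None


def _delete_vertex(adj: dict[int, set[int]], v: int) -> None:
    adj.pop(v, None)
    for s in adj.values():
        s.discard(v)


def remove_length2_cycles(g: DependencyGraph) -> tuple[DependencyGraph, list[int]]:
    """Remove 2-cycles by repeatedly deleting the most entangled vertex.

    While any mutually-dependent pair remains, the vertex participating in a
    2-cycle with the largest in-degree x out-degree product (tie: lowest id)
    is removed along with all incident edges.  Returns the reduced graph and
    the removed vertex ids in removal order.
    """
    adj = _successors(g)
    removed: list[int] = []
    while True:
        two_cycle = sorted(
            v for v in adj if any(w in adj and v in adj[w] for w in adj[v])
        )
        if not two_cycle:
            break
        in_deg = {v: 0 for v in adj}
        for u in adj:
            for w in adj[u]:
                if w in in_deg:
                    in_deg[w] += 1
        best = max(two_cycle, key=lambda v: (len(adj[v]) * in_deg[v], -v))
        _delete_vertex(adj, best)
        removed.append(best)
    keep = set(adj)
    return g.subgraph(keep), removed


def stochastic_acyclic_reduction(
    g: DependencyGraph, params: ReductionParams
) -> tuple[DependencyGraph, list[int], list[ConvergencePoint]]:
    """Iterative stochastic maximum-acyclic-subgraph search.

    Each iteration restarts from the input graph and, while it is cyclic,
    deletes a uniformly random vertex of one located cycle.  The result
    retained over ``n_iterations`` iterations maximizes vertex count (ties:
    first attained).  Acyclic inputs return unchanged immediately.  The
    convergence history records every improvement of the best size.

    Returns ``(best_subgraph, removed_ids, history)``.
    """
    base = _successors(g)
    if _find_cycle(base) is None:
        return g, [], [ConvergencePoint(iteration=0, best_size=len(g.vertices))]

    rng = np.random.default_rng(params.rng_seed)
    best_removed: list[int] | None = None
    history: list[ConvergencePoint] = []
    for it in range(1, params.n_iterations + 1):
        adj = {v: set(s) for v, s in base.items()}
        removed: list[int] = []
        while (cycle := _find_cycle(adj)) is not None:
            victim = cycle[int(rng.integers(len(cycle)))]
            _delete_vertex(adj, victim)
            removed.append(victim)
        if best_removed is None or len(removed) < len(best_removed):
            best_removed = removed
            history.append(ConvergencePoint(iteration=it,
                                            best_size=len(base) - len(removed)))
        if len(best_removed) == 1:
            # The graph is cyclic, so at least one vertex must go: optimal.
            break
    keep = set(base) - set(best_removed)
    return g.subgraph(keep), list(best_removed), history


def reduce_to_acyclic(
    g: DependencyGraph, params: ReductionParams
) -> tuple[DependencyGraph, list[RemovalAudit], list[ConvergencePoint]]:
    """Two-stage reduction: 2-cycle pre-processing then stochastic search.

    Returns the acyclic subgraph, an audit of every removal labelled by
    stage, and the stochastic stage's convergence history.
    """
    g1, removed1 = remove_length2_cycles(g)
    g2, removed2, history = stochastic_acyclic_reduction(g1, params)
    audit = [RemovalAudit(vertex=v, stage="two_cycle", iteration=i + 1)
             for i, v in enumerate(removed1)]
    audit += [RemovalAudit(vertex=v, stage="stochastic", iteration=i + 1)
              for i, v in enumerate(removed2)]
    return g2, audit, history
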