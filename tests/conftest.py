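import numpy as np
import pytest

import fiberpath as fp


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def quarter_scale_geometry():
    """22 GA needle printing setup (inner diameter 0.4 mm, bead 0.548 mm)."""
    return fp.PrinterGeometry(d_n=0.4, d_p=0.548)


@pytest.fixture(scope="session")
def small_phantom():
    """A coarse helical-ventricle phantom shared by slower geometry tests."""
    spec = fp.PhantomSpec(outer_radii=(8.0, 8.0, 9.0), inner_radii=(5.0, 5.0, 6.0),
                          spacing=0.5)
    field, mask, depth = fp.lv_phantom(spec)
    return spec, field, mask, depth


def random_polyline(rng, n_min=2, n_max=5, box=0.8, step=(0.3, 0.8)):
    """A short random polyline with bounded turning, for collision tests."""
    start = rng.uniform(-box, box, 3)
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    pts = [start]
    for _ in range(int(rng.integers(n_min - 1, n_max))):
        d = d + 0.4 * rng.normal(size=3)
        d /= np.linalg.norm(d)
        pts.append(pts[-1] + d * rng.uniform(*step))
    return np.asarray(pts)


def random_dag(rng, n, p):
    """A random DAG: edges only from higher to lower topological rank."""
    perm = rng.permutation(n)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.add((int(perm[j]), int(perm[i])))  # later depends on earlier
    return fp.DependencyGraph(vertices=list(range(n)), edges=edges)


def random_digraph(rng, n, p):
    edges = {
        (i, j)
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    }
    return fp.DependencyGraph(vertices=list(range(n)), edges=edges)
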