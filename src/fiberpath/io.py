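"""File formats: NIFTI grids, streamline JSON-lines, graphs, and tables.

Conventions
-----------
* NIFTI: images and masks are stored as plain 3D volumes; vector fields as
  4D with the vector components in the last dimension (size 3); tensors as
  4D with 6 lower-triangular components (xx, yy, zz, xy, xz, yz).  The
  affine is diagonal (spacing) plus translation (origin); data are written
  in world mm.
* Streamlines: JSON-lines, one streamline object per line with mm
  coordinates rounded to 4 decimals
  (``{"id": ..., "seed_index": ..., "direction": ..., "points": [[x,y,z], ...]}``).
* Graphs: edge-list CSV (``source,target`` meaning source depends on
  target) with an accompanying vertex list, or GraphML via networkx.
* Gradient tables: FSL-style whitespace text (one row of b-values; three
  rows of b-vector components).
"""

from __future__ import annotations

import csv
import json

import nibabel as nib
import numpy as np

from .fields import Image, TensorField, VectorField, VoxelMask
from .interference import DependencyGraph
from .tracking import Streamline

_COORD_DECIMALS = 4


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _grid_from_affine(aff: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    spacing = np.linalg.norm(aff[:3, :3], axis=0)
    origin = aff[:3, 3]
    return spacing, origin


def save_nifti(obj, path) -> None:
    """Write a VectorField, VoxelMask, Image or TensorField as NIFTI."""
    path = str(path)
    if isinstance(obj, VectorField):
        data = obj.values
    elif isinstance(obj, VoxelMask):
        data = obj.flags.astype(np.uint8)
    elif isinstance(obj, Image):
        data = obj.data
    elif isinstance(obj, TensorField):
        t = obj.tensors
        data = np.stack(
            [t[..., 0, 0], t[..., 1, 1], t[..., 2, 2],
             t[..., 0, 1], t[..., 0, 2], t[..., 1, 2]],
            axis=-1,
        )
    else:
        raise TypeError(f"cannot save object of type {type(obj).__name__}")
    nib.save(nib.Nifti1Image(np.asarray(data), _affine(obj.spacing, obj.origin)), path)


def load_vector_field(path) -> VectorField:
    img = nib.load(str(path))
    spacing, origin = _grid_from_affine(img.affine)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"{path} is not a 4D x 3 vector field")
    return VectorField(values=data, spacing=spacing, origin=origin)


def load_mask(path) -> VoxelMask:
    img = nib.load(str(path))
    spacing, origin = _grid_from_affine(img.affine)
    return VoxelMask(flags=np.asarray(img.dataobj) > 0, spacing=spacing, origin=origin)


def load_image(path) -> Image:
    img = nib.load(str(path))
    spacing, origin = _grid_from_affine(img.affine)
    return Image(data=np.asarray(img.dataobj, dtype=float), spacing=spacing, origin=origin)


def load_tensor_field(path, s0=None) -> TensorField:
    img = nib.load(str(path))
    spacing, origin = _grid_from_affine(img.affine)
    d = np.asarray(img.dataobj, dtype=float)
    if d.ndim != 4 or d.shape[-1] != 6:
        raise ValueError(f"{path} is not a 4D x 6 lower-triangular tensor image")
    T = np.zeros(d.shape[:3] + (3, 3))
    T[..., 0, 0], T[..., 1, 1], T[..., 2, 2] = d[..., 0], d[..., 1], d[..., 2]
    T[..., 0, 1] = T[..., 1, 0] = d[..., 3]
    T[..., 0, 2] = T[..., 2, 0] = d[..., 4]
    T[..., 1, 2] = T[..., 2, 1] = d[..., 5]
    s0_arr = np.ones(d.shape[:3]) if s0 is None else np.asarray(s0, dtype=float)
    return TensorField(tensors=T, s0=s0_arr, spacing=spacing, origin=origin)


def read_bvals_bvecs(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    """FSL-style gradient table: bvals one row, bvecs three rows."""
    bvals = np.loadtxt(str(bval_path)).reshape(-1)
    bvecs = np.loadtxt(str(bvec_path))
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # ambiguous square case: assume FSL row layout
    return bvals, bvecs.reshape(-1, 3)


def write_bvals_bvecs(bvals, bvecs, bval_path, bvec_path) -> None:
    np.savetxt(str(bval_path), np.asarray(bvals).reshape(1, -1), fmt="%.6g")
    np.savetxt(str(bvec_path), np.asarray(bvecs).T, fmt="%.8f")


# ---------------------------------------------------------------------------
# Streamlines
# ---------------------------------------------------------------------------

def save_streamlines(streamlines, path) -> None:
    """JSON-lines streamline export (4-decimal fixed precision, mm)."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, s in enumerate(streamlines):
            pts = np.asarray(getattr(s, "points", s), dtype=float)
            rec = {
                "id": i,
                "seed_index": int(getattr(s, "seed_index", -1)),
                "direction": getattr(s, "direction_flag", "forward"),
                "points": np.round(pts, _COORD_DECIMALS).tolist(),
            }
            fh.write(json.dumps(rec) + "\n")


def load_streamlines(path) -> list[Streamline]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            out.append(
                Streamline(
                    points=np.asarray(rec["points"], dtype=float),
                    seed_index=rec.get("seed_index", -1),
                    direction_flag=rec.get("direction", "forward"),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Graphs and tabular audits
# ---------------------------------------------------------------------------

def save_graph_csv(graph: DependencyGraph, edges_path, vertices_path=None) -> None:
    """Edge list CSV; ``source`` depends on (prints after) ``target``."""
    with open(edges_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "target"])
        for u, v in sorted(graph.edges):
            w.writerow([u, v])
    if vertices_path is not None:
        with open(vertices_path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["id"])
            for v in graph.vertices:
                w.writerow([v])


def load_graph_csv(edges_path, vertices_path=None) -> DependencyGraph:
    edges = set()
    verts = set()
    with open(edges_path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            u, v = int(row["source"]), int(row["target"])
            edges.add((u, v))
            verts.update((u, v))
    if vertices_path is not None:
        with open(vertices_path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                verts.add(int(row["id"]))
    return DependencyGraph(vertices=sorted(verts), edges=edges)


def save_graphml(graph: DependencyGraph, path) -> None:
    import networkx as nx

    nx.write_graphml(graph.to_networkx(), str(path))


def load_graphml(path) -> DependencyGraph:
    import networkx as nx

    g = nx.read_graphml(str(path))
    return DependencyGraph(
        vertices=[int(v) for v in g.nodes],
        edges={(int(u), int(v)) for u, v in g.edges},
    )


def save_table_csv(rows: list[dict], path) -> None:
    """Write a list of uniform dicts (audits, manifests) as CSV."""
    rows = list(rows)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if not rows:
            return
        w = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        w.writeheader()
        w.writerows(rows)
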