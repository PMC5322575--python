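"""Plain-text I/O: Triangle-dialect mesh files, VTK export, measurement CSV.

Mesh files use the classic `.node`/`.ele` pair: a header line with counts,
then 1-based indexed records (stated in the file header comments).  Floats
are written with 17 significant digits so a write/read round trip is
bit-exact.
"""

from __future__ import annotations

import os

import numpy as np

from .forward import MeasurementSet
from .mesh import TriMesh, build_trimesh

__all__ = ["write_mesh", "read_mesh", "write_vtk", "write_measurements",
           "read_measurements", "write_field_csv"]

_FMT = "%.17g"


def write_mesh(mesh: TriMesh, basepath: str) -> None:
    """Write ``basepath.node`` and ``basepath.ele`` (1-based indices)."""
    with open(basepath + ".node", "w") as fh:
        fh.write(f"# node file, 1-based indices\n{mesh.n_nodes} 2 0 0\n")
        for i, (x, y) in enumerate(mesh.nodes, start=1):
            fh.write(f"{i} {_FMT % x} {_FMT % y}\n")
    with open(basepath + ".ele", "w") as fh:
        fh.write(f"# ele file, 1-based indices\n{mesh.n_elements} 3 0\n")
        for i, tri in enumerate(mesh.triangles, start=1):
            fh.write(f"{i} {tri[0] + 1} {tri[1] + 1} {tri[2] + 1}\n")


def read_mesh(basepath: str, radius: float | None = None) -> TriMesh:
    """Read a ``.node``/``.ele`` pair written by :func:`write_mesh` (or any
    Triangle-dialect file without attributes)."""

    def records(path):
        with open(path) as fh:
            rows = [ln.split() for ln in fh
                    if ln.strip() and not ln.lstrip().startswith("#")]
        return rows[0], rows[1:]

    (nv, _dim, *_), node_rows = records(basepath + ".node")
    nodes = np.empty((int(nv), 2))
    for row in node_rows:
        nodes[int(row[0]) - 1] = (float(row[1]), float(row[2]))
    (nt, *_), ele_rows = records(basepath + ".ele")
    tris = np.empty((int(nt), 3), dtype=np.int64)
    for row in ele_rows:
        tris[int(row[0]) - 1] = (int(row[1]) - 1, int(row[2]) - 1, int(row[3]) - 1)
    return build_trimesh(nodes, tris, radius=radius)


def write_vtk(path: str, mesh: TriMesh, cell_data: dict[str, np.ndarray]
              | None = None) -> None:
    """Legacy ASCII VTK export of the mesh and optional per-element fields."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ntriangulated disk\nASCII\n"
                 "DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y in mesh.nodes:
            fh.write(f"{_FMT % x} {_FMT % y} 0\n")
        T = mesh.n_elements
        fh.write(f"CELLS {T} {4 * T}\n")
        for tri in mesh.triangles:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        fh.write(f"CELL_TYPES {T}\n" + "5\n" * T)
        if cell_data:
            fh.write(f"CELL_DATA {T}\n")
            for name, vals in cell_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in np.asarray(vals, dtype=float):
                    fh.write(f"{_FMT % v}\n")


def write_measurements(path: str, ms: MeasurementSet,
                       metadata: dict | None = None) -> None:
    """Detector x source CSV plus a ``path.meta`` key-value sidecar."""
    n_det, n_src = ms.M.shape
    with open(path, "w") as fh:
        fh.write("detector," + ",".join(f"source_{i + 1}" for i in range(n_src))
                 + "\n")
        for j in range(n_det):
            fh.write(f"{j + 1}," + ",".join(_FMT % v for v in ms.M[j]) + "\n")
    meta = {"n_detectors": n_det, "n_sources": n_src, "delta": ms.delta,
            "seed": ms.seed}
    meta.update(metadata or {})
    with open(path + ".meta", "w") as fh:
        for k, v in meta.items():
            fh.write(f"{k} = {v}\n")


def read_measurements(path: str):
    """Read a measurement CSV; returns (M array, metadata dict or {})."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("detector,"):
            raise ValueError(f"{path}: not a measurement CSV")
        rows = [ln.strip().split(",")[1:] for ln in fh if ln.strip()]
    M = np.array([[float(v) for v in row] for row in rows])
    meta = {}
    if os.path.exists(path + ".meta"):
        with open(path + ".meta") as fh:
            for ln in fh:
                if "=" in ln:
                    k, v = ln.split("=", 1)
                    meta[k.strip()] = v.strip()
    return M, meta


def write_field_csv(path: str, **fields) -> None:
    """Per-element fields as CSV: element_index (1-based) plus one column per
    keyword array."""
    names = list(fields)
    arrs = [np.asarray(fields[n], dtype=float) for n in names]
    n = len(arrs[0])
    with open(path, "w") as fh:
        fh.write("element_index," + ",".join(names) + "\n")
        for i in range(n):
            fh.write(f"{i + 1}," + ",".join(_FMT % a[i] for a in arrs) + "\n")
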