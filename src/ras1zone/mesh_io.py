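"""PLY and legacy-VTK export of the membrane mesh with per-cell fields.

Polygons are the Voronoi cells lifted from their local tangent charts, so
adjacent faces do not share vertex records; per-cell scalars (areas and
arbitrary fields) are written as face properties with 17 significant
digits so a write/read round-trip reproduces them bit-exactly.
"""

from __future__ import annotations

import numpy as np

from .mesh import SurfaceMesh

__all__ = ["write_ply", "read_ply_fields", "write_vtk", "read_vtk_fields"]

_FMT = "%.17g"


def _face_table(mesh: SurfaceMesh):
    verts, faces = [], []
    off = 0
    for poly in mesh.polygons:
        k = len(poly)
        verts.append(poly)
        faces.append(list(range(off, off + k)))
        off += k
    return np.concatenate(verts), faces


def write_ply(mesh: SurfaceMesh, path, fields: dict | None = None) -> None:
    fields = dict(fields or {})
    fields.setdefault("area", mesh.areas)
    verts, faces = _face_table(mesh)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write("comment ras1zone membrane mesh\n")
        fh.write(f"element vertex {len(verts)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write(f"element face {len(faces)}\n")
        fh.write("property list uchar int vertex_indices\n")
        for name in fields:
            fh.write(f"property double {name}\n")
        fh.write("end_header\n")
        for v in verts:
            fh.write(" ".join(_FMT % x for x in v) + "\n")
        names = list(fields)
        for i, f in enumerate(faces):
            row = [str(len(f))] + [str(j) for j in f]
            row += [_FMT % fields[name][i] for name in names]
            fh.write(" ".join(row) + "\n")


def read_ply_fields(path) -> dict:
    """Per-face scalar fields from an ASCII PLY written by :func:`write_ply`."""
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError("not a PLY file")
        n_vert = n_face = 0
        names: list[str] = []
        element = None
        while True:
            line = fh.readline().strip()
            if line == "end_header":
                break
            parts = line.split()
            if parts[0] == "element":
                element = parts[1]
                if element == "vertex":
                    n_vert = int(parts[2])
                elif element == "face":
                    n_face = int(parts[2])
            elif parts[0] == "property" and element == "face" and parts[1] != "list":
                names.append(parts[2])
        for _ in range(n_vert):
            fh.readline()
        out = {name: np.empty(n_face) for name in names}
        for i in range(n_face):
            parts = fh.readline().split()
            k = int(parts[0])
            vals = parts[1 + k:]
            for name, v in zip(names, vals):
                out[name][i] = float(v)
    return out


def write_vtk(mesh: SurfaceMesh, path, fields: dict | None = None) -> None:
    fields = dict(fields or {})
    fields.setdefault("area", mesh.areas)
    verts, faces = _face_table(mesh)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("ras1zone membrane mesh\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(verts)} double\n")
        for v in verts:
            fh.write(" ".join(_FMT % x for x in v) + "\n")
        size = sum(len(f) + 1 for f in faces)
        fh.write(f"POLYGONS {len(faces)} {size}\n")
        for f in faces:
            fh.write(" ".join([str(len(f))] + [str(j) for j in f]) + "\n")
        fh.write(f"CELL_DATA {len(faces)}\n")
        for name, vals in fields.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(_FMT % v for v in vals) + "\n")


def read_vtk_fields(path) -> dict:
    with open(path) as fh:
        lines = fh.read().split("\n")
    out = {}
    i = 0
    n_cells = 0
    while i < len(lines):
        parts = lines[i].split()
        if parts and parts[0] == "CELL_DATA":
            n_cells = int(parts[1])
        elif parts and parts[0] == "SCALARS":
            name = parts[1]
            i += 2  # skip LOOKUP_TABLE
            vals = [float(lines[i + k]) for k in range(n_cells)]
            out[name] = np.asarray(vals)
            i += n_cells - 1
        i += 1
    return out
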