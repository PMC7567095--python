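"""Minimal legacy-ASCII VTK writers for meshes, point sets and field data.

Good enough for ParaView inspection of surfaces, coil dipole clouds and
E-field snapshots; intentionally writes only what this package produces.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import TriMesh

__all__ = ["write_vtk_mesh", "write_vtk_points"]


def _header(fh, title: str) -> None:
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\n")


def write_vtk_mesh(
    mesh: TriMesh, path: str | Path, point_data: dict[str, np.ndarray] | None = None
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        _header(fh, mesh.label or "surface")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} float\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        _write_point_data(fh, mesh.n_vertices, point_data)
    return path


def write_vtk_points(
    points: np.ndarray, path: str | Path, point_data: dict[str, np.ndarray] | None = None
) -> Path:
    points = np.atleast_2d(points)
    path = Path(path)
    with open(path, "w") as fh:
        _header(fh, "points")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} float\n")
        for v in points:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        fh.write(f"VERTICES {len(points)} {2 * len(points)}\n")
        for i in range(len(points)):
            fh.write(f"1 {i}\n")
        _write_point_data(fh, len(points), point_data)
    return path


def _write_point_data(fh, n: int, point_data: dict[str, np.ndarray] | None) -> None:
    if not point_data:
        return
    fh.write(f"POINT_DATA {n}\n")
    for name, arr in point_data.items():
        arr = np.asarray(arr)
        if arr.ndim == 1:
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            for x in arr:
                fh.write(f"{x:.6g}\n")
        else:
            fh.write(f"VECTORS {name} float\n")
            for v in arr:
                fh.write(f"{v[0]:.6g} {v[1]:.6g} {v[2]:.6g}\n")
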