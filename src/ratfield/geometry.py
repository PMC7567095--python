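"""Triangle-mesh data model, I/O, validation and statistics.

All geometry in this package is expressed in millimetres in a right-handed
world frame; meshes carry no unit metadata.  Solver modules convert to SI
internally.  A conductor boundary must be a closed, consistently wound
2-manifold whose face normals point away from the enclosed region;
evaluation surfaces may be open.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import trimesh as _trimesh

__all__ = [
    "TriMesh",
    "MeshStats",
    "MeshValidation",
    "MeshFormatError",
    "read_mesh",
    "write_mesh",
    "validate_mesh",
    "mesh_statistics",
    "weld_vertices",
]

#: vertices closer than this (mm) are considered duplicates
WELD_TOLERANCE = 1e-9


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be interpreted as a triangle mesh."""


@dataclasses.dataclass
class TriMesh:
    """Indexed triangle surface.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array, 0-based vertex indices
    label : optional surface role (``body``, ``skull``, ``eyes``, ``evaluation``)
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshFormatError("faces must be triangles (m, 3)")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    # -- derived quantities -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_normals(self, unit: bool = True) -> np.ndarray:
        t = self.triangles()
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        if unit:
            nn = np.linalg.norm(n, axis=1, keepdims=True)
            nn[nn == 0] = 1.0
            n = n / nn
        return n

    def face_areas(self) -> np.ndarray:
        t = self.triangles()
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    def face_centroids(self) -> np.ndarray:
        return self.triangles().mean(axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def signed_volume(self) -> float:
        """Signed enclosed volume (mm^3); positive for outward orientation."""
        t = self.triangles()
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def edges_unique(self) -> np.ndarray:
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        return np.unique(np.sort(e, axis=1), axis=0)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges_unique()
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals (unit)."""
        fn = self.face_normals(unit=False)
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        nn = np.linalg.norm(vn, axis=1, keepdims=True)
        nn[nn == 0] = 1.0
        return vn / nn

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy(), self.label)

    def flipped(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces[:, ::-1].copy(), self.label)

    def as_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices, self.faces, process=False)


@dataclasses.dataclass(frozen=True)
class MeshStats:
    n_vertices: int
    n_faces: int
    mean_edge: float
    sd_edge: float
    total_area: float
    euler_characteristic: int


@dataclasses.dataclass(frozen=True)
class MeshValidation:
    closed: bool
    oriented: bool
    manifold: bool
    signed_volume: float
    boundary_edge_count: int
    defects: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.defects


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMATS = {".stl": "stl", ".off": "off", ".ply": "ply"}


def _format_for(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("stl", "off", "ply"):
            raise MeshFormatError(f"unsupported mesh format {fmt!r}")
        return fmt
    try:
        return _FORMATS[path.suffix.lower()]
    except KeyError:
        raise MeshFormatError(f"cannot infer mesh format from {path.name!r}") from None


def _read_off(path: Path) -> TriMesh:
    tokens: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.split())
    if not tokens or tokens[0] != "OFF":
        raise MeshFormatError(f"{path}: missing OFF header")
    pos = 1
    nv, nf = int(tokens[pos]), int(tokens[pos + 1])
    pos += 3  # skip edge count
    verts = np.array(tokens[pos : pos + 3 * nv], dtype=float).reshape(nv, 3)
    pos += 3 * nv
    faces = []
    for _ in range(nf):
        cnt = int(tokens[pos])
        if cnt != 3:
            raise MeshFormatError(f"{path}: non-triangular face with {cnt} vertices")
        faces.append([int(tokens[pos + 1]), int(tokens[pos + 2]), int(tokens[pos + 3])])
        pos += 1 + cnt
    return TriMesh(verts, np.array(faces, dtype=np.int64))


def _write_off(mesh: TriMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9f} {v[1]:.9f} {v[2]:.9f}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _check_ascii_ply_triangular(path: Path) -> None:
    # trimesh silently triangulates polygon faces; reject them instead for
    # ascii files, where the face valence is cheap to inspect.
    with open(path, "rb") as fh:
        header = fh.read(2048).decode("ascii", errors="replace")
    if "format ascii" not in header:
        return
    n_vert = n_face = 0
    for line in header.splitlines():
        parts = line.split()
        if parts[:2] == ["element", "vertex"]:
            n_vert = int(parts[2])
        elif parts[:2] == ["element", "face"]:
            n_face = int(parts[2])
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        start = lines.index("end_header") + 1
    except ValueError:
        return
    for line in lines[start + n_vert : start + n_vert + n_face]:
        parts = line.split()
        if parts and int(parts[0]) != 3:
            raise MeshFormatError(f"{path}: non-triangular PLY face")


def read_mesh(path: str | Path, fmt: str | None = None) -> TriMesh:
    """Read a triangle surface from STL, OFF or PLY.

    Coordinates are interpreted as millimetres.  Winding is taken as stored;
    call :func:`validate_mesh` to check orientation.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"mesh file not found: {path}")
    fmt = _format_for(path, fmt)
    if fmt == "off":
        return _read_off(path)
    if fmt == "ply":
        _check_ascii_ply_triangular(path)
    try:
        tm = _trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # pragma: no cover - backend specific
        raise MeshFormatError(f"could not parse {path}: {exc}") from exc
    if tm.faces.size and tm.faces.shape[1] != 3:
        raise MeshFormatError(f"{path}: non-triangular faces")
    mesh = TriMesh(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces, dtype=np.int64))
    if fmt == "stl":
        # STL stores a triangle soup; weld duplicated corner vertices
        mesh = weld_vertices(mesh)
    return mesh


def write_mesh(mesh: TriMesh, path: str | Path, fmt: str | None = None) -> Path:
    """Write ``mesh`` to STL/OFF/PLY (format from extension unless given)."""
    path = Path(path)
    fmt = _format_for(path, fmt)
    if fmt == "off":
        _write_off(mesh, path)
    else:
        mesh.as_trimesh().export(str(path), file_type=fmt)
    return path


# ---------------------------------------------------------------------------
# validation / statistics
# ---------------------------------------------------------------------------


def _edge_face_degree(faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e_sorted = np.sort(e, axis=1)
    uniq, counts = np.unique(e_sorted, axis=0, return_counts=True)
    return uniq, counts


def validate_mesh(mesh: TriMesh, require_closed: bool = True) -> MeshValidation:
    """Report-only validation of manifoldness, closedness and orientation.

    ``closed`` means every edge is shared by exactly two faces; ``oriented``
    means winding is consistent (each directed edge used once) and, for a
    closed mesh, the total signed volume is positive (outward normals).
    """
    defects: list[str] = []
    if mesh.n_faces == 0:
        return MeshValidation(False, False, False, 0.0, 0, ("empty mesh",))

    uniq, counts = _edge_face_degree(mesh.faces)
    manifold = bool((counts <= 2).all())
    boundary = int((counts == 1).sum())
    closed = manifold and boundary == 0
    if not manifold:
        defects.append(f"{int((counts > 2).sum())} non-manifold edges")
    if boundary and require_closed:
        defects.append(f"{boundary} boundary edges (surface not closed)")

    # consistent winding: no directed edge may appear twice
    de = np.concatenate([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]])
    _, d_counts = np.unique(de, axis=0, return_counts=True)
    consistent = bool((d_counts == 1).all())
    if not consistent:
        defects.append("inconsistent winding (repeated directed edge)")

    vol = mesh.signed_volume()
    oriented = consistent
    if closed and consistent and vol <= 0:
        oriented = False
        defects.append("signed volume <= 0 (normals point inward)")

    areas = mesh.face_areas()
    n_zero = int((areas < 1e-12).sum())
    if n_zero:
        defects.append(f"{n_zero} zero-area faces")

    return MeshValidation(closed, oriented, manifold, vol, boundary, tuple(defects))


def mesh_statistics(mesh: TriMesh) -> MeshStats:
    """Vertex/face counts, unique-edge length statistics, area and V-E+F."""
    if mesh.n_faces == 0 or mesh.n_vertices == 0:
        raise ValueError("mesh_statistics requires a non-empty mesh")
    lengths = mesh.edge_lengths()
    n_edges = len(lengths)
    return MeshStats(
        n_vertices=mesh.n_vertices,
        n_faces=mesh.n_faces,
        mean_edge=float(lengths.mean()),
        sd_edge=float(lengths.std()),
        total_area=mesh.area(),
        euler_characteristic=int(mesh.n_vertices - n_edges + mesh.n_faces),
    )


def weld_vertices(mesh: TriMesh, tol: float = WELD_TOLERANCE) -> TriMesh:
    """Merge vertices closer than ``tol`` mm and drop degenerate faces.

    First-occurrence vertex order is preserved.
    """
    key = np.round(mesh.vertices / max(tol, 1e-300)).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    verts = mesh.vertices[first[order]]
    faces = rank[inverse[mesh.faces]]
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 2] != faces[:, 0])
    )
    return TriMesh(verts, faces[ok], mesh.label)
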