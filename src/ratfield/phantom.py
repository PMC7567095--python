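"""Synthetic rat-head phantoms: geometry and CT volumes.

The phantom stands in for a high-resolution small-animal CT acquisition and
reproduces the structural features the modelling pipeline relies on:

* an oblong body/head outline (prolate ellipsoid, default semi-axes
  30 x 16 x 14 mm — the "front half" of an adult rat);
* a thin skull shell (0.7 mm) just inside the scalp, realised as ONE closed
  surface bounding the bone volume, with large holes (posterior foramen
  magnum and two anterolateral orbital openings) realised as cut-outs whose
  rims connect the inner and outer shell sheets;
* an evaluation ("cortex") surface at least 1 mm inside the inner skull
  sheet, where induced fields are computed;
* synthetic CT with the three-mode Hounsfield histogram (air/soft/bone)
  that the threshold-based segmentation recipe expects.

World frame: +x anterior (nose), +y left, +z dorsal; origin at the body
centre.  All phantom generation is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage import measure

from ._kernels import voxelize_parity
from .geometry import TriMesh, validate_mesh, weld_vertices
from .model import (
    SIGMA_BODY,
    SIGMA_SKULL,
    BoundarySurface,
    CompartmentModel,
    body_with_floating_skull,
)
from .remesh import remesh_to_target_edge
from .volume import CTVolume

__all__ = [
    "PhantomSpec",
    "SkullHole",
    "make_icosphere",
    "ellipsoid_mesh",
    "make_concentric_spheres_model",
    "make_rat_phantom",
    "synthesize_ct",
    "phantom_masks",
    "HU_AIR",
    "HU_SOFT",
    "HU_BONE",
]

HU_AIR = -1000.0
HU_SOFT = 40.0
HU_BONE = 1500.0


# ---------------------------------------------------------------------------
# icosphere / ellipsoid primitives
# ---------------------------------------------------------------------------

def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return v, f


def make_icosphere(radius: float, subdivisions: int, center=(0.0, 0.0, 0.0)) -> TriMesh:
    """Closed, outward-oriented icosphere; vertices at ``radius`` exactly.

    Subdivision ``s`` gives ``10*4**s + 2`` vertices and ``20*4**s`` faces.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    verts, faces = _icosahedron()
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}
        vlist = [v for v in verts]

        def midpoint(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key in cache:
                return cache[key]
            m = vlist[a] + vlist[b]
            m /= np.linalg.norm(m)
            vlist.append(m)
            cache[key] = len(vlist) - 1
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab = midpoint(a, b)
            bc = midpoint(b, c)
            ca = midpoint(c, a)
            new_faces.extend([(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)])
        verts = np.array(vlist)
        faces = np.array(new_faces, dtype=np.int64)
    verts = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    return TriMesh(verts * radius + np.asarray(center, dtype=float), faces)


def _ellipsoid_radius(dirs: np.ndarray, axes: np.ndarray) -> np.ndarray:
    """Radial distance to the ellipsoid surface along unit directions."""
    return 1.0 / np.sqrt(((dirs / axes) ** 2).sum(axis=1))


def ellipsoid_mesh(
    semi_axes,
    target_edge: float | None = None,
    subdivisions: int | None = None,
    center=(0.0, 0.0, 0.0),
    label: str | None = None,
) -> TriMesh:
    """Closed ellipsoid surface from a radially mapped icosphere.

    If ``target_edge`` is given the mesh is remeshed isotropically to that
    mean edge length; otherwise the raw mapped icosphere is returned.
    """
    axes = np.asarray(semi_axes, dtype=float)
    if (axes <= 0).any():
        raise ValueError("semi-axes must be positive")
    r_mean = float(axes.mean())
    if subdivisions is None:
        edge = target_edge if target_edge else r_mean * 0.07
        subdivisions = int(np.clip(round(np.log2(1.0515 * r_mean / edge)), 0, 7))
    sph = make_icosphere(1.0, subdivisions)
    dirs = sph.vertices
    verts = dirs * _ellipsoid_radius(dirs, axes)[:, None]
    mesh = TriMesh(verts + np.asarray(center, dtype=float), sph.faces, label)
    if target_edge is not None:
        mesh = remesh_to_target_edge(mesh, target_edge, feature_check=False)
        mesh.label = label
    return mesh


def ellipsoid_normals(points: np.ndarray, axes: np.ndarray) -> np.ndarray:
    """Outward unit normals of an origin-centred ellipsoid at surface points."""
    n = points / axes**2
    return n / np.linalg.norm(n, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# concentric spheres (oracle geometry)
# ---------------------------------------------------------------------------

def make_concentric_spheres_model(
    radii, conductivities, subdivisions: int = 4, center=(0.0, 0.0, 0.0)
) -> CompartmentModel:
    """Nested spherical conductor model (radii outer->inner, mm).

    ``conductivities[i]`` is the conductivity of the region directly inside
    surface ``i`` (the last entry is the innermost region); outside the
    outermost surface is air.
    """
    radii = [float(r) for r in np.atleast_1d(radii)]
    cond = [float(c) for c in np.atleast_1d(conductivities)]
    if len(cond) != len(radii):
        raise ValueError("need one conductivity per enclosed region (= one per surface)")
    if any(r2 >= r1 for r1, r2 in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly decreasing outer->inner")
    surfaces = []
    for i, r in enumerate(radii):
        mesh = make_icosphere(r, subdivisions, center)
        mesh.label = "body" if i == 0 else f"shell{i}"
        sigma_out = 0.0 if i == 0 else cond[i - 1]
        surfaces.append(BoundarySurface(mesh, cond[i], sigma_out))
    return CompartmentModel(surfaces)


# ---------------------------------------------------------------------------
# rat phantom
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SkullHole:
    """Spherical-cap cut-out of the skull shell."""

    direction: tuple[float, float, float]
    angular_radius_deg: float

    def unit(self) -> np.ndarray:
        d = np.asarray(self.direction, dtype=float)
        return d / np.linalg.norm(d)


def _default_holes() -> tuple[SkullHole, ...]:
    return (
        SkullHole((-1.0, 0.0, -0.15), 12.0),   # posterior foramen (brainstem exit)
        SkullHole((0.75, 0.6, -0.1), 10.0),    # left orbital opening
        SkullHole((0.75, -0.6, -0.1), 10.0),   # right orbital opening
    )


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Geometry and discretisation of the synthetic rat head.

    Lengths in mm.  The skull is an ellipsoidal shell of thickness
    ``skull_thickness`` occupying the anterior-dorsal part of the body
    outline, so that (as in a real rat) the cranial crown lies
    ``skull_offset`` below the scalp while a large conductive body volume
    continues behind the posterior foramen — the current path that makes
    skull holes matter.  ``eval_margin`` is the minimum depth of the
    evaluation (cortex) surface below the inner skull sheet.
    """

    body_semiaxes: tuple[float, float, float] = (30.0, 16.0, 14.0)
    skull_center: tuple[float, float, float] = (6.0, 0.0, 2.5)
    skull_semiaxes: tuple[float, float, float] = (18.0, 12.0, 10.0)
    skull_offset: float = 1.5
    skull_thickness: float = 0.7
    holes: tuple[SkullHole, ...] = dataclasses.field(default_factory=_default_holes)
    eval_margin: float = 1.0
    body_edge: float = 1.4
    skull_edge: float = 0.67
    eval_subdivisions: int = 4
    grid_spacing: float = 0.2  # implicit-surface sampling for the skull
    spine: bool = False
    spine_radius: float = 4.0
    spine_length: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.skull_thickness <= 0:
            raise ValueError("skull thickness must be positive")
        if self.eval_margin < 0:
            raise ValueError("evaluation margin must be >= 0")
        dirs = [h.unit() for h in self.holes]
        radii = [np.deg2rad(h.angular_radius_deg) for h in self.holes]
        for i in range(len(dirs)):
            for j in range(i + 1, len(dirs)):
                sep = np.arccos(np.clip(dirs[i] @ dirs[j], -1, 1))
                if sep < radii[i] + radii[j]:
                    raise ValueError("skull holes overlap")
        # the skull shell must stay inside the body outline
        c = np.asarray(self.skull_center)
        ax = np.asarray(self.skull_semiaxes)
        probes = c + np.vstack([np.diag(ax), -np.diag(ax)])
        rho = np.sqrt(((probes / np.asarray(self.body_semiaxes)) ** 2).sum(axis=1))
        if (rho >= 1.0).any():
            raise ValueError("skull shell extends outside the body surface")

    @property
    def skull_outer_axes(self) -> np.ndarray:
        return np.asarray(self.skull_semiaxes, dtype=float)

    @property
    def skull_inner_axes(self) -> np.ndarray:
        return self.skull_outer_axes - self.skull_thickness

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["holes"] = [
            {"direction": list(h.direction), "angular_radius_deg": h.angular_radius_deg}
            for h in self.holes
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "holes" in d:
            d["holes"] = tuple(
                SkullHole(tuple(h["direction"]), h["angular_radius_deg"]) for h in d["holes"]
            )
        for key in ("body_semiaxes", "skull_center", "skull_semiaxes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _skull_field(points: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Implicit bone field: negative inside the bone shell (pseudo-distance, mm).

    The shell is the set within half a thickness of the mid-sheet ellipsoid
    (first-order signed distance, so the thickness is uniform along the
    true surface normal).  Each hole removes a spherical-cap region; its
    rim is the half-torus of revolution around the hole-edge circle, which
    keeps full bone thickness up to the edge, joins the two sheets
    tangentially, and is everywhere convex — so the segmentation recipe's
    morphological closure leaves it unchanged.
    """
    rel = points - np.asarray(spec.skull_center)
    half_t = spec.skull_thickness / 2.0
    ax_mid = spec.skull_outer_axes - half_t
    rho = np.sqrt(((rel / ax_mid) ** 2).sum(axis=1))
    grad = np.sqrt((rel**2 / ax_mid**4).sum(axis=1))
    d_mid = (rho - 1.0) * rho / np.maximum(grad, 1e-12)
    f = np.abs(d_mid) - half_t
    r = np.linalg.norm(rel, axis=1)
    r = np.where(r == 0, 1e-12, r)
    dirs = rel / r[:, None]
    for hole in spec.holes:
        ang = np.arccos(np.clip(dirs @ hole.unit(), -1.0, 1.0))
        # signed arc distance beyond the hole edge (negative inside the hole)
        a = (ang - np.deg2rad(hole.angular_radius_deg)) * r
        g = np.sqrt(np.minimum(a, 0.0) ** 2 + d_mid**2) - half_t
        f = np.maximum(f, g)
    if spec.spine:
        f = np.minimum(f, _spine_field(points, spec))
    return f


def _spine_field(points: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Hollow posterior tube (spinal canal wall) joined to the skull shell."""
    c = np.asarray(spec.skull_center)
    hole_dir = spec.holes[0].unit() if spec.holes else np.array([-1.0, 0.0, 0.0])
    # tube axis through the posterior foramen
    exit_pt = c + hole_dir * _ellipsoid_radius(hole_dir[None, :], spec.skull_outer_axes)[0]
    x0 = exit_pt[0]
    x1 = x0 - spec.spine_length
    rad = np.sqrt((points[:, 1] - exit_pt[1]) ** 2 + (points[:, 2] - exit_pt[2]) ** 2)
    wall = np.abs(rad - (spec.spine_radius - spec.skull_thickness / 2)) - spec.skull_thickness / 2
    xclip = np.maximum(points[:, 0] - x0, x1 - points[:, 0])
    return np.maximum(wall, xclip)


def _mesh_from_implicit(
    field_fn, bounds_lo, bounds_hi, spacing: float, label: str | None = None
) -> TriMesh:
    lo = np.asarray(bounds_lo, dtype=float)
    hi = np.asarray(bounds_hi, dtype=float)
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    xs = [lo[d] + spacing * np.arange(shape[d]) for d in range(3)]
    grid = np.stack(np.meshgrid(*xs, indexing="ij"), axis=-1).reshape(-1, 3)
    vals = field_fn(grid).reshape(shape)
    verts, faces, _, _ = measure.marching_cubes(vals, level=0.0, spacing=(spacing,) * 3)
    verts = verts + lo
    mesh = weld_vertices(TriMesh(verts, faces.astype(np.int64), label), tol=1e-7)
    mesh = _drop_speck_components(mesh)
    if mesh.signed_volume() < 0:
        mesh = mesh.flipped()
    return mesh


def _drop_speck_components(mesh: TriMesh, min_area_fraction: float = 0.01) -> TriMesh:
    """Remove negligible connected components (numerical specks of the
    implicit sampling); genuine sheets are orders of magnitude larger."""
    import scipy.sparse as sp

    e = np.concatenate(
        [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
    )
    adj = sp.coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(mesh.n_vertices,) * 2
    )
    ncomp, lab = sp.csgraph.connected_components(adj, directed=False)
    if ncomp <= 1:
        return mesh
    areas = np.zeros(ncomp)
    fl = lab[mesh.faces[:, 0]]
    np.add.at(areas, fl, mesh.face_areas())
    keep_labels = np.nonzero(areas >= min_area_fraction * areas.sum())[0]
    keep = np.isin(fl, keep_labels)
    out = TriMesh(mesh.vertices, mesh.faces[keep], mesh.label)
    # compact unused vertices
    used = np.unique(out.faces)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriMesh(out.vertices[used], remap[out.faces], mesh.label)


_PHANTOM_CACHE: dict[PhantomSpec, tuple] = {}


def make_rat_phantom(
    spec: PhantomSpec = PhantomSpec(),
) -> tuple[CompartmentModel, TriMesh, TriMesh]:
    """Build the synthetic two-compartment rat head.

    Returns ``(model, evaluation_surface, scalp)``: the volume-conductor
    model (body outline + floating skull-with-holes), the cortical
    evaluation surface and the scalp mesh used for coil placement (the same
    mesh as the model's body surface).  Generation is deterministic, so
    repeated builds of the same spec are served from a cache (as copies).
    """
    if spec in _PHANTOM_CACHE:
        body_c, skull_c, eval_c = _PHANTOM_CACHE[spec]
        body, skull, ev = body_c.copy(), skull_c.copy(), eval_c.copy()
        model = body_with_floating_skull(body, skull, SIGMA_BODY, SIGMA_SKULL)
        return model, ev, body
    body = ellipsoid_mesh(spec.body_semiaxes, target_edge=spec.body_edge, label="body")

    pad = 3.0 * spec.grid_spacing
    ax_out = spec.skull_outer_axes
    c = np.asarray(spec.skull_center)
    lo = c - (ax_out + pad)
    hi = c + (ax_out + pad)
    if spec.spine:
        lo[0] -= spec.spine_length + 2 * pad
    skull = _mesh_from_implicit(
        lambda p: _skull_field(p, spec), lo, hi, spec.grid_spacing, label="skull"
    )
    skull = remesh_to_target_edge(skull, spec.skull_edge, feature_check=False)
    skull.label = "skull"

    rep = validate_mesh(skull, require_closed=True)
    if not rep.closed or not rep.oriented:
        raise RuntimeError(f"phantom skull surface invalid: {rep.defects}")

    eval_surface = _evaluation_surface(spec)
    model = body_with_floating_skull(body, skull, SIGMA_BODY, SIGMA_SKULL)
    model.validate()
    _PHANTOM_CACHE[spec] = (body.copy(), skull.copy(), eval_surface.copy())
    return model, eval_surface, body


#: extra inward offset absorbing faceting error of the skull mesh
_EVAL_GUARD = 0.1


def _evaluation_surface(spec: PhantomSpec) -> TriMesh:
    """Cortex surface: inner skull sheet offset inward along its normals."""
    axes = spec.skull_inner_axes
    sph = make_icosphere(1.0, spec.eval_subdivisions)
    pts = sph.vertices * _ellipsoid_radius(sph.vertices, axes)[:, None]
    normals = ellipsoid_normals(pts, axes)
    offset = spec.eval_margin + _EVAL_GUARD
    verts = pts - offset * normals + np.asarray(spec.skull_center)
    return TriMesh(verts, sph.faces, label="evaluation")


# ---------------------------------------------------------------------------
# ground-truth masks and CT synthesis
# ---------------------------------------------------------------------------

def _grid_axes(ct: CTVolume) -> np.ndarray:
    nx, ny, nz = ct.data.shape
    return np.stack(
        np.meshgrid(
            ct.voxel_centres_axis(0),
            ct.voxel_centres_axis(1),
            ct.voxel_centres_axis(2),
            indexing="ij",
        ),
        axis=-1,
    ).reshape(-1, 3)


def phantom_masks(spec: PhantomSpec, ct: CTVolume) -> dict[str, np.ndarray]:
    """Exact ground-truth masks of the phantom on a CT grid.

    ``brain`` is the intracranial cavity (inside the inner skull sheet);
    computed from the implicit geometry, not from the meshes.
    """
    pts = _grid_axes(ct)
    shape = ct.data.shape
    rho_body = np.sqrt(((pts / np.asarray(spec.body_semiaxes)) ** 2).sum(axis=1))
    body = (rho_body < 1.0).reshape(shape)
    bone = (_skull_field(pts, spec) < 0.0).reshape(shape)
    rel = pts - np.asarray(spec.skull_center)
    rho_in = np.sqrt(((rel / spec.skull_inner_axes) ** 2).sum(axis=1))
    brain = (rho_in < 1.0).reshape(shape)
    return {"body": body, "bone": bone, "brain": brain}


def synthesize_ct(
    model: CompartmentModel,
    spacing: float = 0.17,
    noise_sd: float = 0.0,
    seed: int = 0,
    padding: float = 2.0,
    hu_values: dict[str, float] | None = None,
) -> CTVolume:
    """Voxelize a compartment model into a synthetic CT (Hounsfield units).

    Voxels are assigned by surface containment (air outside the outermost
    surface, soft tissue inside it, bone inside any surface labelled
    ``skull``), then i.i.d. Gaussian noise of ``noise_sd`` HU is added with
    the given seed.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    hu = {"air": HU_AIR, "body": HU_SOFT, "skull": HU_BONE}
    if hu_values:
        hu.update(hu_values)

    all_v = np.vstack([s.mesh.vertices for s in model.surfaces])
    lo = all_v.min(axis=0) - padding
    hi = all_v.max(axis=0) + padding
    # tiny irrational shift so grid lines never hit mesh vertices exactly
    lo = lo - spacing * 0.0137
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    nx, ny, nz = (int(s) for s in shape)

    vol = np.full((nx, ny, nz), hu["air"], dtype=np.float32)
    outer = model.surfaces[0].mesh
    inside_outer = voxelize_parity(outer.vertices, outer.faces, lo, spacing, nx, ny, nz)
    vol[inside_outer] = hu["body"]
    for s in model.surfaces[1:]:
        key = s.mesh.label or "skull"
        if key not in hu:
            continue
        m = voxelize_parity(s.mesh.vertices, s.mesh.faces, lo, spacing, nx, ny, nz)
        vol[m] = hu[key]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, noise_sd, size=vol.shape).astype(np.float32)
    return CTVolume(vol, spacing, lo)
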