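"""Figure-of-eight TMS coil as a magnetic-dipole quadrature.

Each winding turn is idealised as a planar circular loop; a loop of radius
``a`` is represented by azimuthal sample dipoles that together carry its
enclosed area ``pi a^2`` (area-turn weights, mm^2, signed per wing).  The
default coil follows a small commercial butterfly coil: two wings, three
layers of four turns each, inner/outer winding diameters 24/47 mm, 9 mm
wire stack starting 2 mm above the casing bottom, with dipole layers at
1.5, 4.5 and 7.5 mm above the lowermost wire surface.

Coil frame: origin at the centre of the coil face (bottom of casing), +z
away from the head, +x along the long (wing-to-wing) axis.  When placed on
a scalp at orientation angle 0 (the posterior-anterior reference), a
positive current rate-of-change induces a primary E-field along the PA
axis under the coil centre.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import TriMesh

__all__ = [
    "CoilSpec",
    "CoilModel",
    "CoilPlacement",
    "build_figure8_quadrature",
    "place_coil_tangential",
    "primary_efield",
    "DEFAULT_DIDT",
]

MU0 = 4e-7 * np.pi
#: default stimulator current rate of change, A/s (50 A/us)
DEFAULT_DIDT = 50e6


@dataclasses.dataclass(frozen=True)
class CoilSpec:
    """Winding geometry (mm) of a figure-of-eight coil."""

    inner_diameter: float = 24.0
    outer_diameter: float = 47.0
    stack_height: float = 9.0
    bottom_insulation: float = 2.0
    wings: int = 2
    layers: tuple[float, ...] = (1.5, 4.5, 7.5)  # heights above lowermost wire surface
    turns_per_layer: int = 4
    azimuthal_samples: int = 32  # on the outermost ring of each turn's disk
    radial_rings: int = 6  # radial subdivisions of each turn's enclosed disk

    def __post_init__(self) -> None:
        if self.inner_diameter >= self.outer_diameter:
            raise ValueError("inner diameter must be smaller than outer diameter")
        if any(h < 0 or h > self.stack_height for h in self.layers):
            raise ValueError("layer heights must lie within the wire stack")
        if self.azimuthal_samples < 8:
            raise ValueError("need at least 8 azimuthal samples per turn")
        if self.wings != 2:
            raise ValueError("only figure-of-eight (2-wing) coils are supported")

    @property
    def turn_radii(self) -> np.ndarray:
        return np.linspace(self.inner_diameter / 2.0, self.outer_diameter / 2.0, self.turns_per_layer)

    def wing_area(self) -> float:
        """Total area-turns of one wing (mm^2): sum of turn areas x layers."""
        return float(len(self.layers) * np.pi * (self.turn_radii**2).sum())

    def single_layer(self, height: float = 4.5) -> "CoilSpec":
        """Thin-winding simplification: the same turns (same total
        area-turns) all placed at one height mid-stack."""
        return dataclasses.replace(self, layers=(height,) * len(self.layers))


@dataclasses.dataclass
class CoilModel:
    """Magnetic-dipole quadrature with a rigid placement transform.

    positions (mm, coil frame), unit loop normals, signed area-turn weights
    (mm^2).  ``transform`` is a 4x4 rigid coil->world matrix.
    """

    positions: np.ndarray
    normals: np.ndarray
    weights: np.ndarray
    spec: CoilSpec
    transform: np.ndarray = dataclasses.field(default_factory=lambda: np.eye(4))

    def placed_positions(self) -> np.ndarray:
        return self.positions @ self.transform[:3, :3].T + self.transform[:3, 3]

    def placed_normals(self) -> np.ndarray:
        return self.normals @ self.transform[:3, :3].T

    @property
    def n_dipoles(self) -> int:
        return len(self.weights)

    def with_transform(self, transform: np.ndarray) -> "CoilModel":
        return CoilModel(self.positions, self.normals, self.weights, self.spec, transform)

    def export_csv(self, path) -> None:
        """Placed dipoles as x,y,z,nx,ny,nz,w (mm, mm^2)."""
        data = np.hstack(
            [self.placed_positions(), self.placed_normals(), self.weights[:, None]]
        )
        header = "x,y,z,nx,ny,nz,w"
        np.savetxt(path, data, delimiter=",", header=header, comments="")

    def export_vtk(self, path) -> None:
        """Placed dipole cloud as a VTK point set for display."""
        from .vtkio import write_vtk_points

        write_vtk_points(
            self.placed_positions(),
            path,
            {"weight": self.weights, "normal": self.placed_normals()},
        )


@dataclasses.dataclass(frozen=True)
class CoilPlacement:
    """Tangential placement on a scalp surface."""

    position: np.ndarray  # mm, point on scalp
    angle_deg: float  # 0 = posterior-anterior
    normal: np.ndarray  # outward unit scalp normal

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        ln = np.linalg.norm(n)
        if not np.isfinite(ln) or ln < 1e-12:
            raise ValueError("degenerate scalp normal")
        object.__setattr__(self, "normal", n / ln)
        object.__setattr__(self, "angle_deg", float(self.angle_deg) % 360.0)


#: world-frame posterior->anterior axis used as the 0-degree reference
PA_AXIS = np.array([1.0, 0.0, 0.0])


def build_figure8_quadrature(spec: CoilSpec = CoilSpec()) -> CoilModel:
    """Dipole quadrature of the figure-of-eight coil in the coil frame.

    A current loop is magnetically equivalent to a uniform dipole density
    over any spanning surface; each turn is therefore represented by
    quadrature points over its enclosed disk (area-weighted radial rings,
    azimuthal samples proportional to ring radius), which keeps the
    near-field accurate — concentrating the whole disk area on the wire
    circle itself misestimates the field at head distances by tens of
    percent.  Wing centres sit at +-(outer radius) on the x axis; the two
    wings wind in opposite senses so their signed weights cancel in total.
    """
    r_out = spec.outer_diameter / 2.0
    pos, nrm, wgt = [], [], []
    for wing_sign, x0 in ((+1.0, +r_out), (-1.0, -r_out)):
        for h in spec.layers:
            z = spec.bottom_insulation + h
            for a in spec.turn_radii:
                edges = np.linspace(0.0, a, spec.radial_rings + 1)
                for i in range(spec.radial_rings):
                    rc = 0.5 * (edges[i] + edges[i + 1])
                    ring_area = np.pi * (edges[i + 1] ** 2 - edges[i] ** 2)
                    # even counts keep the dipole cloud 180-degree symmetric
                    n_phi = max(6, 2 * int(round(spec.azimuthal_samples * rc / (2 * a))))
                    w = wing_sign * ring_area / n_phi
                    for phi in 2.0 * np.pi * np.arange(n_phi) / n_phi:
                        pos.append([x0 + rc * np.cos(phi), rc * np.sin(phi), z])
                        nrm.append([0.0, 0.0, 1.0])
                        wgt.append(w)
    return CoilModel(
        np.asarray(pos), np.asarray(nrm), np.asarray(wgt), spec, np.eye(4)
    )


def _tangent_frame(normal: np.ndarray, reference: np.ndarray = PA_AXIS) -> tuple[np.ndarray, np.ndarray]:
    """In-plane PA direction and its orthogonal complement on the scalp."""
    t = reference - (reference @ normal) * normal
    ln = np.linalg.norm(t)
    if ln < 1e-8:
        # coil directly over a pole of the reference axis: fall back to +y
        t = np.array([0.0, 1.0, 0.0]) - (normal[1]) * normal
        ln = np.linalg.norm(t)
    t = t / ln
    return t, np.cross(normal, t)


def place_coil_tangential(
    coil: CoilModel, placement: CoilPlacement, standoff: float = 0.0
) -> CoilModel:
    """Rigidly place the coil tangentially on the scalp.

    The coil face (z=0 plane of the coil frame) is orthogonal to the scalp
    normal at ``position + standoff * normal``; the orientation angle is
    measured in the tangent plane from the PA reference direction.  At
    angle 0 the induced primary E-field under the coil centre points along
    the PA axis (for positive dI/dt).
    """
    n = placement.normal
    pa, left = _tangent_frame(n)
    ang = np.deg2rad(placement.angle_deg)
    # E under the centre of a figure-8 is along the central current segment,
    # i.e. along the coil-frame +y axis; rotate so that +y maps to the
    # requested field direction.
    e_dir = np.cos(ang) * pa + np.sin(ang) * left
    x_axis = np.cross(e_dir, n)  # long axis
    x_axis /= np.linalg.norm(x_axis)
    rot = np.column_stack([x_axis, e_dir, n])
    tf = np.eye(4)
    tf[:3, :3] = rot
    tf[:3, 3] = placement.position + standoff * n
    return coil.with_transform(tf)


def primary_efield(
    coil: CoilModel, dIdt: float, points: np.ndarray, min_distance: float = 1e-6
) -> np.ndarray:
    """Infinite-homogeneous-medium (primary) E-field, V/m.

    E(r) = -(mu0/4pi) dI/dt sum_k w_k n_k x (r - r_k) / |r - r_k|^3,
    with positions converted to metres and weights to m^2 internally.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float)) * 1e-3
    rk = coil.placed_positions() * 1e-3
    nk = coil.placed_normals()
    wk = coil.weights * 1e-6
    E = np.zeros((len(pts), 3))
    for k in range(len(rk)):
        d = pts - rk[k]
        r = np.linalg.norm(d, axis=1)
        if (r < min_distance * 1e-3).any():
            raise ValueError(f"evaluation point coincides with coil dipole {k}")
        E += wk[k] * np.cross(np.broadcast_to(nk[k], d.shape), d) / r[:, None] ** 3
    return -(MU0 / (4 * np.pi)) * dIdt * E


def scalp_placement(scalp: TriMesh, position: np.ndarray, angle_deg: float) -> CoilPlacement:
    """Snap a nominal position onto the scalp and build a placement there."""
    from .proximity import SurfaceDistance

    sd = SurfaceDistance(scalp)
    p = sd.project(np.atleast_2d(position))[0]
    vn = scalp.vertex_normals()
    # normal of the nearest vertex (smooth enough for placement purposes)
    from scipy.spatial import cKDTree

    idx = cKDTree(scalp.vertices).query(p)[1]
    return CoilPlacement(p, angle_deg, vn[idx])
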