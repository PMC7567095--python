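"""Linear-collocation boundary-element solver for piecewise-homogeneous
conductors, and the reciprocity-based TMS E-field.

Surface potential.  For a current dipole ``p`` at ``r_p`` inside a
piecewise-homogeneous conductor, the potential on the boundaries satisfies

    sigma_k^- phi(r) - (1/4pi) sum_j (sigma_j^- - sigma_j^+)
        integral over S_j of phi(r') dOmega_r(r')  =  s(r),
    s(r) = (1/4pi) p . (r - r_p) / |r - r_p|^3,

with ``dOmega`` the solid-angle kernel and the equation taken in the
interior limit; the own-surface diagonal is fixed by the solid-angle
closure condition (row sum 4pi from inside), which makes the constant
vector an exact null vector for the insulated outermost surface.  The
null space is removed by rank-one deflation; the remaining gauge constant
does not affect any magnetic or electric output.

Magnetic field.  Geselowitz: B = B_inf - (mu0/4pi) sum_j
(sigma_j^- - sigma_j^+) integral of phi n x (r_s - r')/|r_s - r'|^3 dS'
(equivalently + with the kernel written n x (r' - r_s)).

E-field by reciprocity.  E_i(r) = -dI/dt * Phi_i(r) where Phi_i is the
coil flux of a unit dipole e_i at r.  Phi is linear in phi, so with the
flux functional ``a`` (Geselowitz surface term evaluated at the coil
quadrature) one adjoint solve x = A^-T a per coil placement yields
Phi_i = Phi_inf,i + x . s_i for every evaluation dipole — algebraically
identical to solving the three unit-dipole problems per point.

Internally SI units (m, S/m, T, V/m); the public mesh interface stays in mm.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from ._kernels import coil_flux_face_weights, double_layer_block
from .coil import MU0, CoilModel, primary_efield
from .model import CompartmentModel
from .proximity import SurfaceDistance

__all__ = [
    "BemSystem",
    "PotentialSolution",
    "assemble_double_layer",
    "build_deflated_system",
    "solve_surface_potentials",
    "geselowitz_bfield",
    "bem_efield",
    "StabilityError",
]

FOUR_PI = 4.0 * np.pi


class StabilityError(ValueError):
    """Source or evaluation point too close to a conductivity boundary."""


@dataclasses.dataclass
class PotentialSolution:
    """Potential (V) at every stacked surface vertex, gauge-arbitrary."""

    phi: np.ndarray


@dataclasses.dataclass
class BemSystem:
    model: CompartmentModel
    matrix: np.ndarray | None  # collocation matrix before factorisation
    offsets: np.ndarray  # vertex offset of each surface in the stacking
    mean_edges: np.ndarray  # mm, per surface
    deflated: bool = False
    lu: tuple | None = None
    _distance_queries: list | None = None

    @property
    def n(self) -> int:
        return int(self.offsets[-1])

    def vertices_mm(self) -> np.ndarray:
        return np.vstack([s.mesh.vertices for s in self.model.surfaces])

    def distance_queries(self) -> list[SurfaceDistance]:
        if self._distance_queries is None:
            self._distance_queries = [SurfaceDistance(s.mesh) for s in self.model.surfaces]
        return self._distance_queries

    def check_source_margin(self, points_mm: np.ndarray, factor: float = 0.5) -> None:
        """Sources/eval points must keep >= factor*mean_edge from every surface."""
        pts = np.atleast_2d(points_mm)
        for sd, edge, s in zip(
            self.distance_queries(), self.mean_edges, self.model.surfaces
        ):
            d = sd.distance(pts)
            bad = np.nonzero(d < factor * edge)[0]
            if len(bad):
                raise StabilityError(
                    f"point {bad[0]} is {d[bad[0]]:.2f} mm from surface "
                    f"'{s.mesh.label}' (< {factor * edge:.2f} mm stability margin)"
                )


def assemble_double_layer(model: CompartmentModel) -> BemSystem:
    """Assemble the (undeflated) linear-collocation matrix.

    All surfaces are validated closed and outward-oriented first.  The
    own-surface diagonal is set by the interior solid-angle closure, so a
    constant potential is an exact null vector of the assembled operator.
    """
    model.validate()
    meshes = [s.mesh for s in model.surfaces]
    sizes = [m.n_vertices for m in meshes]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    n = int(offsets[-1])
    colloc = np.vstack([m.vertices for m in meshes])
    mean_edges = np.array([m.edge_lengths().mean() for m in meshes])

    A = np.zeros((n, n))
    for j, s in enumerate(model.surfaces):
        lo, hi = int(offsets[j]), int(offsets[j + 1])
        block = A[:, lo:hi]
        double_layer_block(colloc, s.mesh.vertices, s.mesh.faces, block)
        # closure: from the interior side, the own-surface solid angle is 4pi
        rows = np.arange(lo, hi)
        rowsum = block[rows, :].sum(axis=1)
        block[rows, rows - lo] += FOUR_PI - rowsum
        block *= -s.jump / FOUR_PI
    sigma_minus = np.concatenate(
        [np.full(sz, s.sigma_in) for sz, s in zip(sizes, model.surfaces)]
    )
    A[np.arange(n), np.arange(n)] += sigma_minus
    return BemSystem(model, A, offsets, mean_edges)


def build_deflated_system(system: BemSystem) -> BemSystem:
    """Remove the constant null space by rank-one deflation and factorise."""
    if system.matrix is None:
        raise ValueError("system already factorised")
    A = system.matrix
    alpha = float(np.abs(np.diag(A)).mean())
    A += alpha / A.shape[0]  # alpha * (1 1^T)/N
    lu = lu_factor(A, overwrite_a=True, check_finite=False)
    return BemSystem(
        system.model,
        None,
        system.offsets,
        system.mean_edges,
        deflated=True,
        lu=lu,
        _distance_queries=system._distance_queries,
    )


def _source_vector(system: BemSystem, moment: np.ndarray, position_mm) -> np.ndarray:
    rv = system.vertices_mm() * 1e-3
    rp = np.asarray(position_mm, dtype=float) * 1e-3
    d = rv - rp
    r3 = np.linalg.norm(d, axis=1) ** 3
    return (d @ np.asarray(moment, dtype=float)) / (FOUR_PI * r3)


def solve_surface_potentials(
    system: BemSystem, moment: np.ndarray, position_mm, check_margin: bool = True
) -> PotentialSolution:
    """Surface potentials of one current dipole (A*m) at ``position_mm``."""
    if system.lu is None:
        raise ValueError("call build_deflated_system first")
    if check_margin:
        system.check_source_margin(np.atleast_2d(position_mm))
    s = _source_vector(system, moment, position_mm)
    phi = lu_solve(system.lu, s, check_finite=False)
    return PotentialSolution(phi)


def _bary_centroids(depth: int) -> np.ndarray:
    """Barycentric centroids of the uniform 4**depth triangle subdivision."""
    k = 1 << depth
    pts = []
    for i in range(k):
        for j in range(k - i):
            pts.append(((i + 1.0 / 3.0) / k, (j + 1.0 / 3.0) / k))
            if j < k - i - 1:
                pts.append(((i + 2.0 / 3.0) / k, (j + 2.0 / 3.0) / k))
    uv = np.asarray(pts)
    return np.column_stack([1.0 - uv[:, 0] - uv[:, 1], uv[:, 0], uv[:, 1]])


def _surface_quadrature(mesh, phi_vertices, depth: int):
    """Quadrature points/values of a linear field over the surface (SI).

    Returns (qpts (F,Q,3) m, qphi (F,Q), weights (F,Q) m^2, normals (F,3)).
    Exact for the linear basis; the kernel is sampled at 4**depth centroids
    per triangle, giving second-order accuracy at sub-triangle scale.
    """
    bary = _bary_centroids(depth)
    tri = mesh.triangles() * 1e-3
    areas = mesh.face_areas() * 1e-6
    normals = mesh.face_normals()
    phif = phi_vertices[mesh.faces]
    qpts = np.einsum("qk,fkc->fqc", bary, tri)
    qphi = phif @ bary.T
    w = np.repeat(areas[:, None] / len(bary), len(bary), axis=1)
    return qpts, qphi, w, normals


def geselowitz_bfield(
    model: CompartmentModel,
    solution: PotentialSolution,
    moment: np.ndarray,
    position_mm,
    field_point_mm,
    quad_depth: int = 2,
) -> np.ndarray:
    """Magnetic field (T) outside the conductor for a solved dipole source.

    ``quad_depth`` controls the surface quadrature of the Geselowitz
    integral (4**depth kernel samples per triangle, linear basis exact).
    """
    rs = np.asarray(field_point_mm, dtype=float) * 1e-3
    rp = np.asarray(position_mm, dtype=float) * 1e-3
    q = np.asarray(moment, dtype=float)
    d = rs - rp
    B = MU0 / FOUR_PI * np.cross(q, d) / np.linalg.norm(d) ** 3
    offset = 0
    for s in model.surfaces:
        mesh = s.mesh
        phi = solution.phi[offset : offset + mesh.n_vertices]
        offset += mesh.n_vertices
        if s.jump == 0.0:
            continue
        # the closed-surface integral of a constant vanishes analytically;
        # removing the mean makes that exact despite quadrature error
        # (gauge invariance to round-off)
        phi = phi - phi.mean()
        qpts, qphi, w, normals = _surface_quadrature(mesh, phi, quad_depth)
        dvec = rs - qpts
        r3 = np.linalg.norm(dvec, axis=2) ** 3
        kern = np.cross(np.broadcast_to(normals[:, None, :], dvec.shape), dvec) / r3[..., None]
        B = B - MU0 / FOUR_PI * s.jump * np.einsum("fq,fq,fqc->c", w, qphi, kern)
    return B


def _flux_functional(system: BemSystem, coil: CoilModel, quad_depth: int = 1) -> np.ndarray:
    """Vector a with Phi_surface = a . phi for the placed coil (SI)."""
    dip_pos = coil.placed_positions() * 1e-3
    dip_nrm = np.ascontiguousarray(coil.placed_normals())
    dip_w = coil.weights * 1e-6
    bary = _bary_centroids(quad_depth)
    a = np.zeros(system.n)
    offset = 0
    for s in system.model.surfaces:
        mesh = s.mesh
        nv = mesh.n_vertices
        if s.jump == 0.0:
            offset += nv
            continue
        areas = mesh.face_areas() * 1e-6
        normals = np.ascontiguousarray(mesh.face_normals())
        tri = mesh.triangles() * 1e-3
        qpts = np.einsum("qk,fkc->fqc", bary, tri)
        contrib = np.zeros(nv)
        for qi in range(len(bary)):
            g = coil_flux_face_weights(
                dip_pos, dip_nrm, dip_w, np.ascontiguousarray(qpts[:, qi]), normals
            )
            fw = -MU0 / FOUR_PI * s.jump * areas / len(bary) * g
            for k in range(3):
                np.add.at(contrib, mesh.faces[:, k], bary[qi, k] * fw)
        # gauge exactness: the functional must annihilate constant phi
        contrib -= contrib.mean()
        a[offset : offset + nv] = contrib
        offset += nv
    return a


def bem_efield(
    model: CompartmentModel,
    system: BemSystem,
    coil: CoilModel,
    dIdt: float,
    points_mm: np.ndarray,
    check_margin: bool = True,
    quad_depth: int = 1,
) -> np.ndarray:
    """Induced E-field (V/m) at evaluation points (mm) for a placed coil.

    Linear in dI/dt; exact superposition over coil dipoles.  Points must
    respect the stability margin to every conductivity boundary.
    """
    if system.lu is None:
        raise ValueError("call build_deflated_system first")
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    if check_margin:
        system.check_source_margin(pts)
    a = _flux_functional(system, coil, quad_depth)
    x = lu_solve(system.lu, a, trans=1, check_finite=False)
    E = primary_efield(coil, dIdt, pts)
    rv = system.vertices_mm() * 1e-3
    pts_m = pts * 1e-3
    chunk = 512
    for i0 in range(0, len(pts_m), chunk):
        p = pts_m[i0 : i0 + chunk]
        d = rv[None, :, :] - p[:, None, :]
        r3 = np.linalg.norm(d, axis=2) ** 3
        E[i0 : i0 + chunk] -= dIdt * np.einsum("v,pvc->pc", x, d / r3[..., None]) / FOUR_PI
    return E
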