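"""Closed-form TMS E-field in a spherically symmetric conductor.

The induced E-field is obtained by reciprocity with the magnetic forward
problem: the component of E along a unit direction at a cortical point
equals ``-dI/dt`` times the magnetic flux the coil would pick up from a
unit current dipole in that direction at that point.  In a spherically
symmetric conductor that flux follows from the closed-form external
magnetic field of a current dipole (Sarvas formula), which is independent
of the radial conductivity profile; radial dipoles are magnetically silent,
hence the induced E-field has no radial component.

The model is valid only for field points at radii smaller than the smallest
distance from the sphere origin to any coil dipole.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import least_squares

from .coil import MU0, CoilModel
from .geometry import TriMesh

__all__ = [
    "SphereModel",
    "fit_local_sphere",
    "sphere_magnetic_forward",
    "sphere_efield",
    "ValidityError",
]


class ValidityError(ValueError):
    """Field point outside the domain of validity of the spherical model."""


@dataclasses.dataclass
class SphereModel:
    origin: np.ndarray  # mm
    radius: float  # mm, fitted radius
    rms_residual: float = 0.0  # mm

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if self.radius <= 0:
            raise ValueError("fit radius must be positive")

    def validity_radius(self, coil: CoilModel) -> float:
        """Smallest origin-to-coil-dipole distance (mm)."""
        return float(
            np.linalg.norm(coil.placed_positions() - self.origin, axis=1).min()
        )


def fit_local_sphere(
    surface: TriMesh, region_center, region_radius: float
) -> SphereModel:
    """Least-squares sphere through the surface vertices near a region.

    Algebraic (linear) fit followed by geometric Levenberg-Marquardt
    refinement.  Raises on degenerate (nearly coplanar) patches.
    """
    c0 = np.asarray(region_center, dtype=float)
    pts = surface.vertices
    sel = np.linalg.norm(pts - c0, axis=1) <= region_radius
    pts = pts[sel]
    if len(pts) < 10:
        raise ValueError(f"only {len(pts)} vertices in fitting region; need >= 10")
    # coplanarity check via PCA thickness
    q = pts - pts.mean(axis=0)
    svals = np.linalg.svd(q, compute_uv=False)
    if svals[2] < 1e-9 * max(svals[0], 1.0):
        raise ValueError("fitting patch is coplanar; sphere fit is degenerate")

    # algebraic fit: |p|^2 = 2 c.p + (R^2 - |c|^2)
    A = np.hstack([2 * pts, np.ones((len(pts), 1))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("algebraic sphere fit failed (non-positive radius)")
    radius = float(np.sqrt(r2))

    def residuals(x):
        return np.linalg.norm(pts - x[:3], axis=1) - x[3]

    res = least_squares(residuals, np.append(center, radius), method="lm")
    center, radius = res.x[:3], float(res.x[3])
    rms = float(np.sqrt(np.mean(residuals(res.x) ** 2)))
    if radius <= 0 or radius > 1e3 * region_radius:
        raise ValueError("sphere fit degenerate (patch too flat)")
    return SphereModel(center, radius, rms)


def sphere_magnetic_forward(
    moment: np.ndarray, position: np.ndarray, origin, field_point: np.ndarray
) -> np.ndarray:
    """External magnetic field (T) of a current dipole in a spherical conductor.

    ``moment`` in A*m, ``position``/``field_point``/``origin`` in mm.  The
    closed form depends only on the sphere origin, not on the conductivity
    profile or the sphere radius.  Radial dipoles produce exactly zero
    field; a dipole at the origin is radial in the degenerate sense and
    also yields zero.
    """
    o = np.asarray(origin, dtype=float)
    q = np.asarray(moment, dtype=float)
    r_q = (np.asarray(position, dtype=float) - o) * 1e-3
    r = (np.asarray(field_point, dtype=float) - o) * 1e-3
    rn = np.linalg.norm(r)
    a_vec = r - r_q
    a = np.linalg.norm(a_vec)
    if a < 1e-12:
        raise ValueError("field point coincides with the dipole")
    if rn <= np.linalg.norm(r_q):
        raise ValueError("field point must be outside the source radius")
    F = a * (rn * a + rn**2 - r_q @ r)
    if abs(F) < 1e-300:
        raise ValueError("field point on the singular set of the sphere formula")
    gradF = (a**2 / rn + (a_vec @ r) / a + 2 * a + 2 * rn) * r - (
        a + 2 * rn + (a_vec @ r) / a
    ) * r_q
    qxrq = np.cross(q, r_q)
    return MU0 / (4 * np.pi * F**2) * (F * qxrq - (qxrq @ r) * gradF)


def _sphere_bfield_many(r_q, field_points_m):
    """Sarvas fields of the three unit dipoles at r_q, at many field points.

    Returns array (n_points, 3 components of B, 3 dipole directions).
    Vectorised over field points; all inputs in metres relative to origin.
    """
    r = field_points_m
    rn = np.linalg.norm(r, axis=1)
    a_vec = r - r_q
    a = np.linalg.norm(a_vec, axis=1)
    F = a * (rn * a + rn**2 - r @ r_q)
    ar = np.einsum("ij,ij->i", a_vec, r)
    gradF = ((a**2 / rn + ar / a + 2 * a + 2 * rn)[:, None] * r) - (
        (a + 2 * rn + ar / a)[:, None] * r_q
    )
    out = np.empty((len(r), 3, 3))
    eye = np.eye(3)
    for i in range(3):
        qxrq = np.cross(eye[i], r_q)
        out[:, :, i] = (MU0 / (4 * np.pi)) * (
            (F[:, None] * qxrq - (r @ qxrq)[:, None] * gradF) / (F**2)[:, None]
        )
    return out


def sphere_efield(
    model: SphereModel, coil: CoilModel, dIdt: float, points: np.ndarray
) -> np.ndarray:
    """Induced E-field (V/m) at cortical points (mm) for a placed coil.

    E_i(r) = -dI/dt * sum_k w_k n_k . B(e_i at r; r_k) over the coil
    quadrature, for the three Cartesian unit dipoles e_i.  Every point must
    lie strictly inside the validity radius.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    validity = model.validity_radius(coil)
    rad = np.linalg.norm(pts - model.origin, axis=1)
    bad = np.nonzero(rad >= validity)[0]
    if len(bad):
        raise ValidityError(
            f"point {bad[0]} at radius {rad[bad[0]]:.2f} mm is outside the "
            f"validity radius {validity:.2f} mm"
        )
    rk = (coil.placed_positions() - model.origin) * 1e-3
    nk = coil.placed_normals()
    wk = coil.weights * 1e-6
    E = np.zeros((len(pts), 3))
    pts_rel = (pts - model.origin) * 1e-3
    for j in range(len(pts)):
        B3 = _sphere_bfield_many(pts_rel[j], rk)  # (K, 3comp, 3dir)
        flux = np.einsum("k,kc,kcd->d", wk, nk, B3)
        E[j] = -dIdt * flux
    return E
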