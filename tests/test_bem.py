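"""Linear-collocation BEM: operator closure, potentials, Geselowitz field,
reciprocity E-field, multi-compartment behaviour."""

import numpy as np
import pytest
from scipy.special import eval_legendre, lpmv

from ratfield._kernels import double_layer_block, solid_angle_sum
from ratfield.bem import (
    PotentialSolution,
    StabilityError,
    assemble_double_layer,
    bem_efield,
    build_deflated_system,
    geselowitz_bfield,
    solve_surface_potentials,
)
from ratfield.geometry import TriMesh
from ratfield.model import single_compartment
from ratfield.phantom import make_concentric_spheres_model, make_icosphere
from ratfield.sphere import SphereModel, sphere_efield, sphere_magnetic_forward

SIGMA = 0.33


def series_sphere_potential(points_mm, moment, depth_mm, radius_mm, sigma, nmax=100):
    """Analytic surface potential of a dipole on the z-axis of a
    homogeneous sphere (Legendre series; tangential moment along x)."""
    pts = points_mm * 1e-3
    Rm, fm = radius_mm * 1e-3, depth_mm * 1e-3
    r = np.linalg.norm(pts, axis=1)
    cos_t = pts[:, 2] / r
    psi = np.arctan2(pts[:, 1], pts[:, 0])
    p_r, p_t = moment[2], moment[0]
    out = np.zeros(len(pts))
    for n in range(1, nmax + 1):
        Pn = eval_legendre(n, cos_t)
        Pn1 = -lpmv(1, n, cos_t)  # without Condon-Shortley phase
        out += (
            (2 * n + 1) / n * fm ** (n - 1) / Rm ** (n + 1)
            * (n * p_r * Pn + p_t * np.cos(psi) * Pn1)
        )
    return out / (4 * np.pi * sigma)


class TestSolidAngles:
    def test_interior_point_closure(self):
        sph = make_icosphere(15.0, 3)
        total = solid_angle_sum(np.array([1.0, 2.0, 0.5]), sph.vertices, sph.faces)
        assert total == pytest.approx(4 * np.pi, abs=1e-6)

    def test_exterior_point_zero(self):
        sph = make_icosphere(15.0, 3)
        total = solid_angle_sum(np.array([20.0, 2.0, 0.5]), sph.vertices, sph.faces)
        assert abs(total) < 1e-6

    def test_on_surface_rowsum_converges_to_2pi(self):
        """Raw vertex row sums deviate from 2pi by the vertex solid-angle
        defect, which shrinks with refinement."""
        devs = []
        for sub in (2, 3):
            sph = make_icosphere(15.0, sub)
            D = np.zeros((sph.n_vertices, sph.n_vertices))
            double_layer_block(sph.vertices, sph.vertices, sph.faces, D)
            devs.append(np.abs(D.sum(axis=1) - 2 * np.pi).mean())
        assert devs[1] < 0.6 * devs[0]
        assert devs[1] < 0.1 * 2 * np.pi

    def test_constant_is_null_vector_after_closure(self):
        """With the closure diagonal, A . 1 = 0 exactly for insulated models."""
        model = single_compartment(make_icosphere(10.0, 2), SIGMA)
        system = assemble_double_layer(model)
        resid = np.abs(system.matrix @ np.ones(system.n)).max()
        assert resid < 1e-12 * SIGMA * system.n


class TestDeflation:
    def test_removes_near_null_singular_value(self):
        model = single_compartment(make_icosphere(10.0, 2), SIGMA)
        raw = assemble_double_layer(model)
        s_raw = np.linalg.svd(raw.matrix.copy(), compute_uv=False)
        deflated = build_deflated_system(raw)
        # reconstruct the deflated matrix from LU to measure conditioning
        from scipy.linalg import lu_solve

        n = deflated.n
        eye = np.eye(n)
        inv = lu_solve(deflated.lu, eye)
        s_defl_min = 1.0 / np.linalg.norm(inv, 2)
        assert s_raw[-1] < 1e-10 * s_raw[0]
        assert s_defl_min > 1e-3 * s_raw[0]

    def test_repeated_solve_identical(self):
        model = single_compartment(make_icosphere(10.0, 2), SIGMA)
        system = build_deflated_system(assemble_double_layer(model))
        p, pos = np.array([1e-8, 0, 0]), [0, 0, 5.0]
        a = solve_surface_potentials(system, p, pos).phi
        b = solve_surface_potentials(system, p, pos).phi
        assert np.array_equal(a, b)

    def test_rhs_constant_shifts_gauge_only(self):
        model = single_compartment(make_icosphere(10.0, 2), SIGMA)
        system = build_deflated_system(assemble_double_layer(model))
        from scipy.linalg import lu_solve

        rng = np.random.default_rng(3)
        b = rng.normal(size=system.n)
        x = lu_solve(system.lu, b)
        y = lu_solve(system.lu, b + 0.7)
        diff = y - x
        assert diff.std() < 1e-10 * np.abs(diff.mean())


class TestPotentials:
    def test_dipole_in_sphere_matches_series(self, sphere4_system):
        p = np.array([1e-8, 0.0, 2e-8])
        sol = solve_surface_potentials(sphere4_system, p, [0, 0, 9.0])
        mesh = sphere4_system.model.surfaces[0].mesh
        exact = series_sphere_potential(mesh.vertices, p, 9.0, 15.0, SIGMA)
        a = sol.phi - sol.phi.mean()
        b = exact - exact.mean()
        assert np.linalg.norm(a - b) / np.linalg.norm(b) < 0.01

    def test_zero_moment_zero_potential(self, sphere4_system):
        sol = solve_surface_potentials(sphere4_system, np.zeros(3), [0, 0, 9.0])
        assert np.abs(sol.phi).max() == 0.0

    def test_source_margin_enforced(self, sphere4_system):
        with pytest.raises(StabilityError):
            solve_surface_potentials(sphere4_system, np.array([1e-8, 0, 0]), [0, 0, 14.99])

    def test_equal_conductivity_shell_is_transparent(self):
        """A nested surface with zero conductivity jump changes nothing."""
        nested = make_concentric_spheres_model([15, 12], [SIGMA, SIGMA], subdivisions=3)
        plain = single_compartment(make_icosphere(15.0, 3), SIGMA)
        p, pos = np.array([1e-8, 0, 1e-8]), [0, 0, 7.0]
        phi_n = solve_surface_potentials(
            build_deflated_system(assemble_double_layer(nested)), p, pos
        ).phi
        phi_p = solve_surface_potentials(
            build_deflated_system(assemble_double_layer(plain)), p, pos
        ).phi
        outer = nested.surfaces[0].mesh.n_vertices
        a = phi_n[:outer] - phi_n[:outer].mean()
        b = phi_p - phi_p.mean()
        assert np.linalg.norm(a - b) / np.linalg.norm(b) < 1e-10


class TestGeselowitz:
    FP = np.array([10.0, 5.0, 25.0])
    POS = [0.0, 0.0, 9.0]

    def test_tangential_matches_sarvas(self, sphere4_model, sphere4_system):
        p = np.array([1e-8, 0, 0])
        sol = solve_surface_potentials(sphere4_system, p, self.POS)
        B = geselowitz_bfield(sphere4_model, sol, p, self.POS, self.FP)
        B_an = sphere_magnetic_forward(p, np.array(self.POS), [0, 0, 0], self.FP)
        assert np.linalg.norm(B - B_an) / np.linalg.norm(B_an) < 0.01

    def test_radial_residual_at_discretisation_floor(self, sphere4_model, sphere4_system):
        """Silent-source leakage is phi-limited, ~1e-2 of the tangential
        scale at this mesh (see the acceptance test for the strict bound)."""
        p_r = np.array([0, 0, 1e-8])
        sol = solve_surface_potentials(sphere4_system, p_r, self.POS)
        B = geselowitz_bfield(sphere4_model, sol, p_r, self.POS, self.FP)
        B_t = sphere_magnetic_forward(
            np.array([1e-8, 0, 0]), np.array(self.POS), [0, 0, 0], self.FP
        )
        assert np.linalg.norm(B) / np.linalg.norm(B_t) < 0.03

    def test_zero_potential_gives_primary_field(self, sphere4_model):
        p = np.array([1e-8, 0, 0])
        sol = PotentialSolution(np.zeros(sphere4_model.surfaces[0].mesh.n_vertices))
        B = geselowitz_bfield(sphere4_model, sol, p, self.POS, self.FP)
        from ratfield.coil import MU0

        d = (self.FP - np.array(self.POS)) * 1e-3
        B_inf = MU0 / (4 * np.pi) * np.cross(p, d) / np.linalg.norm(d) ** 3
        assert np.allclose(B, B_inf, rtol=1e-12)

    def test_gauge_invariance(self, sphere4_model, sphere4_system):
        p = np.array([1e-8, 0, 0])
        sol = solve_surface_potentials(sphere4_system, p, self.POS)
        B1 = geselowitz_bfield(sphere4_model, sol, p, self.POS, self.FP)
        shifted = PotentialSolution(sol.phi + 10 * np.abs(sol.phi).max())
        B2 = geselowitz_bfield(sphere4_model, shifted, p, self.POS, self.FP)
        assert np.linalg.norm(B2 - B1) / np.linalg.norm(B1) < 1e-6


class TestBemEfield:
    def test_matches_sphere_closed_form(self, sphere4_model, sphere4_system, placed_coil):
        pts = make_icosphere(13.0, 2).vertices
        E = bem_efield(sphere4_model, sphere4_system, placed_coil, 50e6, pts)
        E_an = sphere_efield(SphereModel(np.zeros(3), 15.0), placed_coil, 50e6, pts)
        assert np.linalg.norm(E - E_an) / np.linalg.norm(E_an) < 0.02

    def test_refinement_monotone(self, placed_coil):
        pts = make_icosphere(12.5, 1).vertices
        E_an = sphere_efield(SphereModel(np.zeros(3), 15.0), placed_coil, 50e6, pts)
        res = []
        for sub in (2, 3, 4):
            model = single_compartment(make_icosphere(15.0, sub), SIGMA)
            system = build_deflated_system(assemble_double_layer(model))
            E = bem_efield(model, system, placed_coil, 50e6, pts, check_margin=sub > 2)
            res.append(np.linalg.norm(E - E_an) / np.linalg.norm(E_an))
        assert res[0] > res[1] > res[2]

    def test_linear_in_didt(self, sphere4_model, sphere4_system, placed_coil):
        pts = make_icosphere(12.0, 1).vertices
        E1 = bem_efield(sphere4_model, sphere4_system, placed_coil, 50e6, pts)
        E2 = bem_efield(sphere4_model, sphere4_system, placed_coil, 100e6, pts)
        assert np.allclose(E2, 2 * E1, rtol=1e-12)

    def test_adjoint_equals_per_dipole_route(self, sphere4_model, sphere4_system, placed_coil):
        """One adjoint solve per coil == three unit-dipole solves per point."""
        from ratfield.coil import primary_efield

        pts = np.array([[0.0, 0.0, 12.0], [5.0, -3.0, 9.0]])
        E_fast = bem_efield(sphere4_model, sphere4_system, placed_coil, 50e6, pts)
        rk = placed_coil.placed_positions()
        nk = placed_coil.placed_normals()
        wk = placed_coil.weights * 1e-6
        E_slow = primary_efield(placed_coil, 50e6, pts)
        for i, r in enumerate(pts):
            for d in range(3):
                e = np.zeros(3)
                e[d] = 1.0
                sol = solve_surface_potentials(sphere4_system, e, r)
                flux = 0.0
                for k in range(len(rk)):
                    B = geselowitz_bfield(sphere4_model, sol, e, r, rk[k], quad_depth=1)
                    Binf = _b_inf(e, r, rk[k])
                    flux += wk[k] * nk[k] @ (B - Binf)
                E_slow[i, d] += -50e6 * flux
        assert np.linalg.norm(E_fast - E_slow) / np.linalg.norm(E_slow) < 1e-8

    def test_skull_shell_conductivity_invariance(self, placed_coil):
        """Spherically symmetric conductivity: field unchanged (RE < 3%)."""
        model = make_concentric_spheres_model(
            [17, 15, 14], [SIGMA, 6.6e-3, SIGMA], subdivisions=3
        )
        system = build_deflated_system(assemble_double_layer(model))
        coil = _coil_on_sphere(17.0)
        pts = make_icosphere(11.5, 2).vertices
        E = bem_efield(model, system, coil, 50e6, pts)
        E_an = sphere_efield(SphereModel(np.zeros(3), 17.0), coil, 50e6, pts)
        assert np.linalg.norm(E - E_an) / np.linalg.norm(E_an) < 0.03

    def test_floating_shell_equals_nested(self, placed_coil):
        """A skull shell written as one two-sheet closed surface behaves
        like the equivalent nested concentric description."""
        outer = make_icosphere(15.0, 3)
        inner = make_icosphere(14.0, 3).flipped()
        shell = TriMesh(
            np.vstack([outer.vertices, inner.vertices]),
            np.vstack([outer.faces, inner.faces + outer.n_vertices]),
            label="skull",
        )
        from ratfield.model import BoundarySurface, CompartmentModel

        body = make_icosphere(17.0, 3)
        body.label = "body"
        floating = CompartmentModel(
            [
                BoundarySurface(body, SIGMA, 0.0),
                BoundarySurface(shell, 6.6e-3, SIGMA),
            ]
        )
        nested = make_concentric_spheres_model(
            [17, 15, 14], [SIGMA, 6.6e-3, SIGMA], subdivisions=3
        )
        coil = _coil_on_sphere(17.0)
        pts = make_icosphere(11.5, 1).vertices
        E_f = bem_efield(floating, build_deflated_system(assemble_double_layer(floating)), coil, 50e6, pts)
        E_n = bem_efield(nested, build_deflated_system(assemble_double_layer(nested)), coil, 50e6, pts)
        assert np.linalg.norm(E_f - E_n) / np.linalg.norm(E_n) < 1e-6

    def test_margin_violation_reported(self, sphere4_model, sphere4_system, placed_coil):
        with pytest.raises(StabilityError, match="point 0"):
            bem_efield(
                sphere4_model, sphere4_system, placed_coil, 50e6, np.array([[0, 0, 14.9]])
            )


def _b_inf(p, pos_mm, fp_mm):
    from ratfield.coil import MU0

    d = (np.asarray(fp_mm) - np.asarray(pos_mm)) * 1e-3
    return MU0 / (4 * np.pi) * np.cross(p, d) / np.linalg.norm(d) ** 3


def _coil_on_sphere(radius: float):
    from ratfield.coil import CoilPlacement, build_figure8_quadrature, place_coil_tangential

    return place_coil_tangential(
        build_figure8_quadrature(),
        CoilPlacement(np.array([0.0, 0.0, radius]), 0.0, np.array([0.0, 0.0, 1.0])),
        2.0,
    )
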