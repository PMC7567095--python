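"""Figure-of-eight coil quadrature, placement and primary E-field."""

import dataclasses

import numpy as np
import pytest

from ratfield.coil import (
    MU0,
    CoilPlacement,
    CoilSpec,
    build_figure8_quadrature,
    place_coil_tangential,
    primary_efield,
)
from ratfield.phantom import make_icosphere
from ratfield.sphere import SphereModel, sphere_efield


class TestQuadrature:
    def test_single_loop_area_closure(self):
        """One turn, one layer: positive weights sum to pi a^2 exactly."""
        spec = CoilSpec(turns_per_layer=1, layers=(4.5,))
        coil = build_figure8_quadrature(spec)
        a = spec.inner_diameter / 2.0
        pos = coil.weights[coil.weights > 0]
        assert pos.sum() == pytest.approx(np.pi * a**2, abs=1e-9)

    def test_signed_weights_cancel(self):
        coil = build_figure8_quadrature()
        assert coil.weights.sum() == pytest.approx(0.0, abs=1e-9)

    def test_wing_flux_matches_analytic_turn_areas(self):
        """Uniform axial B=1: wing flux = sum of 12 turn areas (r 12..23.5)."""
        spec = CoilSpec()
        coil = build_figure8_quadrature(spec)
        radii = np.linspace(12.0, 23.5, 4)
        analytic = 3 * np.pi * (radii**2).sum()
        wing = coil.weights[coil.weights > 0].sum()  # flux of B=1 through wing
        assert wing == pytest.approx(analytic, rel=1e-12)
        assert spec.wing_area() == pytest.approx(analytic, rel=1e-12)

    def test_dipoles_above_insulation(self):
        coil = build_figure8_quadrature()
        assert (coil.positions[:, 2] >= coil.spec.bottom_insulation - 1e-12).all()

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            CoilSpec(inner_diameter=50.0)
        with pytest.raises(ValueError):
            CoilSpec(layers=(12.0,))
        with pytest.raises(ValueError):
            CoilSpec(azimuthal_samples=4)


class TestPlacement:
    def test_opposite_angles_reverse_field(self):
        """theta and theta+180: same dipole positions, negated weights."""
        coil = build_figure8_quadrature()
        pl0 = CoilPlacement(np.array([0, 0, 15.0]), 30.0, np.array([0, 0, 1.0]))
        pl180 = CoilPlacement(np.array([0, 0, 15.0]), 210.0, np.array([0, 0, 1.0]))
        c0 = place_coil_tangential(coil, pl0, 2.0)
        c180 = place_coil_tangential(coil, pl180, 2.0)
        p0 = c0.placed_positions()
        p180 = c180.placed_positions()
        o0 = np.lexsort(np.round(p0, 9).T)
        o180 = np.lexsort(np.round(p180, 9).T)
        assert np.allclose(p0[o0], p180[o180], atol=1e-9)
        # same dipole cloud carrying the reversed current: field flips sign
        pts = np.array([[0.0, 0.0, 12.0], [4.0, -3.0, 10.0]])
        assert np.allclose(
            primary_efield(c0, 50e6, pts), -primary_efield(c180, 50e6, pts), rtol=1e-9
        )

    def test_full_turn_identity(self):
        coil = build_figure8_quadrature()
        a = place_coil_tangential(
            coil, CoilPlacement(np.array([1.0, 2, 14]), 40.0, np.array([0, 0.2, 1.0])), 2.0
        )
        b = place_coil_tangential(
            coil, CoilPlacement(np.array([1.0, 2, 14]), 400.0, np.array([0, 0.2, 1.0])), 2.0
        )
        assert np.allclose(a.transform, b.transform, atol=1e-12)

    def test_standoff_keeps_dipoles_above_scalp(self):
        coil = build_figure8_quadrature()
        for ang in (0.0, 35.0, 90.0):
            placed = place_coil_tangential(
                coil, CoilPlacement(np.array([0, 0, 15.0]), ang, np.array([0, 0, 1.0])), 0.0
            )
            z = placed.placed_positions()[:, 2]
            assert (z >= 15.0 + coil.spec.bottom_insulation - 1e-9).all()

    def test_degenerate_normal_rejected(self):
        with pytest.raises(ValueError, match="normal"):
            CoilPlacement(np.zeros(3), 0.0, np.zeros(3))

    def test_pa_reference_direction(self, placed_coil):
        """Angle 0 induces a PA-directed (+x) primary E under the centre."""
        E = primary_efield(placed_coil, 50e6, np.array([[0.0, 0.0, 12.0]]))[0]
        assert E[0] > 0
        assert abs(E[1]) < 1e-9 * abs(E[0])
        assert abs(E[2]) < 1e-9 * abs(E[0])


class TestPrimaryField:
    def test_zero_didt(self, placed_coil):
        E = primary_efield(placed_coil, 0.0, np.array([[0, 0, 10.0]]))
        assert np.all(E == 0)

    def test_linearity(self, placed_coil):
        pts = np.array([[0, 0, 10.0], [3, 2, 8.0]])
        assert np.allclose(
            primary_efield(placed_coil, 100e6, pts),
            2 * primary_efield(placed_coil, 50e6, pts),
            rtol=1e-12,
        )

    def test_singularity_guard(self, placed_coil):
        p = placed_coil.placed_positions()[0]
        with pytest.raises(ValueError, match="coincides"):
            primary_efield(placed_coil, 50e6, p[None, :])

    def test_dipole_vs_line_current_loop(self):
        """Far from a small loop, the dipole quadrature matches Biot-Savart.

        Oracle: E = -(mu0/4pi) dIdt * closed line integral of dl'/|r-r'|
        over the wire path, evaluated by dense numerical integration.
        """
        a = 1.0  # mm loop radius
        spec = CoilSpec(
            inner_diameter=2 * a,
            outer_diameter=2 * a + 1e-6,
            turns_per_layer=1,
            layers=(0.0,),
            bottom_insulation=0.0,
            azimuthal_samples=16,
        )
        coil = build_figure8_quadrature(spec)
        # keep only the positive wing, recentred at the origin
        keep = coil.weights > 0
        x0 = spec.outer_diameter / 2.0
        positions = coil.positions[keep] - np.array([x0, 0.0, 0.0])
        from ratfield.coil import CoilModel

        wing = CoilModel(positions, coil.normals[keep], coil.weights[keep], spec)
        pts = np.array([[60.0, 25.0, 40.0]])  # |r| >> a
        E_dip = primary_efield(wing, 50e6, pts)[0]

        theta = np.linspace(0, 2 * np.pi, 20000, endpoint=False)
        wire = np.column_stack([a * np.cos(theta), a * np.sin(theta), np.zeros_like(theta)])
        dl = np.roll(wire, -1, axis=0) - wire
        r = pts[0] * 1e-3 - wire * 1e-3
        E_loop = -(MU0 / (4 * np.pi)) * 50e6 * (dl * 1e-3 / np.linalg.norm(r, axis=1)[:, None]).sum(axis=0)
        assert np.linalg.norm(E_dip - E_loop) / np.linalg.norm(E_loop) < 0.01

    def test_mirror_antisymmetry(self):
        """Reflection across the long axis reverses each loop's winding
        sense, so the field maps to minus its mirror image:
        E(x,-y,z) = -(Ex,-Ey,Ez)(x,y,z)."""
        coil = build_figure8_quadrature()
        pts = np.array([[5.0, 3.0, -9.0], [-11.0, 7.0, -12.0]])
        mirrored = pts * np.array([1.0, -1.0, 1.0])
        E = primary_efield(coil, 50e6, pts)
        Em = primary_efield(coil, 50e6, mirrored)
        assert np.allclose(Em, -E * np.array([1.0, -1.0, 1.0]), rtol=1e-9, atol=1e-12)


def test_azimuthal_quadrature_convergence():
    """Doubling azimuthal samples changes sphere-model peak |E| by < 0.5%."""
    model = SphereModel(np.zeros(3), 15.0)
    pts = make_icosphere(12.5, 2).vertices
    peaks = []
    for n in (16, 32, 64):
        spec = CoilSpec(azimuthal_samples=n)
        coil = place_coil_tangential(
            build_figure8_quadrature(spec),
            CoilPlacement(np.array([0, 0, 15.0]), 0.0, np.array([0, 0, 1.0])),
            2.0,
        )
        E = sphere_efield(model, coil, 50e6, pts)
        peaks.append(np.linalg.norm(E, axis=1).max())
    assert abs(peaks[1] - peaks[0]) / peaks[0] < 0.005
    assert abs(peaks[2] - peaks[1]) / peaks[1] < 0.005


def test_export_formats(tmp_path, placed_coil):
    placed_coil.export_csv(tmp_path / "coil.csv")
    placed_coil.export_vtk(tmp_path / "coil.vtk")
    data = np.loadtxt(tmp_path / "coil.csv", delimiter=",", skiprows=1)
    assert data.shape == (placed_coil.n_dipoles, 7)
    text = (tmp_path / "coil.vtk").read_text()
    assert f"POINTS {placed_coil.n_dipoles} float" in text


def test_single_layer_simplification():
    """Thin-coil model keeps total ampere-turns at one height."""
    spec = CoilSpec()
    thin = spec.single_layer(4.5)
    assert thin.layers == (4.5, 4.5, 4.5)
    assert thin.wing_area() == pytest.approx(spec.wing_area(), rel=1e-12)
    assert dataclasses.replace(thin, layers=spec.layers) == spec
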