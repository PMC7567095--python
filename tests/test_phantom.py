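"""Synthetic phantom: primitives, rat head geometry, CT synthesis."""

import numpy as np
import pytest

from ratfield.geometry import mesh_statistics, validate_mesh
from ratfield.model import single_compartment
from ratfield.phantom import (
    PhantomSpec,
    SkullHole,
    make_concentric_spheres_model,
    make_icosphere,
    make_rat_phantom,
    phantom_masks,
    synthesize_ct,
    HU_AIR,
    HU_BONE,
    HU_SOFT,
)
from ratfield.proximity import SurfaceDistance


class TestIcosphere:
    def test_base_icosahedron(self):
        m = make_icosphere(10.0, 0)
        assert (m.n_vertices, m.n_faces) == (12, 20)

    def test_subdivision_counts_and_radius(self):
        m = make_icosphere(10.0, 3)
        assert m.n_vertices == 642
        assert np.abs(np.linalg.norm(m.vertices, axis=1) - 10.0).max() < 1e-9

    def test_polyhedral_volume_converges(self):
        """Inscribed-polyhedron volume deficit shrinks ~4x per subdivision."""
        exact = 4.0 / 3.0 * np.pi * 1000.0
        err2 = abs(make_icosphere(10.0, 2).signed_volume() - exact) / exact
        err3 = abs(make_icosphere(10.0, 3).signed_volume() - exact) / exact
        assert err2 < 0.04
        assert err3 < 0.01
        assert err3 < 0.35 * err2

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            make_icosphere(-1.0, 2)
        with pytest.raises(ValueError):
            make_icosphere(1.0, -1)


class TestConcentricSpheres:
    def test_two_shell_skull_model(self):
        m = make_concentric_spheres_model([17, 15, 14], [0.33, 0.0066, 0.33], subdivisions=2)
        assert len(m.surfaces) == 3
        assert m.surfaces[0].sigma_out == 0.0
        assert m.surfaces[1].sigma_in == pytest.approx(0.0066)
        assert m.surfaces[1].sigma_out == pytest.approx(0.33)
        m.validate()

    def test_single_sphere(self):
        m = make_concentric_spheres_model([15.0], [0.33], subdivisions=2)
        assert len(m.surfaces) == 1

    def test_ordering_error(self):
        with pytest.raises(ValueError):
            make_concentric_spheres_model([15, 17], [0.33, 0.0066])

    def test_count_mismatch(self):
        with pytest.raises(ValueError):
            make_concentric_spheres_model([17, 15], [0.33, 0.0066, 0.33])


class TestRatPhantom:
    def test_surfaces_valid_and_topology(self, coarse_phantom):
        model, evaluation, scalp = coarse_phantom
        model.validate()
        body_stats = mesh_statistics(model.surfaces[0].mesh)
        skull_stats = mesh_statistics(model.surfaces[1].mesh)
        assert body_stats.euler_characteristic == 2
        # three holes: two sheets joined by three tubes -> genus 2
        assert skull_stats.euler_characteristic == -2
        assert validate_mesh(evaluation).closed

    def test_no_holes_gives_disjoint_sheets(self, coarse_spec):
        import dataclasses

        spec = dataclasses.replace(coarse_spec, holes=())
        model, _, _ = make_rat_phantom(spec)
        assert mesh_statistics(model.surfaces[1].mesh).euler_characteristic == 4

    def test_evaluation_margin(self, coarse_phantom, coarse_spec):
        model, evaluation, _ = coarse_phantom
        d = SurfaceDistance(model.surfaces[1].mesh).distance(evaluation.vertices)
        assert d.min() >= coarse_spec.eval_margin

    def test_overlapping_holes_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PhantomSpec(holes=(SkullHole((1, 0, 0), 20.0), SkullHole((1, 0.2, 0), 20.0)))

    def test_deterministic_geometry(self, coarse_spec, coarse_phantom):
        model, _, _ = coarse_phantom
        model2, _, _ = make_rat_phantom(coarse_spec)
        assert np.array_equal(model.surfaces[1].mesh.vertices, model2.surfaces[1].mesh.vertices)
        assert np.array_equal(model.surfaces[1].mesh.faces, model2.surfaces[1].mesh.faces)


class TestSynthesizeCT:
    def test_sphere_noise_free_two_level(self):
        m = single_compartment(make_icosphere(8.0, 3), 0.33)
        ct = synthesize_ct(m, spacing=0.5, noise_sd=0.0)
        vals = np.unique(ct.data)
        assert set(vals.tolist()) == {HU_AIR, HU_SOFT}
        # containment volume close to the sphere volume
        frac = (ct.data == HU_SOFT).sum() * 0.5**3
        assert frac == pytest.approx(4 / 3 * np.pi * 8**3, rel=0.02)

    def test_rat_ct_histogram_modes(self, coarse_phantom):
        model, _, _ = coarse_phantom
        ct = synthesize_ct(model, spacing=0.4, noise_sd=50.0, seed=1)
        hist, edges = np.histogram(ct.data, bins=np.arange(-1200, 1800, 10.0))
        centers = 0.5 * (edges[:-1] + edges[1:])

        def local_peak(target, width=150):
            sel = np.abs(centers - target) < width
            return centers[sel][np.argmax(hist[sel])]

        assert abs(local_peak(HU_AIR) - HU_AIR) <= 30
        assert abs(local_peak(HU_SOFT) - HU_SOFT) <= 30
        assert abs(local_peak(HU_BONE) - HU_BONE) <= 30

    def test_seed_determinism(self, coarse_phantom):
        model, _, _ = coarse_phantom
        a = synthesize_ct(model, spacing=0.6, noise_sd=50.0, seed=7)
        b = synthesize_ct(model, spacing=0.6, noise_sd=50.0, seed=7)
        assert np.array_equal(a.data, b.data)
        c = synthesize_ct(model, spacing=0.6, noise_sd=50.0, seed=8)
        assert not np.array_equal(a.data, c.data)

    def test_invalid_spacing(self, coarse_phantom):
        model, _, _ = coarse_phantom
        with pytest.raises(ValueError):
            synthesize_ct(model, spacing=0.0)

    def test_bone_thickness_recovered(self, coarse_spec, coarse_phantom):
        """Voxelised shell thickness matches the spec within one voxel."""
        model, _, _ = coarse_phantom
        ct = synthesize_ct(model, spacing=0.25, noise_sd=0.0)
        masks = phantom_masks(coarse_spec, ct)
        bone = masks["bone"]
        # thickness along +z through the skull crown
        cx, cy, cz = coarse_spec.skull_center
        i = int(round((cx - ct.origin[0]) / ct.spacing))
        j = int(round((cy - ct.origin[1]) / ct.spacing))
        col = bone[i, j, :]
        # the column crosses the shell at the crown and at the base
        n_runs = (np.diff(np.nonzero(col)[0]) > 1).sum() + 1
        thickness_vox = col.sum() / max(1, n_runs)
        assert abs(thickness_vox * ct.spacing - coarse_spec.skull_thickness) <= ct.spacing
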