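"""Threshold segmentation, morphology and surface extraction."""

import numpy as np
import pytest

from ratfield.geometry import mesh_statistics, validate_mesh
from ratfield.model import single_compartment
from ratfield.phantom import (
    HU_AIR,
    HU_SOFT,
    make_icosphere,
    phantom_masks,
    synthesize_ct,
)
from ratfield.proximity import SurfaceDistance
from ratfield.segmentation import (
    SegmentationParams,
    extract_boundary_surface,
    find_thresholds,
    make_evaluation_surface,
    morph_close,
    segment_volume,
)
from ratfield.volume import CTVolume, LABEL_BODY, LABEL_BONE


def two_level_volume(shape=(40, 40, 40), spacing=0.5):
    data = np.full(shape, HU_AIR, dtype=np.float32)
    data[10:30, 10:30, 10:30] = HU_SOFT
    return CTVolume(data, spacing, np.zeros(3))


class TestThresholds:
    def test_noise_free_midpoint_exact(self):
        t1, _ = find_thresholds(two_level_volume())
        assert t1 == pytest.approx(-480.0, abs=0.5)

    def test_noisy_phantom(self, coarse_phantom):
        model, _, _ = coarse_phantom
        ct = synthesize_ct(model, spacing=0.4, noise_sd=50.0, seed=1)
        t1, t2 = find_thresholds(ct)
        assert t1 == pytest.approx(-480.0, abs=30.0)
        assert HU_SOFT < t2 < 1000.0

    def test_constant_volume_error(self):
        ct = CTVolume(np.zeros((10, 10, 10), dtype=np.float32), 1.0, np.zeros(3))
        with pytest.raises(ValueError, match="modes"):
            find_thresholds(ct)


class TestSegmentVolume:
    def test_noise_free_exact_masks(self):
        m = single_compartment(make_icosphere(8.0, 3), 0.33)
        ct = synthesize_ct(m, spacing=0.5, noise_sd=0.0)
        lab = segment_volume(ct, SegmentationParams(t_air_soft=-480.0, t_soft_bone=500.0))
        assert np.array_equal(lab.mask(LABEL_BODY), ct.data == HU_SOFT)

    def test_noisy_body_dice(self, coarse_phantom):
        """Body mask under 50-HU noise vs the phantom voxelisation."""
        model, _, _ = coarse_phantom
        ct = synthesize_ct(model, spacing=0.34, noise_sd=50.0, seed=1)
        truth = synthesize_ct(model, spacing=0.34, noise_sd=0.0).data > (HU_AIR + 1)
        lab = segment_volume(ct)
        body = lab.mask(LABEL_BODY) | lab.mask(LABEL_BONE)
        dice = 2 * (body & truth).sum() / (body.sum() + truth.sum())
        assert dice > 0.99

    def test_largest_component_kept(self):
        data = np.full((30, 30, 30), HU_AIR, dtype=np.float32)
        data[2:20, 2:20, 2:20] = HU_SOFT  # large blob
        data[24:27, 24:27, 24:27] = HU_SOFT  # small blob
        ct = CTVolume(data, 1.0, np.zeros(3))
        lab = segment_volume(ct, SegmentationParams(t_air_soft=-480.0, t_soft_bone=500.0))
        assert not lab.mask(LABEL_BODY)[25, 25, 25]
        assert lab.mask(LABEL_BODY)[10, 10, 10]

    def test_bone_monotone_in_threshold(self, coarse_phantom):
        model, _, _ = coarse_phantom
        ct = synthesize_ct(model, spacing=0.5, noise_sd=50.0, seed=2)
        lo = segment_volume(ct, SegmentationParams(t_air_soft=-480, t_soft_bone=400.0))
        hi = segment_volume(ct, SegmentationParams(t_air_soft=-480, t_soft_bone=700.0))
        assert (lo.mask(LABEL_BONE) | hi.mask(LABEL_BONE)).sum() == lo.mask(LABEL_BONE).sum()


class TestMorphClose:
    def test_zero_radius_identity(self):
        rng = np.random.default_rng(0)
        m = rng.random((20, 20, 20)) > 0.5
        assert np.array_equal(morph_close(m, 0.0, 0.5), m)

    def test_fills_narrow_tunnel(self):
        cube = np.zeros((40, 40, 40), dtype=bool)
        cube[5:35, 5:35, 5:35] = True
        cube[19:21, :, 19:21] = False  # 1-mm-wide tunnel at 0.5 mm spacing
        closed = morph_close(cube, 2.0, 0.5)
        assert closed[20, 20, 20]
        inner = closed[8:32, 8:32, 8:32]
        assert inner.all()

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        blob = np.zeros((30, 30, 30), dtype=bool)
        pts = rng.integers(8, 22, size=(40, 3))
        blob[pts[:, 0], pts[:, 1], pts[:, 2]] = True
        once = morph_close(blob, 1.5, 0.5)
        twice = morph_close(once, 1.5, 0.5)
        assert np.array_equal(once, twice)

    def test_closure_is_extensive(self):
        m = np.zeros((20, 20, 20), dtype=bool)
        m[8:12, 8:12, 8:12] = True
        closed = morph_close(m, 1.0, 0.5)
        assert (closed | m).sum() == closed.sum()


class TestExtractSurface:
    def test_voxelised_sphere_radius(self):
        spacing = 0.34
        n = int(24 / spacing)
        ax = (np.arange(n) - n / 2) * spacing
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        mask = X**2 + Y**2 + Z**2 < 10.0**2
        mesh = extract_boundary_surface(mask, spacing, np.full(3, ax[0]), target_edge=0.8)
        rad = np.linalg.norm(mesh.vertices, axis=1)
        assert np.abs(rad - 10.0).max() <= spacing
        assert validate_mesh(mesh).closed

    def test_single_voxel(self):
        mask = np.zeros((7, 7, 7), dtype=bool)
        mask[3, 3, 3] = True
        mesh = extract_boundary_surface(mask, 1.0, np.zeros(3), target_edge=0.8)
        st = mesh_statistics(mesh)
        assert st.euler_characteristic == 2
        assert validate_mesh(mesh).closed

    def test_border_touch_rejected(self):
        mask = np.ones((5, 5, 5), dtype=bool)
        with pytest.raises(ValueError, match="border"):
            extract_boundary_surface(mask, 1.0, np.zeros(3), target_edge=1.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_boundary_surface(np.zeros((5, 5, 5), dtype=bool), 1.0, np.zeros(3), 1.0)


def test_noisy_end_to_end_extraction(coarse_phantom):
    """Surface extraction stays usable under 50-HU noise (the rough level
    set triggers the smoothing-retry path)."""
    from ratfield.segmentation import SegmentationParams, segment_to_surfaces
    from ratfield.proximity import hausdorff_distance

    model, _, _ = coarse_phantom
    ct = synthesize_ct(model, spacing=0.4, noise_sd=50.0, seed=3)
    res = segment_to_surfaces(
        ct, SegmentationParams(body_target_edge=2.0, skull_target_edge=1.0)
    )
    assert validate_mesh(res.body).closed
    assert validate_mesh(res.skull).closed
    assert hausdorff_distance(res.body, model.surfaces[0].mesh) < 1.0


class TestEvaluationSurface:
    @staticmethod
    def _masks(spacing=0.5):
        n = int(30 / spacing)
        ax = (np.arange(n) - n / 2) * spacing
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        r2 = X**2 + Y**2 + Z**2
        brain = r2 < 10.0**2
        skull = (r2 >= 10.0**2) & (r2 < 12.0**2)
        return brain, skull, spacing, np.full(3, ax[0])

    def test_margin_zero_is_brain_boundary(self):
        brain, skull, sp, orig = self._masks()
        mesh = make_evaluation_surface(brain, skull, 0.0, sp, orig)
        rad = np.linalg.norm(mesh.vertices, axis=1)
        assert np.abs(rad - 10.0).max() <= 1.5 * sp

    def test_margin_respected(self):
        brain, skull, sp, orig = self._masks()
        mesh = make_evaluation_surface(brain, skull, 1.0, sp, orig)
        skull_surf = extract_boundary_surface(skull, sp, orig, target_edge=1.0)
        d = SurfaceDistance(skull_surf).distance(mesh.vertices)
        assert d.min() >= 1.0 - sp

    def test_margin_too_large(self):
        brain, skull, sp, orig = self._masks()
        with pytest.raises(ValueError, match="margin"):
            make_evaluation_surface(brain, skull, 25.0, sp, orig)
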