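"""Tunnel morphometry: volumes, thresholds, local thickness, full reports."""
import numpy as np
import pytest

from bonetunnel import (
    LabelMask,
    MorphometryConfig,
    PhantomSpec,
    TunnelAxis,
    VoxelGrid,
    bone_in_tunnel,
    crop_roi,
    local_thickness_map,
    make_lattice_phantom,
    morphometry_report,
    tunnel_volume,
)
from bonetunnel.phantom import cylinder_mask

from conftest import brute_force_thickness


class TestTunnelVolume:
    def test_empty_mask(self):
        assert tunnel_volume(np.zeros((2, 2, 2), np.uint8), 1.0) == 0.0

    def test_unit_spacing(self):
        m = np.ones((10, 10, 10), np.uint8)
        assert tunnel_volume(m, 1.0) == 1000.0

    def test_hrpqct_spacing(self):
        m = np.ones((10, 10, 10), np.uint8)
        assert tunnel_volume(m, 0.0607) == 1000 * 0.0607**3

    def test_exactness_random(self, rng):
        for _ in range(20):
            m = (rng.random((6, 6, 6)) > 0.5).astype(np.uint8)
            sp = float(rng.uniform(0.01, 2.0))
            assert tunnel_volume(m, sp) == int(m.sum()) * sp**3


class TestBoneInTunnel:
    def test_uniform_interior_all_bone(self):
        grid = VoxelGrid(np.full((3, 6, 6), 150.0), spacing=0.1)
        tun = np.zeros((3, 6, 6), np.uint8)
        tun[:, 2:5, 2:5] = 1
        bone = bone_in_tunnel(grid, LabelMask(tun), method=100.0)
        np.testing.assert_array_equal(bone.values, tun)

    def test_otsu_recovers_phantom_truth(self):
        spec = PhantomSpec(shape=(10, 40, 40), spacing=0.1, noise_sd=0.0,
                           tunnel_axis=TunnelAxis(20, 20), tunnel_radius=1.2,
                           refill_fraction=0.5, seed=3)
        sample = make_lattice_phantom(spec)
        bone = bone_in_tunnel(sample.grid, sample.tunnel_truth, method="otsu")
        truth = sample.bone_truth.as_bool() & sample.tunnel_truth.as_bool()
        np.testing.assert_array_equal(bone.as_bool(), truth)

    def test_always_subset_of_tunnel(self, rng):
        grid = VoxelGrid(rng.random((4, 12, 12)) * 255, spacing=0.1)
        tun = (rng.random((4, 12, 12)) > 0.4).astype(np.uint8)
        bone = bone_in_tunnel(grid, LabelMask(tun), method="otsu")
        assert not (bone.as_bool() & ~tun.astype(bool)).any()

    def test_empty_tunnel_rejected(self):
        grid = VoxelGrid(np.ones((2, 4, 4)), spacing=0.1)
        with pytest.raises(ValueError, match="empty tunnel"):
            bone_in_tunnel(grid, LabelMask(np.zeros((2, 4, 4), np.uint8)))


class TestLocalThickness:
    def test_slab_thickness(self):
        m = np.zeros((20, 20, 20), np.uint8)
        m[:, 7:12, :] = 1  # 5-voxel slab spanning the volume
        t = local_thickness_map(m, 0.1)
        mean = t[m.astype(bool)].mean()
        assert abs(mean - 5 * 0.1) <= 0.1  # within one voxel

    def test_single_voxel(self):
        m = np.zeros((7, 7, 7), np.uint8)
        m[3, 3, 3] = 1
        t = local_thickness_map(m, 1.0)
        assert t[3, 3, 3] == pytest.approx(1.0)

    def test_empty_mask_all_zero(self):
        t = local_thickness_map(np.zeros((4, 4, 4), np.uint8), 1.0)
        assert not t.any()

    def test_zero_outside_structure(self, random_blob):
        t = local_thickness_map(random_blob, 1.0)
        assert not t[~random_blob.astype(bool)].any()
        assert (t[random_blob.astype(bool)] > 0).all()

    def test_matches_brute_force_oracle(self, random_blob):
        ours = local_thickness_map(random_blob, 1.0)
        ref = brute_force_thickness(random_blob)
        assert np.abs(ours - ref).max() <= 1.0  # within one voxel everywhere

    def test_dilation_does_not_decrease_thickness(self, random_blob):
        from scipy import ndimage
        grown = ndimage.binary_dilation(random_blob.astype(bool))
        t0 = local_thickness_map(random_blob, 1.0)
        t1 = local_thickness_map(grown.astype(np.uint8), 1.0)
        sel = random_blob.astype(bool)
        assert t1[sel].mean() >= t0[sel].mean() - 1e-12


class TestMorphometryReport:
    def test_all_bone_tunnel(self):
        grid = VoxelGrid(np.full((4, 20, 20), 200.0), spacing=0.1)
        tun = np.zeros((4, 20, 20), np.uint8)
        tun[:, 5:15, 5:15] = 1
        res = morphometry_report(grid, LabelMask(tun),
                                 MorphometryConfig(bone_threshold=100.0))
        assert res.bvtv == 1.0
        assert res.tb_sp == 0.0

    @pytest.mark.parametrize("t_over_p", [0.3, 0.5])
    def test_plate_phantom_recovery(self, t_over_p):
        p, sp = 1.0, 0.1
        spec = PhantomSpec(shape=(50, 60, 60), spacing=sp,
                           plate_thickness_t=t_over_p * p, plate_period_p=p, seed=1)
        sample = make_lattice_phantom(spec)
        roi = LabelMask(cylinder_mask(spec.shape, sp, TunnelAxis(30, 30), 2.0).astype(np.uint8))
        res = morphometry_report(sample.grid, roi)
        assert abs(res.bvtv - t_over_p) <= 0.02
        assert abs(res.tb_th - t_over_p * p) <= sp + 1e-9
        assert abs(res.tb_sp - (p - t_over_p * p)) <= sp + 1e-9
        # odd-width plates/gaps: direct Tb.N recovers 1/p closely
        assert res.tb_n == pytest.approx(1.0 / p, abs=0.05)

    def test_plate_model_tbn_option(self):
        spec = PhantomSpec(shape=(40, 50, 50), spacing=0.1, plate_thickness_t=0.3, seed=2)
        sample = make_lattice_phantom(spec)
        roi = LabelMask(cylinder_mask(spec.shape, 0.1, TunnelAxis(25, 25), 1.5).astype(np.uint8))
        res = morphometry_report(sample.grid, roi, MorphometryConfig(tbn_method="plate"))
        assert res.tb_n == pytest.approx(res.bvtv / res.tb_th)

    def test_scale_equivariance(self):
        spec1 = PhantomSpec(shape=(30, 40, 40), spacing=0.1, plate_thickness_t=0.3, seed=5)
        spec2 = PhantomSpec(shape=(30, 40, 40), spacing=0.2, plate_thickness_t=0.3, seed=5)
        # identical voxel content, doubled spacing
        s1, s2 = make_lattice_phantom(spec1), make_lattice_phantom(spec2)
        roi1 = LabelMask(cylinder_mask(spec1.shape, 0.1, TunnelAxis(20, 20), 1.2).astype(np.uint8))
        roi2 = LabelMask(cylinder_mask(spec2.shape, 0.2, TunnelAxis(20, 20), 2.4).astype(np.uint8))
        np.testing.assert_array_equal(roi1.values, roi2.values)
        g2 = VoxelGrid(s1.grid.intensities, spacing=0.2)
        r1 = morphometry_report(s1.grid, roi1)
        r2 = morphometry_report(g2, roi2)
        assert r2.bvtv == pytest.approx(r1.bvtv)
        assert r2.tb_th == pytest.approx(2 * r1.tb_th)
        assert r2.tb_sp == pytest.approx(2 * r1.tb_sp)
        assert r2.tb_n == pytest.approx(r1.tb_n / 2)
        assert r2.volume == pytest.approx(8 * r1.volume)

    def test_empty_tunnel_rejected(self):
        grid = VoxelGrid(np.ones((2, 40, 40)), spacing=0.1)
        with pytest.raises(ValueError, match="empty tunnel"):
            morphometry_report(grid, LabelMask(np.zeros((2, 40, 40), np.uint8)))

    def test_units_volume_and_mgv(self):
        grid = VoxelGrid(np.full((4, 40, 40), 120.0), spacing=0.0607)
        tun = np.zeros((4, 40, 40), np.uint8)
        tun[:, 10:30, 10:30] = 1
        res = morphometry_report(grid, LabelMask(tun),
                                 MorphometryConfig(bone_threshold=50.0))
        assert res.volume == pytest.approx(int(tun.sum()) * 0.0607**3)
        assert res.mgv == pytest.approx(120.0)


class TestCropRoi:
    def test_center_crop(self):
        grid = VoxelGrid(np.arange(2 * 10 * 10, dtype=float).reshape(2, 10, 10), spacing=0.1)
        mask = LabelMask(np.ones((2, 10, 10), np.uint8))
        g, m = crop_roi(grid, mask, size=6)
        assert g.shape == (2, 6, 6) and m.shape == (2, 6, 6)
        np.testing.assert_array_equal(g.intensities, grid.intensities[:, 2:8, 2:8])

    def test_oversize_rejected(self):
        grid = VoxelGrid(np.zeros((1, 8, 8)), spacing=0.1)
        with pytest.raises(ValueError, match="exceeds"):
            crop_roi(grid, LabelMask(np.zeros((1, 8, 8), np.uint8)), size=16)
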