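"""Centerline extraction: circle inscription, reslicing, tracking, correction."""

import warnings

import numpy as np
import pytest
from scipy.spatial import cKDTree

from aortacalc.centerline import (
    Centerline,
    SeedError,
    TrackingConfig,
    extract_centerline,
    inscribe_circle,
    perpendicular_correction,
    reslice_oblique,
    track_arch,
    track_descending,
)
from aortacalc.phantom import default_phantom_spec, generate_phantom
from aortacalc.volume import CTVolume

from conftest import cylinder_volume


def _disk_image(radius_px=20, n=64, spacing=(1.0, 1.0), lumen=40.0, bg=-100.0):
    img = np.full((n, n), bg, dtype=np.float32)
    ii, jj = np.indices((n, n))
    c = n // 2
    img[(ii - c) ** 2 + (jj - c) ** 2 <= radius_px**2] = lumen
    return img, np.array([c * spacing[0], c * spacing[1]]), radius_px * spacing[0]


class TestInscribeCircle:
    def test_recovers_disk_from_true_center(self, cfg):
        img, center, radius = _disk_image()
        c, r = inscribe_circle(img, (1.0, 1.0), center, cfg)
        assert np.linalg.norm(c - center) < 0.5
        assert abs(r - radius) < 0.5

    def test_recovers_disk_from_offset_seed(self, cfg):
        img, center, radius = _disk_image()
        seed = center + np.array([5.0, -3.0])
        c, r = inscribe_circle(img, (1.0, 1.0), seed, cfg)
        assert np.linalg.norm(c - center) < 0.5
        assert abs(r - radius) < 0.5

    def test_background_seed_raises(self, cfg):
        img, center, _ = _disk_image()
        with pytest.raises(SeedError):
            inscribe_circle(img, (1.0, 1.0), np.array([2.0, 2.0]), cfg)


class TestResliceOblique:
    def test_axial_aligned_plane_equals_axial_slice(self, clean_phantom):
        _, volume, _ = clean_phantom
        k = 20
        n = 41  # odd -> plane pixels land exactly on voxel centres
        cx = (volume.shape[0] // 2) * volume.spacing[0]
        cy = (volume.shape[1] // 2) * volume.spacing[1]
        origin = np.array([cx, cy, k * volume.spacing[2]])
        plane = reslice_oblique(volume, origin, [1, 0, 0], [0, 1, 0],
                                size_mm=(n - 1) * volume.spacing[0],
                                pixel_mm=volume.spacing[0])
        i0 = volume.shape[0] // 2 - (n - 1) // 2
        j0 = volume.shape[1] // 2 - (n - 1) // 2
        expected = volume.data[i0:i0 + n, j0:j0 + n, k]
        assert np.array_equal(plane.data, expected)

    def test_constant_volume_gives_constant_plane(self):
        vol = CTVolume(np.full((32, 32, 16), 7.0, dtype=np.float32), (1, 1, 2.5))
        plane = reslice_oblique(vol, [16, 16, 20], [1, 0, 0], [0, 0.6, 0.8],
                                size_mm=10, pixel_mm=0.5)
        assert np.allclose(plane.data, 7.0)

    def test_linear_ramp_sampled_exactly_on_oblique_plane(self):
        # trilinear interpolation reproduces a linear field exactly
        nx = 64
        data = np.broadcast_to(np.arange(nx, dtype=np.float32)[:, None, None] * 3.0,
                               (nx, 32, 32)).copy()
        vol = CTVolume(data, (1.0, 1.0, 1.0))
        e1 = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)  # 45° plane
        e2 = np.array([0.0, 1.0, 0.0])
        plane = reslice_oblique(vol, [32, 16, 16], e1, e2, size_mm=10, pixel_mm=0.5)
        npx = plane.data.shape[0]
        uv = (np.arange(npx) - (npx - 1) / 2) * 0.5
        expected_x = 32 + uv / np.sqrt(2)
        assert np.allclose(plane.data, (expected_x * 3.0)[:, None], atol=1e-6)

    def test_degenerate_axes_raise(self, clean_phantom):
        _, volume, _ = clean_phantom
        with pytest.raises(ValueError, match="degenerate"):
            reslice_oblique(volume, [10, 10, 10], [1, 0, 0], [2, 0, 0], 10, 0.5)


class TestTrackDescending:
    def test_vertical_cylinder_one_point_per_slice(self, cfg):
        vol, axis_at = cylinder_volume()
        start = axis_at(40 * 2.5)  # slice index 40
        points = track_descending(vol, start, cfg)
        assert len(points) == 41  # start slice plus 40 below
        for p in points:
            true = axis_at(p.position[2])
            assert np.linalg.norm(p.position[:2] - true[:2]) < 0.5

    def test_tilted_cylinder_centers_on_axis_after_correction(self, cfg):
        vol, axis_at = cylinder_volume(tilt_deg=10.0)
        start = axis_at(40 * 2.5)
        points = track_descending(vol, start, cfg)
        corrected = perpendicular_correction(Centerline(list(reversed(points))), vol, cfg)
        for pos in corrected.positions[3:-3]:  # end caps clip the oblique planes
            true = axis_at(pos[2])
            assert np.linalg.norm(pos[:2] - true[:2]) < 1.0

    def test_seed_on_bottom_slice_gives_single_point(self, cfg):
        vol, axis_at = cylinder_volume()
        points = track_descending(vol, axis_at(0.0), cfg)
        assert len(points) == 1


class TestTrackArch:
    def test_default_sweep_has_121_planes(self, clean_phantom, cfg):
        _, volume, gt = clean_phantom
        points, thetas = track_arch(volume, gt.seeds["C_A"], gt.seeds["C_D"], cfg)
        assert len(points) == 121
        assert thetas[0] == 0.0 and thetas[-1] == 240.0

    def test_zero_span_gives_single_plane(self, clean_phantom):
        _, volume, gt = clean_phantom
        cfg0 = TrackingConfig(angular_span_deg=0.0)
        points, thetas = track_arch(volume, gt.seeds["C_A"], gt.seeds["C_D"], cfg0)
        assert len(points) == 1 and thetas.tolist() == [0.0]

    def test_torus_centers_and_diameters(self, cfg):
        spec = default_phantom_spec(shape=(128, 128, 64), spacing=(1.0, 1.0, 2.5),
                                    lumen_diameter_mm=25.0)
        volume, gt = generate_phantom(spec)
        points, _ = track_arch(volume, gt.seeds["C_A"], gt.seeds["C_D"], cfg)
        s = np.linspace(0, spec.total_length, 20000)
        tree = cKDTree(spec.centerline_point(s))
        pos = np.array([p.position for p in points])
        d, _ = tree.query(pos)
        assert d.max() < 1.0  # within one in-plane voxel of the analytic path
        arch_pts = [p for p in points if p.position[2] > spec.arch_center[2]]
        diam = np.array([p.diameter for p in arch_pts])
        assert np.median(np.abs(diam - 25.0)) < 1.0


class TestPerpendicularCorrection:
    def test_tilted_cylinder_diameters_within_2pct(self, cfg):
        # near-isotropic voxels so the check isolates the geometric
        # obliquity effect from axial partial volume
        vol, axis_at = cylinder_volume(tilt_deg=20.0, radius=15.0,
                                       shape=(96, 96, 100), spacing=(1.0, 1.0, 1.0))
        points = track_descending(vol, axis_at(50.0), cfg)
        raw = Centerline(list(reversed(points)))
        corrected = perpendicular_correction(raw, vol, cfg)
        # the perpendicular section spans ±r·sin(tilt) in z, so sections
        # within ~6 mm of the end caps are clipped by the volume boundary
        inner = slice(8, -8)
        assert np.all(np.abs(corrected.diameters[inner] - 30.0) / 30.0 < 0.02)
        # uncorrected axial sections overestimate the tilted diameter
        assert np.median(raw.diameters[inner]) >= np.median(corrected.diameters[inner])

    def test_vertical_cylinder_is_a_fixed_point(self, cfg):
        vol, axis_at = cylinder_volume()
        points = track_descending(vol, axis_at(40 * 2.5), cfg)
        raw = Centerline(list(reversed(points)))
        corrected = perpendicular_correction(raw, vol, cfg)
        assert np.allclose(corrected.positions[:, :2], raw.positions[:, :2], atol=0.5)
        assert np.allclose(corrected.diameters, raw.diameters, atol=0.5)
        assert np.all(np.abs(np.einsum("ij,ij->i", corrected.normals,
                                       corrected.normals)) >= 0.99)


class TestExtractCenterline:
    def test_point_count_and_accuracy(self, lesion_phantom, tracked):
        spec, _, _ = lesion_phantom
        cl, _ = tracked
        assert 140 <= len(cl) <= 220
        s = np.linspace(0, spec.total_length, 40000)
        tree = cKDTree(spec.centerline_point(s))
        d, _ = tree.query(cl.positions)
        assert np.median(d) < 0.5
        assert np.all(np.diff(cl.arc) > 0)
        assert abs(cl.total_length - spec.total_length) / spec.total_length < 0.02

    def test_bitwise_determinism(self, clean_phantom, cfg):
        _, volume, gt = clean_phantom
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = extract_centerline(volume, gt.seeds["C_A"], gt.seeds["C_D"], cfg)
            b = extract_centerline(volume, gt.seeds["C_A"], gt.seeds["C_D"], cfg)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.diameters, b.diameters)

    def test_mirror_symmetry(self, clean_phantom, cfg):
        _, volume, gt = clean_phantom
        flipped = CTVolume(volume.data[::-1].copy(), volume.spacing, volume.origin)
        xmax = (volume.shape[0] - 1) * volume.spacing[0]

        def mirror(p):
            return np.array([xmax - p[0], p[1], p[2]])

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cl = extract_centerline(volume, gt.seeds["C_A"], gt.seeds["C_D"], cfg)
            clm = extract_centerline(flipped, mirror(gt.seeds["C_A"]),
                                     mirror(gt.seeds["C_D"]), cfg)
        assert len(cl) == len(clm)
        mirrored = np.array([mirror(p) for p in clm.positions])
        assert np.allclose(cl.positions, mirrored, atol=0.05)

    def test_robust_to_noise(self, cfg):
        spec = default_phantom_spec(shape=(128, 128, 64), spacing=(1.0, 1.0, 2.5),
                                    noise_sd=20.0, seed=21)
        volume, gt = generate_phantom(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cl = extract_centerline(volume, gt.seeds["C_A"], gt.seeds["C_D"], cfg)
        s = np.linspace(0, spec.total_length, 40000)
        tree = cKDTree(spec.centerline_point(s))
        d, _ = tree.query(cl.positions)
        assert np.median(d) < 1.0  # within one in-plane voxel

    def test_robust_to_seed_perturbation(self, clean_phantom, cfg):
        spec, volume, gt = clean_phantom
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = extract_centerline(volume, gt.seeds["C_A"], gt.seeds["C_D"], cfg)
            moved = extract_centerline(volume,
                                       gt.seeds["C_A"] + np.array([2.0, 2.0, 0.0]),
                                       gt.seeds["C_D"] + np.array([-2.0, 1.0, 0.0]), cfg)
        tree = cKDTree(base.positions)
        d, _ = tree.query(moved.positions)
        assert np.median(d) < 0.5
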