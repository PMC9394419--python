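"""Registration preprocessing, initializers, metric and affine recovery."""

import numpy as np
import pytest
import SimpleITK as sitk
from scipy import ndimage

from trusfit import (
    AffineTransform3D,
    BinaryMask3D,
    ImageVolume,
    LandmarkSet,
    apply_transform,
    crop_voi,
    dsc,
    gaussian_smooth,
    init_center,
    init_landmarks,
    make_registration_pair,
    register,
    resample_isotropic,
    signed_distance_map,
    ssd,
)


def cube_mask(shape=(41, 41, 41), lo=18, hi=23, spacing=(1.0, 1.0, 1.0)):
    a = np.zeros(shape, np.uint8)
    a[lo:hi, lo:hi, lo:hi] = 1
    return BinaryMask3D(data=a, spacing=spacing)


def rigid_perturbation(mask, angle_deg, translation):
    ang = np.deg2rad(angle_deg)
    c, s = np.cos(ang), np.sin(ang)
    rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    center = np.asarray(mask.origin) + np.array(mask.data.shape[::-1]) / 2 * np.asarray(
        mask.spacing
    )
    return AffineTransform3D(matrix=rot, translation=translation, center=center)


class TestCropVoi:
    def test_single_voxel_margin_ten(self):
        a = np.zeros((41, 41, 41), np.uint8)
        a[20, 20, 20] = 1
        out = crop_voi(BinaryMask3D(data=a), margin_mm=10)
        assert out.data.shape == (21, 21, 21)
        assert out.data.sum() == 1

    def test_clips_at_image_border(self):
        a = np.zeros((15, 15, 15), np.uint8)
        a[0:3, 0:3, 0:3] = 1
        out = crop_voi(BinaryMask3D(data=a), margin_mm=10)
        assert out.data.shape == (13, 13, 13)  # clipped low side, padded high side
        assert out.data.sum() == 27

    def test_foreground_preserved_and_origin_shifted(self):
        m = cube_mask()
        out = crop_voi(m, margin_mm=5)
        assert out.data.sum() == m.data.sum()
        assert out.origin == (13.0, 13.0, 13.0)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            crop_voi(BinaryMask3D(data=np.zeros((5, 5, 5), np.uint8)))


class TestResample:
    def test_extent_arithmetic(self):
        m = cube_mask(shape=(10, 10, 10), lo=3, hi=7)
        out = resample_isotropic(m, res_mm=0.3, mode="nearest")
        assert out.data.shape == (33, 33, 33)
        assert out.spacing == (0.3, 0.3, 0.3)

    def test_binary_stays_binary(self):
        out = resample_isotropic(cube_mask(), res_mm=0.7, mode="nearest")
        assert set(np.unique(out.data)) <= {0, 1}

    def test_constant_volume_stays_constant(self):
        v = ImageVolume(data=np.full((8, 8, 8), 3.5), spacing=(1.2, 0.8, 2.0))
        out = resample_isotropic(v, res_mm=0.5, mode="linear")
        assert np.allclose(out.data, 3.5)

    def test_invalid_resolution(self):
        with pytest.raises(ValueError):
            resample_isotropic(cube_mask(), res_mm=-1)


class TestGaussianSmooth:
    def test_range_symmetry_and_mass(self):
        m = cube_mask()
        out = gaussian_smooth(m, sigma=3)
        assert out.data.min() >= 0 and out.data.max() <= 1
        # cube is centrally symmetric, so the smoothed field must be too
        assert np.allclose(out.data, out.data[::-1, ::-1, ::-1], atol=1e-12)
        assert abs(out.data.sum() - m.data.sum()) / m.data.sum() < 1e-3

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            gaussian_smooth(cube_mask(), sigma=0)


class TestSignedDistanceMap:
    def test_cube_geometry(self):
        a = np.zeros((15, 15, 15), np.uint8)
        a[3:12, 3:12, 3:12] = 1
        sdm = signed_distance_map(BinaryMask3D(data=a))
        assert sdm.data[3, 3, 3] == 0.0  # boundary voxel
        assert -4 <= sdm.data[7, 7, 7] <= -3  # deep interior of a 9-cube
        assert sdm.data[0, 7, 7] == pytest.approx(3.0)  # outside, 3 voxels away

    def test_matches_brute_force_on_random_blobs(self, rng):
        """Exact distance (mm) to the nearest 6-connectivity boundary voxel."""
        for _ in range(5):
            a = ndimage.gaussian_filter(rng.normal(size=(16, 16, 16)), 2) > 0
            if not a.any() or a.all():
                continue
            spacing = (0.8, 1.0, 1.7)
            sdm = signed_distance_map(BinaryMask3D(data=a.astype(np.uint8), spacing=spacing))
            struct = ndimage.generate_binary_structure(3, 1)
            boundary = a & ~ndimage.binary_erosion(a, struct, border_value=0)
            coords = np.argwhere(boundary) * np.array([spacing[2], spacing[1], spacing[0]])
            grid = np.indices(a.shape).reshape(3, -1).T * np.array(
                [spacing[2], spacing[1], spacing[0]]
            )
            brute = np.sqrt(((grid[:, None, :] - coords[None, :, :]) ** 2).sum(-1)).min(1)
            brute = brute.reshape(a.shape)
            brute[a] *= -1
            assert np.abs(sdm.data - brute).max() < 1e-6

    def test_agrees_with_maurer_filter(self):
        """Cross-check against the ITK signed Maurer distance transform."""
        a = np.zeros((12, 12, 12), np.uint8)
        a[4:9, 3:8, 5:10] = 1
        m = BinaryMask3D(data=a)
        sdm = signed_distance_map(m)
        img = sitk.GetImageFromArray(a)
        img.SetSpacing((1.0, 1.0, 1.0))
        ref = sitk.GetArrayFromImage(
            sitk.SignedMaurerDistanceMap(
                img, insideIsPositive=False, squaredDistance=False, useImageSpacing=True
            )
        )
        assert np.abs(sdm.data - ref).max() <= 0.5 + 1e-9

    def test_empty_or_full_raises(self):
        with pytest.raises(ValueError):
            signed_distance_map(BinaryMask3D(data=np.zeros((4, 4, 4), np.uint8)))
        with pytest.raises(ValueError):
            signed_distance_map(BinaryMask3D(data=np.ones((4, 4, 4), np.uint8)))


class TestInitializers:
    def test_center_identical_geometry_zero_translation(self):
        v = ImageVolume(data=np.zeros((8, 8, 8)), spacing=(1, 1, 1), origin=(0, 0, 0))
        t = init_center(v, v)
        assert np.allclose(t.translation, 0)
        assert np.allclose(t.matrix, np.eye(3))

    def test_center_origin_shift(self):
        f = ImageVolume(data=np.zeros((8, 8, 8)), origin=(0, 0, 0))
        m = ImageVolume(data=np.zeros((8, 8, 8)), origin=(5.0, 0, 0))
        t = init_center(f, m)
        assert np.allclose(t.translation, (5.0, 0, 0))

    def test_center_uses_physical_coordinates(self):
        a = ImageVolume(data=np.zeros((9, 9, 9)), spacing=(1, 1, 1))
        b = ImageVolume(data=np.zeros((9, 9, 9)), spacing=(2, 2, 2))
        assert np.allclose(b.geometric_center(), 2 * a.geometric_center())

    def test_landmarks_identity_and_translation(self):
        pts = {"UB": (0, 0, 40.0), "VM": (2.0, -3.0, 20.0), "UA": (1.0, 4.0, 0.0)}
        f = LandmarkSet(points=pts)
        t = init_landmarks(f, f)
        assert np.allclose(t.matrix, np.eye(3), atol=1e-12)
        assert np.allclose(t.translation, 0, atol=1e-12)
        shifted = LandmarkSet(points={k: np.asarray(v) + [2.0, 0, 0] for k, v in pts.items()})
        t2 = init_landmarks(f, shifted)
        assert np.allclose(t2.apply_points(list(pts.values())) - list(shifted.points.values()),
                           0, atol=1e-12)

    def test_landmarks_recover_known_rotation(self):
        """Closed-form Procrustes reproduces a pure 20-degree rotation."""
        ang = np.deg2rad(20.0)
        c, s = np.cos(ang), np.sin(ang)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        fixed = np.array([[10.0, 0, 0], [0, 12.0, 0], [0, 0, 9.0], [4.0, 4.0, 4.0]])
        moving = fixed @ rot.T
        t = init_landmarks(
            LandmarkSet(points={str(i): p for i, p in enumerate(fixed)}),
            LandmarkSet(points={str(i): p for i, p in enumerate(moving)}),
        )
        recovered = t.as_matrix4()[:3, :3]
        assert np.abs(recovered - rot).max() < 1e-6

    def test_landmarks_need_three_noncollinear(self):
        a = LandmarkSet(points={"A": (0, 0, 0), "B": (1, 1, 1)})
        with pytest.raises(ValueError):
            init_landmarks(a, a)
        line = LandmarkSet(points={"A": (0, 0, 0), "B": (1, 1, 1), "C": (2, 2, 2)})
        with pytest.raises(ValueError):
            init_landmarks(line, line)


class TestSSD:
    def test_closed_forms_and_oracle(self, rng):
        a = ImageVolume(data=rng.normal(size=(6, 6, 6)))
        assert ssd(a, a) == 0.0
        b = ImageVolume(data=a.data + 2.0)
        assert ssd(a, b) == pytest.approx(6**3 * 4.0)
        c = ImageVolume(data=rng.normal(size=(6, 6, 6)))
        naive = sum(
            (a.data[i, j, k] - c.data[i, j, k]) ** 2
            for i in range(6) for j in range(6) for k in range(6)
        )
        assert ssd(a, c) == pytest.approx(naive)

    def test_grid_mismatch(self):
        a = ImageVolume(data=np.zeros((4, 4, 4)))
        b = ImageVolume(data=np.zeros((4, 4, 4)), spacing=(2, 2, 2))
        with pytest.raises(ValueError):
            ssd(a, b)


class TestApplyTransform:
    def test_identity_preserves_mask(self):
        m = cube_mask()
        out = apply_transform(m, AffineTransform3D(), m)
        assert np.array_equal(out.data, m.data)

    def test_integer_translation_exact_shift(self):
        m = cube_mask()
        t = AffineTransform3D(translation=(3.0, 0.0, 0.0))
        out = apply_transform(m, t, m)
        assert np.array_equal(out.data[:, :, :-3], m.data[:, :, 3:])

    def test_roundtrip_through_inverse(self):
        m = cube_mask()
        t = rigid_perturbation(m, 12.0, (2.3, -1.1, 0.7))
        fwd = apply_transform(m, t, m)
        back = apply_transform(fwd, t.inverse(), m)
        assert dsc(back, m) >= 0.98

    def test_singular_transform_rejected(self):
        with pytest.raises(ValueError):
            AffineTransform3D(matrix=np.zeros((3, 3)))


@pytest.mark.usefixtures("small_phantom")
class TestRegister:
    def test_self_registration_is_identity(self, small_phantom):
        _, mask, _ = small_phantom
        res = register(mask, mask, init="center", res_mm=0.6, max_iterations=50)
        aligned = apply_transform(mask, res.transform, mask)
        assert dsc(aligned, mask) >= 0.999
        assert res.final_metric <= res.initial_metric

    def test_recovers_rigid_perturbation(self, small_phantom):
        _, mask, _ = small_phantom
        perturb = rigid_perturbation(mask, 8.0, (5.0, -4.0, 2.0))
        fixed, moving, true_t = make_registration_pair(mask, perturb)
        res = register(fixed, moving, init="center", res_mm=0.6)
        aligned = apply_transform(moving, res.transform, fixed)
        assert dsc(aligned, fixed) >= 0.97
        assert res.final_metric <= res.initial_metric
        center = np.asarray(mask.origin) + np.array(mask.data.shape[::-1]) / 2 * np.asarray(
            mask.spacing
        )
        resid = true_t.compose(res.transform).apply_points([center])[0] - center
        assert np.linalg.norm(resid) <= 0.6  # one coarse voxel at this resolution

    def test_center_and_landmark_inits_agree(self, small_phantom):
        """The two initializers converge to closely matching overlaps."""
        _, mask, _ = small_phantom
        perturb = rigid_perturbation(mask, 5.0, (3.0, 2.0, -1.5))
        fixed, moving, true_t = make_registration_pair(mask, perturb)
        lm_fixed = {"UB": (24.0, 24.0, 30.0), "VM": (22.0, 28.0, 16.0), "UA": (25.0, 23.0, 2.0)}
        inv = true_t.inverse()
        lm_moving = {k: inv.apply_points([v])[0] for k, v in lm_fixed.items()}
        res_c = register(fixed, moving, init="center", res_mm=0.6)
        res_l = register(
            fixed,
            moving,
            init="landmarks",
            landmarks=(LandmarkSet(points=lm_fixed), LandmarkSet(points=lm_moving)),
            res_mm=0.6,
        )
        d_c = dsc(apply_transform(moving, res_c.transform, fixed), fixed)
        d_l = dsc(apply_transform(moving, res_l.transform, fixed), fixed)
        assert abs(d_c - d_l) <= 0.02

    def test_landmark_init_requires_landmarks(self, small_phantom):
        _, mask, _ = small_phantom
        with pytest.raises(ValueError):
            register(mask, mask, init="landmarks")
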