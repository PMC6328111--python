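import numpy as np
import pytest
from scipy import ndimage

from nodulecad.volume_io import CTVolume
from nodulecad.feature_extraction import (FEATURE_NAMES, SELECTED_FEATURES,
                                          gray_features, surface_voxels,
                                          surface_gradient_features,
                                          shell_gradient_features, inertia_tensor,
                                          shape_features, feature_vector,
                                          select_features)
from tests.conftest import make_candidate, ball_mask


def _smoothed_ball_volume(shape=(40, 40, 40), center=(20, 20, 20), r=6,
                          value=0.7, bg=0.15):
    solid = np.where(ball_mask(shape, center, r), value, 0.0)
    data = np.maximum(bg, ndimage.gaussian_filter(solid, 1.0))
    return CTVolume(data, normalized=True), ball_mask(shape, center, r)


class TestGrayFeatures:
    def test_constant_candidate(self):
        vol = CTVolume(np.full((6, 6, 6), 0.42))
        m = ball_mask((6, 6, 6), (3, 3, 3), 2)
        f = gray_features(make_candidate(m), vol)
        assert (f["gray_level_max"], f["gray_level_min"], f["gray_level_mean"],
                f["gray_level_std"]) == pytest.approx((0.42, 0.42, 0.42, 0.0))

    def test_two_point_statistics(self):
        vol = CTVolume(np.zeros((1, 1, 2)))
        vol.data[0, 0] = [0.2, 0.8]
        m = np.ones((1, 1, 2), bool)
        f = gray_features(make_candidate(m), vol)
        assert (f["gray_level_max"], f["gray_level_min"], f["gray_level_mean"],
                f["gray_level_std"]) == pytest.approx((0.8, 0.2, 0.5, 0.3))

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(0)
        vol = CTVolume(rng.random((10, 10, 10)))
        m = rng.random((10, 10, 10)) < 0.3
        f = gray_features(make_candidate(m), vol)
        vals = [vol.data[tuple(v)] for v in np.argwhere(m)]
        assert f["gray_level_mean"] == pytest.approx(np.mean(vals))
        assert f["gray_level_std"] == pytest.approx(np.std(vals))


class TestSurfaceVoxels:
    def test_cube_surface(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:4, 1:4, 1:4] = True
        assert len(surface_voxels(make_candidate(m))) == 26

    def test_single_voxel(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        surf = surface_voxels(make_candidate(m))
        np.testing.assert_array_equal(surf, [[1, 1, 1]])

    def test_sphere_surface_matches_naive_neighbor_scan(self):
        m = ball_mask((16, 16, 16), (8, 8, 8), 5)
        surf = {tuple(v) for v in surface_voxels(make_candidate(m))}
        # brute-force oracle: scan the 26-neighborhood of every voxel
        expected = set()
        for v in map(tuple, np.argwhere(m)):
            for dz in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        if (dz, dy, dx) == (0, 0, 0):
                            continue
                        p = (v[0] + dz, v[1] + dy, v[2] + dx)
                        if not (0 <= p[0] < 16 and 0 <= p[1] < 16 and 0 <= p[2] < 16) \
                                or not m[p]:
                            expected.add(v)
        assert surf == expected


class TestSurfaceGradients:
    def test_symmetric_blob_statistics(self):
        # radial symmetry: tight magnitude distribution; the residual negative
        # skew (~-1) is a lattice-surface artifact common to all blobs
        vol, m = _smoothed_ball_volume(shape=(44, 44, 44), center=(22, 22, 22),
                                       r=8)
        f = surface_gradient_features(make_candidate(m), vol)
        assert f["SurG_std"] / f["SurG_mean"] < 0.2
        assert abs(f["SurG_skewness"]) < 1.5

    def test_attached_stub_breaks_symmetry(self):
        # a vessel stub skews the surface-gradient distribution well beyond
        # the isolated sphere's lattice baseline
        shape = (44, 44, 60)
        m = ball_mask(shape, (22, 22, 22), 8)
        solid = np.where(m, 0.7, 0.0)
        vol = CTVolume(np.maximum(0.15, ndimage.gaussian_filter(solid, 1.5)),
                       normalized=True)
        stub = np.zeros(shape, bool)
        stub[19:26, 19:26, 28:50] = True
        solid2 = np.where(m | stub, 0.7, 0.0)
        vol2 = CTVolume(np.maximum(0.15, ndimage.gaussian_filter(solid2, 1.5)),
                        normalized=True)
        f_iso = surface_gradient_features(make_candidate(m), vol)
        f_stub = surface_gradient_features(make_candidate(m | stub), vol2)
        assert f_stub["SurG_skewness"] < f_iso["SurG_skewness"] - 0.3

    def test_uniform_gradient_degenerate_moments(self):
        # linear ramp: every surface voxel sees the same gradient magnitude
        zz = np.arange(20, dtype=float)[:, None, None] * 0.01
        vol = CTVolume(np.tile(zz, (1, 20, 20)))
        m = np.zeros((20, 20, 20), bool)
        m[8:12, 8:12, 8:12] = True
        f = surface_gradient_features(make_candidate(m), vol)
        assert f["SurG_std"] == pytest.approx(0.0, abs=1e-12)
        assert f["SurG_skewness"] == 0.0 and f["SurG_kurtosis"] == 0.0

    def test_too_few_surface_voxels_rejected(self):
        vol = CTVolume(np.zeros((3, 3, 3)))
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        with pytest.raises(ValueError):
            surface_gradient_features(make_candidate(m), vol)


class TestShellGradients:
    def test_bright_sphere_is_radial(self):
        vol, m = _smoothed_ball_volume()
        f = shell_gradient_features(make_candidate(m), vol)
        assert f["ShellGD_med"] > 0.8
        assert 0.0 <= f["ShellGD_min_max_sq"] <= 1.0
        assert 0.0 <= f["ShellGD_med_max_sq"] <= 1.0

    def test_tube_composite_less_radial(self):
        shape = (44, 44, 60)
        m = ball_mask(shape, (22, 22, 30), 8)
        vol = CTVolume(np.maximum(0.15, ndimage.gaussian_filter(
            np.where(m, 0.7, 0.0), 1.5)), normalized=True)
        zz, yy, xx = np.mgrid[:shape[0], :shape[1], :shape[2]]
        tube = (zz - 22) ** 2. + (yy - 22) ** 2. <= 25.
        vol2 = CTVolume(np.maximum(0.15, ndimage.gaussian_filter(
            np.where(m | tube, 0.7, 0.0), 1.5)), normalized=True)
        f_iso = shell_gradient_features(make_candidate(m), vol)
        f_comp = shell_gradient_features(make_candidate(m), vol2)
        assert f_comp["ShellGD_med"] < f_iso["ShellGD_med"] - 0.005


class TestInertiaTensor:
    def test_uniform_sphere_equal_eigenvalues(self):
        m = ball_mask((30, 30, 30), (15, 15, 15), 8)
        vol = CTVolume(np.where(m, 1.0, 0.0))
        ev = inertia_tensor(make_candidate(m), vol).eigenvalues
        assert np.ptp(ev) / ev.max() < 0.02

    def test_single_voxel_zero_tensor(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        it = inertia_tensor(make_candidate(m), CTVolume(np.ones((3, 3, 3))))
        np.testing.assert_allclose(it.matrix, 0.0, atol=1e-12)

    def test_cuboid_matches_closed_form(self):
        # uniform 2x2x8 box: I = M/12 * (a^2+b^2) per axis with the
        # discrete-uniform variance correction (n^2-1)/12 per side
        m = np.zeros((6, 6, 12), bool)
        m[2:4, 2:4, 2:10] = True
        vol = CTVolume(np.ones(m.shape))
        ev = np.sort(inertia_tensor(make_candidate(m), vol).eigenvalues)
        M = m.sum()
        var = {n: (n ** 2 - 1) / 12.0 for n in (2, 8)}
        expected = np.sort([M * (var[2] + var[8]), M * (var[2] + var[8]),
                            M * (var[2] + var[2])])
        np.testing.assert_allclose(ev, expected, rtol=1e-9)


class TestShapeFeatures:
    def test_sphere_ratios_one(self):
        m = ball_mask((30, 30, 30), (15, 15, 15), 8)
        vol = CTVolume(np.where(m, 1.0, 0.0))
        f = shape_features(make_candidate(m), vol)
        assert f["elongation_shape"] == pytest.approx(1.0, abs=0.02)
        assert f["flatness_shape"] == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("r", [5, 10])
    def test_sphere_non_compactness_closed_form(self, r):
        # (8*pi/5) r^5 / ((4*pi/3) r^3)^(5/3) ~ 0.4618, radius-invariant
        n = 2 * r + 6
        m = ball_mask((n, n, n), (n // 2,) * 3, r)
        vol = CTVolume(np.where(m, 1.0, 0.0))
        f = shape_features(make_candidate(m), vol)
        expected = (8 * np.pi / 5) / (4 * np.pi / 3) ** (5 / 3)
        assert f["non_compactness"] == pytest.approx(expected, rel=0.05)

    def test_rod_and_disc_eigenvalue_ratios(self):
        # inertia-tensor geometry: a rod has two large equal moments (about
        # the transverse axes) and one small one, so the rod signal lives in
        # e2/e3; a flat disc has one large moment (about its normal), so the
        # disc signal lives in e1/e2 (= 2 for an ideal disc)
        rod = np.zeros((6, 6, 20), bool)
        rod[2:4, 2:4, 2:18] = True  # 2x2x16
        vol = CTVolume(np.ones(rod.shape))
        f = shape_features(make_candidate(rod), vol)
        assert f["elongation_shape"] == pytest.approx(1.0, abs=0.01)
        assert f["flatness_shape"] > 3
        disc = np.zeros((6, 40, 40), bool)
        yy, xx = np.ogrid[:40, :40]
        disc[2] = (yy - 20) ** 2 + (xx - 20) ** 2 <= 15 ** 2
        f2 = shape_features(make_candidate(disc), CTVolume(np.ones(disc.shape)))
        assert f2["elongation_shape"] == pytest.approx(2.0, rel=0.1)
        assert f2["flatness_shape"] == pytest.approx(1.0, abs=0.05)


class TestFeatureVector:
    def test_canonical_order_and_length(self):
        vol, m = _smoothed_ball_volume()
        fv = feature_vector(make_candidate(m), vol)
        assert list(fv) == list(FEATURE_NAMES)
        assert len(fv) == 27

    def test_selected_subset_is_16(self):
        vol, m = _smoothed_ball_volume()
        sel = select_features(feature_vector(make_candidate(m), vol))
        assert list(sel) == list(SELECTED_FEATURES)
        assert len(sel) == 16

    def test_translation_invariance(self):
        vol, m = _smoothed_ball_volume(shape=(50, 50, 50), center=(20, 20, 20))
        shift = (7, 9, 11)
        vol2 = CTVolume(np.roll(vol.data, shift, axis=(0, 1, 2)), normalized=True)
        m2 = np.roll(m, shift, axis=(0, 1, 2))
        f1 = feature_vector(make_candidate(m), vol)
        f2 = feature_vector(make_candidate(m2), vol2)
        for name in FEATURE_NAMES:
            assert f1[name] == pytest.approx(f2[name], rel=1e-6, abs=1e-9), name

    def test_intensity_scaling_leaves_eigen_ratios(self):
        vol, m = _smoothed_ball_volume()
        doubled = CTVolume(vol.data * 2.0)
        c = make_candidate(m)
        f1, f2 = shape_features(c, vol), shape_features(c, doubled)
        assert f1["elongation_shape"] == pytest.approx(f2["elongation_shape"], rel=1e-9)
        assert f1["flatness_shape"] == pytest.approx(f2["flatness_shape"], rel=1e-9)
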