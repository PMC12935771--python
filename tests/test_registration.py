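"""Thin-plate-spline registration, stacking, affine fits, Dice QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import histopet as hp
from histopet.phantom import upsample_labels
from histopet.registration import (
    LandmarkSet,
    apply_transform_2d,
    dice_coefficient,
    fit_affine_3d,
    fit_tps,
    stack_sections,
)


class TestFitTps:
    def test_identity_landmarks_give_identity(self, rng):
        src = rng.uniform(0, 30, (8, 2))
        tps = fit_tps(LandmarkSet(src, src))
        np.testing.assert_allclose(tps.affine, np.eye(2), atol=1e-9)
        np.testing.assert_allclose(tps.offset, 0, atol=1e-8)
        assert np.abs(tps.weights).max() < 1e-9

    def test_pure_translation_exact_everywhere(self, rng):
        src = rng.uniform(0, 30, (6, 2))
        tps = fit_tps(LandmarkSet(src, src + [2.0, 0.0]))
        probes = rng.uniform(-5, 35, (40, 2))
        np.testing.assert_allclose(tps(probes), probes + [2.0, 0.0], atol=1e-8)

    def test_interpolates_landmarks_exactly_at_lambda_zero(self):
        warp = hp.random_smooth_warp((40, 40), max_disp_mm=2.5,
                                     n_landmarks=12, landmark_jitter_sd=0.0,
                                     seed=9)
        lms = LandmarkSet(warp.landmark_src, warp.landmark_dst)
        tps = fit_tps(lms, 0.0)
        err = np.linalg.norm(tps(lms.src) - lms.dst, axis=1).max()
        assert err <= 1e-6
        assert tps.side_condition_residual() <= 1e-8

    def test_held_out_correspondences(self):
        rng = np.random.default_rng(4)
        warp = hp.random_smooth_warp((40, 40), max_disp_mm=2.5,
                                     n_landmarks=12, landmark_jitter_sd=0.0,
                                     seed=4)
        tps = fit_tps(LandmarkSet(warp.landmark_src, warp.landmark_dst))
        q = rng.uniform(8, 32, (50, 2))
        p = warp.transform(q)
        err = np.linalg.norm(tps(p) - q, axis=1).mean()
        mean_disp = np.linalg.norm(warp.displacement(q), axis=1).mean()
        assert err < 0.15 * mean_disp

    def test_three_landmarks_reduce_to_affine(self):
        src = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        dst = np.array([[1.0, 2.0], [12.0, 1.0], [0.5, 13.0]])
        tps = fit_tps(LandmarkSet(src, dst))
        assert np.abs(tps.weights).max() <= 1e-8

    def test_collinear_sources_rejected(self):
        src = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            fit_tps(LandmarkSet(src, src))

    def test_duplicate_sources_rejected_at_lambda_zero(self):
        src = np.array([[0, 0], [0, 0], [1, 5], [4, 2]], dtype=float)
        with pytest.raises(ValueError, match="duplicate"):
            fit_tps(LandmarkSet(src, src))

    def test_regularization_trades_interpolation_for_smoothness(self):
        warp = hp.random_smooth_warp((40, 40), max_disp_mm=2.0,
                                     n_landmarks=12, landmark_jitter_sd=0.0,
                                     seed=2)
        lms = LandmarkSet(warp.landmark_src, warp.landmark_dst)
        exact = fit_tps(lms, 0.0)
        smooth = fit_tps(lms, 10.0)
        res_exact = np.linalg.norm(exact(lms.src) - lms.dst, axis=1).max()
        res_smooth = np.linalg.norm(smooth(lms.src) - lms.dst, axis=1).max()
        assert res_exact < 1e-6 < res_smooth

    def test_matches_scipy_rbf_interpolator(self):
        # independent cross-check of the TPS solve/evaluate path
        from scipy.interpolate import RBFInterpolator
        warp = hp.random_smooth_warp((40, 40), max_disp_mm=2.0,
                                     n_landmarks=10, landmark_jitter_sd=0.0,
                                     seed=6)
        src, dst = warp.landmark_src, warp.landmark_dst
        tps = fit_tps(LandmarkSet(src, dst))
        rbf = RBFInterpolator(src, dst, kernel="thin_plate_spline", degree=1,
                              smoothing=0.0)
        probes = np.random.default_rng(0).uniform(5, 35, (30, 2))
        np.testing.assert_allclose(tps(probes), rbf(probes), atol=1e-8)

    def test_json_roundtrip(self):
        warp = hp.random_smooth_warp((30, 30), seed=1)
        tps = fit_tps(LandmarkSet(warp.landmark_src, warp.landmark_dst))
        clone = hp.TPSTransform.from_json(tps.to_json())
        probes = np.random.default_rng(1).uniform(0, 30, (10, 2))
        np.testing.assert_allclose(tps(probes), clone(probes), atol=1e-12)


class TestApplyTransform:
    def test_identity_returns_input(self, rng):
        img = rng.random((20, 25))
        tps = fit_tps(LandmarkSet(np.array([[0, 0], [20, 0], [0, 15], [20, 15]],
                                           dtype=float),
                                  np.array([[0, 0], [20, 0], [0, 15], [20, 15]],
                                           dtype=float)))
        out = apply_transform_2d(img, tps, img.shape, 1.0)
        np.testing.assert_allclose(out.grid, img, atol=1e-9)
        assert out.valid_mask.all()

    def test_one_cell_translation_shifts_content(self, rng):
        img = rng.random((12, 12))
        shift = lambda pts: pts + [1.0, 0.0]      # output x -> input x+1
        out = apply_transform_2d(img, shift, img.shape, 1.0,
                                 interpolation="nearest")
        np.testing.assert_allclose(out.grid[:, :-1], img[:, 1:])
        assert not out.valid_mask[:, -1].any()
        assert out.valid_mask[:, :-1].all()

    def test_unknown_interpolation_rejected(self, rng):
        img = rng.random((5, 5))
        with pytest.raises(ValueError, match="interpolation"):
            apply_transform_2d(img, lambda p: p, (5, 5), 1.0,
                               interpolation="cubic")


class TestClosedLoopRegistration:
    def _tissue(self, seed):
        lm = hp.generate_label_map((64, 64), 0.5, seed=seed)
        return upsample_labels(lm, 100.0) > 0    # 320x320 px at 0.1 mm

    @pytest.mark.parametrize("seed", range(3))
    def test_warp_register_dice_and_residuals(self, seed):
        tissue = self._tissue(seed)
        jitter = 0.1
        warp = hp.random_smooth_warp((32, 32), max_disp_mm=2.0,
                                     n_landmarks=12,
                                     landmark_jitter_sd=jitter, seed=seed)
        section, pairs = hp.warp_with_landmarks(
            tissue.astype(float), warp, seed=seed + 100, spacing_mm=0.1,
            interpolation="nearest")
        tps = fit_tps(pairs, 0.0)
        back = apply_transform_2d(section, tps, tissue.shape, 0.1,
                                  interpolation="nearest")
        d = dice_coefficient(back.grid > 0.5, tissue)
        assert d.value >= 0.95
        # residual error at true correspondences <= 2x jitter SD
        true_pairs = LandmarkSet(warp.landmark_src, warp.landmark_dst)
        resid = np.linalg.norm(tps(true_pairs.src) - true_pairs.dst,
                               axis=1).mean()
        assert resid <= 2 * jitter


class TestStackSections:
    def test_single_slice(self, rng):
        v = stack_sections([rng.random((5, 5))], 0.16)
        assert v.shape == (1, 5, 5)

    def test_through_plane_extent(self, rng):
        slices = [rng.random((8, 8)) for _ in range(20)]
        v = stack_sections(slices, 0.16)
        assert v.shape[0] * v.spacing_mm[0] == pytest.approx(3.2)

    def test_roundtrip_bitwise(self, rng):
        slices = [rng.random((6, 7)) for _ in range(4)]
        v = stack_sections(slices, 1.0)
        for k in range(4):
            assert np.array_equal(v.data[k], slices[k])

    def test_shape_mismatch_names_index(self, rng):
        slices = [rng.random((6, 6)), rng.random((6, 7))]
        with pytest.raises(ValueError, match="slice 1"):
            stack_sections(slices, 1.0)


class TestAffine3D:
    def test_identity(self, rng):
        src = rng.uniform(0, 10, (6, 3))
        aff = fit_affine_3d(LandmarkSet(src, src))
        np.testing.assert_allclose(aff.matrix, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(aff.offset, 0, atol=1e-8)

    def test_pure_scaling(self, rng):
        src = rng.uniform(0, 10, (8, 3))
        aff = fit_affine_3d(LandmarkSet(src, 2.0 * src))
        np.testing.assert_allclose(aff.matrix, 2.0 * np.eye(3), atol=1e-9)

    def test_noisy_recovery_within_005(self):
        rng = np.random.default_rng(8)
        A = np.eye(3) + rng.normal(0, 0.1, (3, 3))
        b = rng.normal(0, 2.0, 3)
        src = rng.uniform(0, 20, (20, 3))
        dst = src @ A.T + b + rng.normal(0, 0.1, (20, 3))
        aff = fit_affine_3d(LandmarkSet(src, dst))
        assert np.abs(aff.matrix - A).max() < 0.05

    def test_coplanar_rejected(self, rng):
        src = np.column_stack([rng.uniform(0, 10, (6, 2)), np.zeros(6)])
        with pytest.raises(ValueError, match="coplanar"):
            fit_affine_3d(LandmarkSet(src, src))


class TestDice:
    def test_identical_masks(self):
        m = np.array([[1, 0], [1, 1]])
        d = dice_coefficient(m, m)
        assert d.value == 1.0 and d.qc_pass and not d.both_empty

    def test_disjoint_masks(self):
        a = np.array([[1, 0], [0, 0]])
        b = np.array([[0, 0], [0, 1]])
        d = dice_coefficient(a, b)
        assert d.value == 0.0 and not d.qc_pass

    def test_half_overlap_closed_form(self):
        a = np.zeros((4, 2), dtype=int)
        b = np.zeros((4, 2), dtype=int)
        a[:2, :] = 1          # |a| = 4
        b[1:3, :] = 1         # |b| = 4, overlap 2
        assert dice_coefficient(a, b).value == pytest.approx(0.5)

    def test_both_empty_flagged(self):
        d = dice_coefficient(np.zeros((3, 3)), np.zeros((3, 3)))
        assert d.value == 1.0 and d.both_empty

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="differ"):
            dice_coefficient(np.zeros((2, 2)), np.zeros((3, 3)))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((6, 6)) < 0.5
        b = rng.random((6, 6)) < 0.5
        d_ab = dice_coefficient(a, b).value
        d_ba = dice_coefficient(b, a).value
        assert d_ab == d_ba
        assert 0.0 <= d_ab <= 1.0
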