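"""Synthetic cohort generators: determinism, calibration, separability."""

import numpy as np
import pytest

import histopet as hp
from histopet.phantom import DEFAULT_DENSITIES, MARKERS, upsample_labels
from histopet.segmentation import threshold_performance


class TestLabelMap:
    def test_deterministic_and_seed_sensitive(self):
        a = hp.generate_label_map((64, 64), 1.0, seed=7)
        b = hp.generate_label_map((64, 64), 1.0, seed=7)
        c = hp.generate_label_map((64, 64), 1.0, seed=8)
        assert np.array_equal(a.grid, b.grid)
        assert not np.array_equal(a.grid, c.grid)

    def test_all_regions_present(self):
        lm = hp.generate_label_map((64, 64), 1.0, seed=7)
        for name in lm.labels.values():
            assert lm.region_mask(name).sum() >= 1, name

    def test_3d_stack_has_all_regions(self):
        lm = hp.generate_label_map((6, 40, 40), (4.0, 1.0, 1.0), seed=2)
        assert lm.grid.shape == (6, 40, 40)
        for name in lm.labels.values():
            assert lm.region_mask(name).any(), name

    def test_too_small_grid_names_region(self):
        with pytest.raises(ValueError, match="region"):
            hp.generate_label_map((16, 16), 1.0, seed=0)


@pytest.fixture(scope="module")
def label_map():
    return hp.generate_label_map((64, 64), 1.0, seed=3)


@pytest.fixture(scope="module")
def truth(label_map):
    return hp.generate_marker_truth(label_map, "ptau", 50.0, {"cortex": 0.3},
                                    seed=4)


class TestMarkerTruth:
    def test_zero_density_gives_empty_mask(self, label_map):
        dens = {name: 0.0 for name in label_map.labels.values()}
        t = hp.generate_marker_truth(label_map, "ptau", 50.0, dens, seed=1)
        assert t.mask.sum() == 0

    def test_saturated_cortex(self, label_map):
        dens = {name: 0.0 for name in label_map.labels.values()}
        dens["cortex"] = 1.0
        t = hp.generate_marker_truth(label_map, "ptau", 50.0, dens, seed=1)
        cortex_px = upsample_labels(label_map, 50.0) == label_map.name_to_label["cortex"]
        assert np.array_equal(t.mask.astype(bool), cortex_px)

    def test_density_calibration_large_region(self):
        # 400x400-cell phantom at one pixel per cell: fraction within 5%
        lm = hp.generate_label_map((400, 400), 1.0, seed=5)
        t = hp.generate_marker_truth(lm, "ptau", 1000.0, {"cortex": 0.2}, seed=3)
        cortex = upsample_labels(lm, 1000.0) == lm.name_to_label["cortex"]
        frac = t.mask[cortex].mean()
        assert 0.19 <= frac <= 0.21

    @pytest.mark.parametrize("marker", MARKERS)
    def test_cortex_density_within_20pct(self, label_map, marker):
        t = hp.generate_marker_truth(label_map, marker, 50.0,
                                     {"cortex": 0.2}, seed=3)
        cortex = upsample_labels(label_map, 50.0) == label_map.name_to_label["cortex"]
        frac = t.mask[cortex].mean()
        assert 0.16 <= frac <= 0.24

    def test_unknown_marker_rejected(self, label_map):
        with pytest.raises(ValueError, match="marker"):
            hp.generate_marker_truth(label_map, "amyloid", 50.0, seed=0)

    def test_deterministic(self, label_map):
        a = hp.generate_marker_truth(label_map, "iron", 50.0, seed=9)
        b = hp.generate_marker_truth(label_map, "iron", 50.0, seed=9)
        assert np.array_equal(a.mask, b.mask)


class TestProbabilityCorruption:
    def test_noiseless_limit_recovers_truth(self, truth):
        p = hp.corrupt_to_probability(truth, pos_params=1.0, neg_params=0.0,
                                      seed=0)
        for t in (0.1, 0.5, 0.9):
            assert np.array_equal((p.grid >= t).astype(np.uint8), truth.mask)

    def test_identical_distributions_auc_half(self, truth):
        p = hp.corrupt_to_probability(truth, pos_params=(2, 2),
                                      neg_params=(2, 2), seed=1)
        curve = threshold_performance(p, truth.mask)
        assert abs(curve.auc_roc - 0.5) < 0.05

    def test_default_params_auc_at_least_08(self, truth):
        p = hp.corrupt_to_probability(truth, seed=11)
        curve = threshold_performance(p, truth.mask)
        assert curve.auc_roc >= 0.8

    def test_auc_monotone_in_separation(self, truth):
        aucs = []
        for a in (2.0, 4.0, 8.0):
            p = hp.corrupt_to_probability(truth, pos_params=(a, 2),
                                          neg_params=(2, a), seed=7)
            aucs.append(threshold_performance(p, truth.mask).auc_roc)
        assert aucs[0] < aucs[1] < aucs[2]

    def test_invalid_constant_rejected(self, truth):
        with pytest.raises(ValueError, match="outside"):
            hp.corrupt_to_probability(truth, pos_params=1.5, seed=0)


class TestSynthesizePet:
    def test_intercept_only(self):
        burdens = {"ptau": np.zeros((3, 4, 4))}
        gt = hp.PETGroundTruth(beta0=1.0, betas={"ptau": 0.0}, noise_sd=0.0)
        vol = hp.synthesize_pet(burdens, gt)
        assert np.allclose(vol.data, 1.0)

    def test_linearity(self):
        burdens = {"ptau": np.full((3, 4, 4), 0.5)}
        gt = hp.PETGroundTruth(beta0=1.0, betas={"ptau": 2.0}, noise_sd=0.0)
        vol = hp.synthesize_pet(burdens, gt)
        assert np.allclose(vol.data, 2.0)

    def test_shape_mismatch_rejected(self):
        gt = hp.PETGroundTruth(beta0=1.0, betas={"ptau": 1.0, "iron": 1.0},
                               noise_sd=0.0)
        with pytest.raises(ValueError, match="mismatch"):
            hp.synthesize_pet({"ptau": np.zeros((3, 4, 4)),
                               "iron": np.zeros((3, 5, 5))}, gt)

    def test_noise_deterministic_in_seed(self):
        burdens = {"iron": np.zeros((4, 8, 8))}
        gt = hp.PETGroundTruth(beta0=1.1, betas={"iron": 0.4}, noise_sd=0.1,
                               seed=5)
        a = hp.synthesize_pet(burdens, gt)
        b = hp.synthesize_pet(burdens, gt)
        assert np.array_equal(a.data, b.data)

    def test_least_squares_recovery_within_3se(self):
        from histopet.models import SuvrModelSuite
        from histopet.pipeline import simulate_voxel_case
        table, gt, _ = simulate_voxel_case(7)
        res = SuvrModelSuite(table).fit()
        fit = res.fits["m0"]
        truth = {"const": gt.beta0, **gt.betas}
        for name in fit.params.index:
            assert abs(fit.params[name] - truth[name]) <= 3 * fit.bse[name], name


class TestWarp:
    def test_identity_warp_preserves_image(self, rng):
        img = rng.random((50, 60))
        warp = hp.random_smooth_warp((49.0, 59.0), max_disp_mm=0.0,
                                     landmark_jitter_sd=0.0, seed=1)
        warped, pairs = hp.warp_with_landmarks(img, warp, seed=2, spacing_mm=1.0)
        assert np.allclose(warped, img)
        assert np.allclose(pairs.src, pairs.dst)

    def test_pure_translation(self, rng):
        img = rng.random((40, 40))
        # one giant-scale bump approximates a uniform (2, 0) mm translation
        warp = hp.WarpGroundTruth(
            control_points=[[20.0, 20.0]], control_displacements=[[2.0, 0.0]],
            scale_mm=1e6,
            landmark_src=[[12, 10], [25, 12], [18, 28]],
            landmark_dst=[[10, 10], [23, 12], [16, 28]],
            landmark_jitter_sd=0.0,
        )
        warped, pairs = hp.warp_with_landmarks(img, warp, seed=0, spacing_mm=1.0)
        # content shifts left by 2 columns: warped(x) = img(x + 2 mm)
        assert np.allclose(warped[:, :-2], img[:, 2:], atol=1e-9)
        assert np.allclose(pairs.src - pairs.dst, [2.0, 0.0], atol=1e-6)

    def test_random_warp_moves_landmarks(self):
        warp = hp.random_smooth_warp((40.0, 40.0), max_disp_mm=2.0,
                                     landmark_jitter_sd=0.1, seed=5)
        disp = np.linalg.norm(warp.landmark_src - warp.landmark_dst, axis=1)
        assert disp.mean() > 0

    def test_out_of_image_landmarks_listed(self, rng):
        img = rng.random((30, 30))
        warp = hp.WarpGroundTruth(
            control_points=np.empty((0, 2)),
            control_displacements=np.empty((0, 2)), scale_mm=5.0,
            landmark_src=[[5, 5], [200, 5], [10, 20]],
            landmark_dst=[[5, 5], [200, 5], [10, 20]],
        )
        with pytest.raises(ValueError, match="outside"):
            hp.warp_with_landmarks(img, warp, seed=0, spacing_mm=1.0)

    def test_excessive_displacement_rejected(self, rng):
        img = rng.random((30, 30))
        warp = hp.WarpGroundTruth(
            control_points=[[15.0, 15.0]], control_displacements=[[10.0, 0.0]],
            scale_mm=1e6,
            landmark_src=[[5, 5], [20, 5], [10, 20]],
            landmark_dst=[[5, 5], [20, 5], [10, 20]],
        )
        with pytest.raises(ValueError, match="10%"):
            hp.warp_with_landmarks(img, warp, seed=0, spacing_mm=1.0)


def test_default_densities_marker_dominance():
    """Cortex-dominant tau, lentiform-dominant iron, WM-dominant MAO-B."""
    assert max(DEFAULT_DENSITIES["ptau"], key=DEFAULT_DENSITIES["ptau"].get) in (
        "cortex", "hippocampus")
    assert max(DEFAULT_DENSITIES["iron"], key=DEFAULT_DENSITIES["iron"].get) == "lentiform"
    assert max(DEFAULT_DENSITIES["maob"], key=DEFAULT_DENSITIES["maob"].get) == "white_matter"
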