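import numpy as np
import pytest
from metric_oracles import (
    cosine_oracle,
    mae_slicewise_oracle,
    mae_volume_oracle,
    mse_slicewise_oracle,
    mse_volume_oracle,
    psnr_oracle,
    psnr_per_plane_oracle,
    ssim_volume_oracle,
)

from vert2ct.eval_metrics import (
    PSNR_CAP_DB,
    AngleSweepReport,
    IntensityScale,
    MetricReport,
    angle_sweep,
    cosine_similarity,
    evaluate_pair,
    evaluate_pairs,
    mae_slicewise,
    mae_volume,
    mse_slicewise,
    mse_volume,
    psnr,
    psnr_3d,
    psnr_per_plane,
    report_frame,
    ssim_2d,
    ssim_volume,
)

SCALE = IntensityScale(2500.0)


@pytest.fixture()
def pair(rng):
    gt = rng.random((4, 4, 4))
    pred = np.clip(gt + rng.normal(0, 0.1, gt.shape), 0, 1)
    return gt, pred


class TestAgainstLoopOracles:
    def test_mae_mse_slicewise(self, pair):
        gt, pred = pair
        assert mae_slicewise(gt, pred) == pytest.approx(
            mae_slicewise_oracle(gt, pred), rel=1e-10
        )
        assert mse_slicewise(gt, pred) == pytest.approx(
            mse_slicewise_oracle(gt, pred), rel=1e-10
        )

    def test_mae_mse_volume(self, pair):
        gt, pred = pair
        assert mae_volume(gt, pred, SCALE) == pytest.approx(
            mae_volume_oracle(gt, pred, 2500.0), rel=1e-10
        )
        assert mse_volume(gt, pred, SCALE) == pytest.approx(
            mse_volume_oracle(gt, pred, 2500.0), rel=1e-10
        )

    def test_cosine(self, pair):
        assert cosine_similarity(*pair) == pytest.approx(
            cosine_oracle(*pair), rel=1e-10
        )

    def test_psnr_family(self, pair):
        gt, pred = pair
        assert psnr(gt, pred) == pytest.approx(psnr_oracle(gt, pred), rel=1e-10)
        assert psnr_3d(gt, pred) == pytest.approx(psnr_oracle(gt, pred), rel=1e-10)
        for axis in range(3):
            assert psnr_per_plane(gt, pred, axis) == pytest.approx(
                psnr_per_plane_oracle(gt, pred, axis), rel=1e-10
            )

    def test_ssim_volume(self, rng):
        gt = rng.random((3, 16, 16))
        pred = np.clip(gt + rng.normal(0, 0.2, gt.shape), 0, 1)
        assert ssim_volume(gt, pred) == pytest.approx(
            ssim_volume_oracle(gt, pred), rel=1e-10
        )


class TestIdentityAndHandValues:
    def test_identity_cases(self, rng):
        v = rng.random((4, 4, 4))
        assert mae_slicewise(v, v) == 0.0
        assert mae_volume(v, v, SCALE) == 0.0
        assert cosine_similarity(v, v) == pytest.approx(1.0)
        assert psnr(v, v) == PSNR_CAP_DB
        vs = rng.random((2, 16, 16))
        assert ssim_volume(vs, vs) == pytest.approx(1.0)

    def test_constant_half_error(self):
        gt, pred = np.ones((4, 4, 4)), np.full((4, 4, 4), 0.5)
        assert mae_slicewise(gt, pred) == pytest.approx(0.5)
        assert psnr(gt, pred) == pytest.approx(10 * np.log10(1 / 0.25))
        assert psnr(gt, pred) == pytest.approx(6.0206, abs=1e-4)

    def test_denormalized_hand_values(self):
        gt, pred = np.ones((4, 4, 4)), np.full((4, 4, 4), 0.9)
        assert mae_volume(gt, pred, SCALE) == pytest.approx(250.0)
        assert mse_volume(gt, pred, SCALE) == pytest.approx(62_500.0)

    def test_scale_identities_on_cubic_volumes(self, pair):
        gt, pred = pair
        assert mae_volume(gt, pred, SCALE) == pytest.approx(
            2500.0 * mae_slicewise(gt, pred), rel=1e-12
        )
        assert mse_volume(gt, pred, SCALE) == pytest.approx(
            2500.0**2 * mse_slicewise(gt, pred), rel=1e-12
        )

    def test_cosine_scale_invariance_and_orthogonality(self, rng):
        v = rng.random((4, 4, 4))
        assert cosine_similarity(v, 0.37 * v) == pytest.approx(1.0)
        a = np.zeros((4, 4, 4))
        b = np.zeros((4, 4, 4))
        a[0], b[1] = 1.0, 1.0
        assert cosine_similarity(a, b) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros((2, 2, 2)), v)

    def test_uniform_error_makes_planes_equal_3d(self):
        gt = np.full((4, 4, 4), 0.8)
        pred = np.full((4, 4, 4), 0.6)
        p3d = psnr_3d(gt, pred)
        for axis in range(3):
            assert psnr_per_plane(gt, pred, axis) == pytest.approx(p3d)

    def test_range_violation_rejected(self):
        with pytest.raises(ValueError):
            mae_slicewise(np.full((2, 2, 2), 1.5), np.zeros((2, 2, 2)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            psnr(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


class TestSsimBehaviour:
    def test_matches_skimage_reference(self, rng):
        from skimage.metrics import structural_similarity

        a = rng.random((32, 32))
        b = np.clip(a + rng.normal(0, 0.1, a.shape), 0, 1)
        ref = structural_similarity(
            a, b, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, data_range=1.0,
        )
        assert ssim_2d(a, b) == pytest.approx(ref, abs=1e-12)

    def test_structural_inversion_penalized(self):
        tile = np.indices((16, 16)).sum(axis=0) % 2
        vol = np.stack([tile.astype(float)] * 2)
        assert ssim_volume(vol, 1.0 - vol) < 0.5

    def test_decreasing_in_noise_on_average(self, rng):
        gt = np.tile((np.indices((16, 16)).sum(axis=0) % 4) / 3.0, (2, 1, 1))
        means = []
        for sd in (0.05, 0.15, 0.3):
            vals = [
                ssim_volume(
                    gt, np.clip(gt + np.random.default_rng(s).normal(0, sd, gt.shape), 0, 1)
                )
                for s in range(10)
            ]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_small_slice_rejected(self):
        with pytest.raises(ValueError):
            ssim_2d(np.zeros((8, 8)), np.zeros((8, 8)))


class TestReports:
    def test_single_pair_report_equals_pair_metrics(self, rng):
        gt = rng.random((16, 16, 16))
        pred = np.clip(gt + rng.normal(0, 0.05, gt.shape), 0, 1)
        single = evaluate_pair(gt, pred, SCALE)
        pooled = evaluate_pairs([(gt, pred)], SCALE)
        for k, v in single.as_dict().items():
            assert pooled.as_dict()[k] == pytest.approx(v)

    def test_two_pairs_average_fieldwise(self, rng):
        pairs = []
        for _ in range(2):
            gt = rng.random((16, 16, 16))
            pairs.append((gt, np.clip(gt + rng.normal(0, 0.05, gt.shape), 0, 1)))
        pooled = evaluate_pairs(pairs, SCALE)
        singles = [evaluate_pair(g, p, SCALE) for g, p in pairs]
        for k in ("mae0", "mse", "cosine", "psnr_3d", "ssim"):
            expected = np.mean([s.as_dict()[k] for s in singles])
            assert pooled.as_dict()[k] == pytest.approx(expected)

    def test_psnr_avg_invariant(self, rng):
        gt = rng.random((16, 16, 16))
        rep = evaluate_pair(gt, np.clip(gt + 0.03, 0, 1), SCALE)
        assert rep.psnr_avg == pytest.approx(
            (rep.psnr_1 + rep.psnr_2 + rep.psnr_3) / 3, rel=1e-15
        )

    def test_identical_pairs_hit_ideal_values(self, rng):
        v = rng.random((16, 16, 16))
        rep = evaluate_pairs([(v, v)] * 2, SCALE)
        assert rep.mae0 == 0.0
        assert rep.cosine == pytest.approx(1.0)
        assert rep.ssim == pytest.approx(1.0)
        for k in ("psnr_1", "psnr_2", "psnr_3", "psnr_avg", "psnr_3d"):
            assert rep.as_dict()[k] == PSNR_CAP_DB

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate_pairs([], SCALE)

    def test_report_frame_row_labels(self, rng):
        v = rng.random((16, 16, 16))
        frame = report_frame(evaluate_pair(v, v, SCALE))
        assert list(frame.index) == [
            "MAE0", "MSE0", "MAE", "MSE", "Cosine Similarity", "PSNR-3D",
            "PSNR-1", "PSNR-2", "PSNR-3", "PSNR-avg", "SSIM",
        ]


class TestAngleSweep:
    def test_ground_truth_stub_gives_identical_ideal_columns(self, phantom_pair):
        from vert2ct.types import CTVolume
        from vert2ct.volume_roi import crop_to_mask

        vol, mask = phantom_pair
        cvol, _ = crop_to_mask(vol, mask)
        size = 32
        from skimage.transform import resize

        norm = np.clip(
            resize(cvol.data / 2500.0, (size, size, size), order=1,
                   anti_aliasing=False), 0, 1,
        )
        case = CTVolume(norm * 2500.0)
        stub = lambda x1, x2: norm
        report = angle_sweep(stub, [case], scale=SCALE, out_size=size)
        assert isinstance(report, AngleSweepReport)
        assert report.angles == (90.0, 85.0, 80.0, 75.0)
        assert len(report.reports) == 4
        for rep in report.reports:
            assert rep.mae0 == pytest.approx(0.0)
            assert rep.cosine == pytest.approx(1.0)
            assert rep.psnr_3d == PSNR_CAP_DB
            assert rep.ssim == pytest.approx(1.0)

    def test_sweep_frame_has_one_column_per_angle(self, phantom_pair):
        from vert2ct.types import CTVolume

        v = np.clip(np.random.default_rng(0).random((32, 32, 32)), 0, 1)
        case = CTVolume(v * 2500.0)
        report = angle_sweep(lambda a, b: v, [case], angles=(90.0, 80.0),
                             scale=SCALE, out_size=32)
        frame = report_frame(report)
        assert list(frame.columns) == ["90 Degree", "80 Degree"]
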