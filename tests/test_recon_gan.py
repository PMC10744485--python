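import numpy as np
import pytest

from vert2ct.recon_gan import (
    ConditionalPatchDiscriminator3d,
    GanConfig,
    LossWeights,
    TwoViewFusionGenerator,
    build_discriminator,
    build_generator,
    feature_matching_loss,
    identity_loss,
    learning_rate_at_epoch,
    lsgan_loss,
    projection_loss,
    reconstruction_loss,
    train,
)
from vert2ct.types import PairedSample

SMALL = GanConfig(volume_size=16, base_channels=4, n_epochs=1)


class TestConfig:
    @pytest.mark.parametrize("size", [8, 24, 100])
    def test_volume_size_must_be_power_of_two(self, size):
        with pytest.raises(ValueError):
            GanConfig(volume_size=size)

    def test_defaults_follow_training_recipe(self):
        cfg = GanConfig()
        assert cfg.learning_rate == pytest.approx(2e-4)
        assert cfg.beta1 == pytest.approx(0.5)
        assert cfg.beta2 == pytest.approx(0.99)
        assert cfg.batch_size == 1
        assert cfg.volume_size == 128

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(0, 0, 0, 0, 0)


class TestLosses:
    def test_lsgan_perfect_discriminator(self, rng):
        d_real = np.ones((1, 4, 4, 4))
        d_fake = np.zeros((1, 4, 4, 4))
        loss_d, _ = lsgan_loss(d_real, d_fake)
        assert float(loss_d) == pytest.approx(0.0)

    def test_lsgan_perfectly_fooled(self):
        _, loss_g = lsgan_loss(np.ones((2, 2)), np.ones((2, 2)))
        assert float(loss_g) == pytest.approx(0.0)

    def test_lsgan_constant_half_scores(self):
        loss_d, loss_g = lsgan_loss(np.full((3, 3), 0.5), np.full((3, 3), 0.5))
        assert float(loss_d) == pytest.approx(0.25)
        assert float(loss_g) == pytest.approx(0.25)

    def test_lsgan_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            lsgan_loss(np.array([np.nan]), np.array([0.0]))

    def test_reconstruction_loss_identity_and_full_scale(self, rng):
        v = rng.random((4, 4, 4))
        assert float(reconstruction_loss(v, v)) == 0.0
        assert float(
            reconstruction_loss(np.zeros((4, 4, 4)), np.ones((4, 4, 4)))
        ) == pytest.approx(1.0)

    def test_reconstruction_loss_matches_loop_oracle(self, rng):
        a, b = rng.random((4, 4, 4)), rng.random((4, 4, 4))
        total = 0.0
        for x, y in zip(a.ravel(), b.ravel()):
            total += (x - y) ** 2
        assert float(reconstruction_loss(a, b)) == pytest.approx(
            total / a.size, rel=1e-12
        )

    def test_projection_loss_zero_for_projection_equal_volumes(self, rng):
        v = rng.random((4, 4, 4))
        # parity perturbation on a 2x2x2 corner block preserves the mean
        # projection along every axis but changes the voxel values
        delta = np.zeros_like(v)
        for z in range(2):
            for y in range(2):
                for x in range(2):
                    delta[z, y, x] = 0.05 if (z + y + x) % 2 == 0 else -0.05
        w = v + delta
        assert float(projection_loss(v, w)) == pytest.approx(0.0, abs=1e-15)
        assert float(reconstruction_loss(v, w)) > 0.0

    def test_projection_loss_matches_loop_oracle(self, rng):
        a, b = rng.random((4, 4, 4)), rng.random((4, 4, 4))
        acc = 0.0
        for axis in range(3):
            pa = a.mean(axis=axis)
            pb = b.mean(axis=axis)
            total = 0.0
            for x, y in zip(pa.ravel(), pb.ravel()):
                total += (x - y) ** 2
            acc += total / pa.size
        assert float(projection_loss(a, b)) == pytest.approx(acc / 3, rel=1e-12)

    def test_feature_matching_identity_and_single_layer_offset(self, rng):
        feats = [rng.random((2, 3, 3)) for _ in range(4)]
        assert float(feature_matching_loss(feats, feats)) == 0.0
        shifted = [f.copy() for f in feats]
        shifted[1] = shifted[1] + 1.0
        assert float(feature_matching_loss(feats, shifted)) == pytest.approx(1 / 4)

    def test_feature_matching_matches_loop_oracle(self, rng):
        a = [rng.random((2, 3)) for _ in range(3)]
        b = [rng.random((2, 3)) for _ in range(3)]
        acc = 0.0
        for fa, fb in zip(a, b):
            total = 0.0
            for x, y in zip(fa.ravel(), fb.ravel()):
                total += abs(x - y)
            acc += total / fa.size
        assert float(feature_matching_loss(a, b)) == pytest.approx(acc / 3, rel=1e-12)

    def test_feature_matching_rejects_mismatch(self, rng):
        with pytest.raises(ValueError):
            feature_matching_loss([rng.random((2, 2))], [])

    def test_identity_loss_zero_for_own_projections(self, rng):
        v = rng.random((8, 8, 8))
        assert float(
            identity_loss(v, v.mean(axis=1), v.mean(axis=2))
        ) == pytest.approx(0.0)


class TestGenerator:
    def test_output_shape_and_range(self, rng):
        G = build_generator(SMALL)
        out = G(rng.random((16, 16)), rng.random((16, 16)))
        assert out.shape == (16, 16, 16)
        assert np.all(np.isfinite(out.data))
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_identical_views_run(self, rng):
        G = build_generator(SMALL)
        x = rng.random((16, 16))
        out = G(x, x)
        assert np.all(np.isfinite(out.data))

    def test_wrong_view_size_rejected(self, rng):
        G = build_generator(SMALL)
        with pytest.raises(ValueError):
            G(rng.random((32, 32)), rng.random((32, 32)))


class TestDiscriminator:
    def test_patch_output_has_multiple_cells(self, rng):
        D = build_discriminator(SMALL)
        score = D(rng.random((16, 16, 16)), rng.random((16, 16)), rng.random((16, 16)))
        assert np.prod(score.shape[1:]) > 1

    def test_deterministic_without_dropout(self, rng):
        D = build_discriminator(SMALL)
        v, x1, x2 = rng.random((16, 16, 16)), rng.random((16, 16)), rng.random((16, 16))
        s1 = D(v, x1, x2).data
        s2 = D(v, x1, x2).data
        np.testing.assert_array_equal(s1, s2)

    def test_wrong_volume_size_rejected(self, rng):
        D = build_discriminator(SMALL)
        with pytest.raises(ValueError):
            D(rng.random((8, 8, 8)), rng.random((16, 16)), rng.random((16, 16)))


def _toy_dataset(rng, n=1, size=16):
    samples = []
    for i in range(n):
        ct = rng.random((size, size, size))
        samples.append(
            PairedSample(
                ct=ct, xray1=ct.mean(axis=1), xray2=ct.mean(axis=2), case_id=f"c{i}"
            )
        )
    return samples


class TestTraining:
    def test_generator_parameters_change_after_one_step(self, rng):
        data = _toy_dataset(rng)
        cfg = GanConfig(volume_size=16, base_channels=4, n_epochs=1, seed=0)
        before = TwoViewFusionGenerator(cfg)
        result = train(data, cfg)
        norm0 = sum(float(np.abs(p.data).sum()) for p in before.parameters())
        norm1 = sum(
            float(np.abs(p.data).sum()) for p in result.generator.parameters()
        )
        assert norm0 != pytest.approx(norm1)

    def test_supervised_mode_reconstruction_decreases(self, rng):
        data = _toy_dataset(rng)
        cfg = GanConfig(
            volume_size=16,
            base_channels=4,
            n_epochs=5,
            seed=1,
            loss_weights=LossWeights(w_gan=0, w_recon=10, w_proj=0, w_fm=0, w_idt=0),
        )
        result = train(data, cfg)
        recon = [h["l_recon"] for h in result.history]
        assert all(b <= a for a, b in zip(recon, recon[1:]))

    def test_learning_rate_decays_linearly_after_half(self):
        lrs = [learning_rate_at_epoch(1.0, e, 10) for e in range(10)]
        assert lrs[:5] == [1.0] * 5
        np.testing.assert_allclose(lrs[5:], [1.0, 0.8, 0.6, 0.4, 0.2])
        assert lrs[-1] < lrs[0]

    def test_lr_in_history_decreases(self, rng):
        result = train(
            _toy_dataset(rng),
            GanConfig(volume_size=16, base_channels=4, n_epochs=4, seed=2),
        )
        assert result.history[-1]["lr"] < result.history[0]["lr"]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], SMALL)

    def test_nan_input_aborts_with_term_name(self, rng):
        s = _toy_dataset(rng)[0]
        s.ct[0, 0, 0] = np.nan
        with pytest.raises((RuntimeError, ValueError)):
            train([s], GanConfig(volume_size=16, base_channels=4, n_epochs=1))

    def test_loss_log_written(self, rng, tmp_path):
        result = train(
            _toy_dataset(rng),
            GanConfig(volume_size=16, base_channels=4, n_epochs=2, seed=3),
            log_dir=str(tmp_path),
        )
        assert result.log_path is not None
        lines = open(result.log_path).read().strip().splitlines()
        assert len(lines) == 3  # header + 2 epochs
        assert len(result.checkpoints) >= 1
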