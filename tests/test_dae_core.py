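import numpy as np
import pytest

from chromstem import voxel_imaging as vi
from chromstem.dae_core import (
    DAEConfig,
    _bce_grad,
    bce_loss,
    build_model,
    denoise,
    denoise_image,
    load_dae,
    save_dae,
    train,
)
from chromstem.noise_model import NoisyImagePair
from chromstem.quality_metrics import mse

TINY = DAEConfig(encoder_filters=(6, 5, 4), seed=1)


class TestArchitecture:
    def test_output_shape_and_range_32(self):
        model = build_model(TINY)
        out = model.predict(np.random.default_rng(0).random((2, 32, 32)))
        assert out.shape == (2, 32, 32)
        assert np.all(out > 0) and np.all(out < 1)

    def test_pad_and_crop_28(self):
        model = build_model(TINY)
        out = model.predict(np.random.default_rng(1).random((28, 28)))
        assert out.shape == (28, 28)

    def test_fully_convolutional_odd_size(self):
        model = build_model(TINY)
        out = model.predict(np.random.default_rng(2).random((64, 96)))
        assert out.shape == (64, 96)
        out = model.predict(np.random.default_rng(3).random((30, 45)))
        assert out.shape == (30, 45)

    def test_layer_counts_match_config(self):
        model = build_model(DAEConfig(encoder_filters=(8, 4)))
        # per encoder block: conv/relu/pool; decoder mirrors; final conv+sigmoid
        assert len(model.layers) == 3 * 2 + 3 * 2 + 2

    def test_empty_filters_rejected(self):
        with pytest.raises(ValueError):
            DAEConfig(encoder_filters=())

    def test_gradients_match_finite_differences(self):
        model = build_model(DAEConfig(encoder_filters=(4, 3), seed=2))
        rng = np.random.default_rng(0)
        x = rng.random((2, 8, 8, 1)).astype(np.float32)
        y = rng.random((2, 8, 8, 1)).astype(np.float32)
        pred = model.forward(x, train=True)
        grads = model.backward(_bce_grad(y, pred))
        check_rng = np.random.default_rng(5)
        for p, g in zip(model.params, grads):
            idx = tuple(check_rng.integers(0, s) for s in p.shape)
            eps, orig = 1e-3, p[idx]
            p[idx] = orig + eps
            lp = bce_loss(y, model.forward(x))
            p[idx] = orig - eps
            lm = bce_loss(y, model.forward(x))
            p[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            # float32 forward passes limit finite-difference agreement
            assert g[idx] == pytest.approx(numeric, rel=0.15, abs=2e-4)


class TestBCE:
    def test_half_half_gives_ln2(self):
        y = np.full((10, 10), 0.5)
        assert bce_loss(y, y) == pytest.approx(np.log(2), abs=1e-12)

    def test_perfect_binary_prediction_near_zero(self):
        y = (np.arange(100).reshape(10, 10) % 2).astype(float)
        assert bce_loss(y, y) < 1e-5

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(7)
        y = rng.random((9, 11))
        p = rng.random((9, 11))
        total = 0.0
        for i in range(9):
            for j in range(11):
                pc = min(max(p[i, j], 1e-7), 1 - 1e-7)
                total += -(y[i, j] * np.log(pc) + (1 - y[i, j]) * np.log(1 - pc))
        assert bce_loss(y, p) == pytest.approx(total / (9 * 11), abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.zeros((2, 2)), np.zeros((3, 3)))


def _identity_pairs(n, seed):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        img = np.clip(rng.random((16, 16)), 0.05, 0.95)
        out.append(NoisyImagePair(clean=img, noisy=img))
    return out


class TestTraining:
    def test_loss_decreases(self, small_pairs):
        cfg = DAEConfig(encoder_filters=(8, 6, 4), max_epochs=5, patience=5, seed=0)
        trained = train(build_model(cfg), small_pairs, cfg)
        h = trained.history
        assert h["train_loss"].iloc[-1] < h["train_loss"].iloc[0]

    def test_identity_task_approaches_entropy_floor(self, small_clean_images):
        """On (clean, clean) pairs the BCE is bounded below by the mean
        self-entropy of the targets; training must approach that floor."""
        images = small_clean_images[:50]
        pairs = [NoisyImagePair(clean=im, noisy=im.copy()) for im in images]
        floor = bce_loss(np.stack(images), np.stack(images))
        cfg = DAEConfig(encoder_filters=(16, 12, 8), max_epochs=60, patience=60,
                        learning_rate=2e-3, seed=4)
        trained = train(build_model(cfg), pairs, cfg)
        final = trained.history["train_loss"].iloc[-1]
        assert final < 1.5 * floor
        # and the floor is a genuine lower bound
        assert final > floor

    def test_early_stopping_halts_and_restores_best(self, small_pairs):
        cfg = DAEConfig(encoder_filters=(6, 5, 4), max_epochs=40, patience=2, seed=5,
                        learning_rate=5e-2)  # aggressive lr forces val regression
        trained = train(build_model(cfg), small_pairs, cfg)
        h = trained.history
        best = h["val_loss"].min()
        # stopped no later than patience epochs after the best epoch
        best_epoch = int(h.loc[h["val_loss"].idxmin(), "epoch"])
        assert h["epoch"].iloc[-1] <= best_epoch + 2
        # restored weights reproduce the best validation loss contract
        assert best <= h["val_loss"].iloc[-1] + 1e-12

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            train(build_model(TINY), _identity_pairs(5, 0), TINY)

    def test_small_dataset_reduces_batch_with_warning(self):
        cfg = DAEConfig(encoder_filters=(4, 3), max_epochs=1, patience=1, seed=6)
        with pytest.warns(UserWarning, match="reducing batch size"):
            train(build_model(cfg), _identity_pairs(12, 1), cfg)

    def test_seeded_reproducibility(self, small_pairs):
        cfg = DAEConfig(encoder_filters=(6, 4), max_epochs=2, patience=2, seed=9)
        a = train(build_model(cfg), small_pairs, cfg)
        b = train(build_model(cfg), small_pairs, cfg)
        np.testing.assert_array_equal(a.weights[0], b.weights[0])
        assert a.history.equals(b.history)


class TestDenoise:
    def test_stack_shape_preserved(self, tiny_trained):
        rng = np.random.default_rng(0)
        stack = vi.VoxelStack(data=rng.random((28, 28, 9)), grid=vi.GridSpec(), normalized=True)
        out = denoise(tiny_trained, stack)
        assert out.data.shape == (28, 28, 9)
        assert out.normalized
        assert out.data.min() > 0 and out.data.max() < 1

    def test_unnormalized_stack_rejected(self, tiny_trained):
        stack = vi.VoxelStack(data=np.full((28, 28, 9), 3.0), grid=vi.GridSpec())
        with pytest.raises(ValueError):
            denoise(tiny_trained, stack)

    def test_improves_over_noisy_input(self, tiny_trained, noisy_pairs):
        """The model's reason to exist: reconstruction beats the noisy input."""
        noisy_err = np.mean([mse(p.clean, p.noisy) for p in noisy_pairs])
        den_err = np.mean(
            [mse(p.clean, denoise_image(tiny_trained, p.noisy)) for p in noisy_pairs]
        )
        assert den_err < noisy_err

    def test_large_slice_processes_without_retraining(self, tiny_trained):
        big = np.random.default_rng(1).random((41, 410)).astype(np.float32)
        out = denoise_image(tiny_trained, big)
        assert out.shape == (41, 410)


class TestPersistence:
    def test_round_trip(self, tiny_trained, tmp_path):
        save_dae(tiny_trained, tmp_path / "model")
        back = load_dae(tmp_path / "model")
        img = np.random.default_rng(2).random((28, 28))
        np.testing.assert_allclose(
            denoise_image(tiny_trained, img), denoise_image(back, img), atol=1e-6
        )
        assert back.config == tiny_trained.config
        assert len(back.history) == len(tiny_trained.history)
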