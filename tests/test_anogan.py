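"""WGAN-GP training, izi_f encoder training and the two loss terms."""

from dataclasses import replace
from types import SimpleNamespace

import numpy as np
import pytest

from anoscore.anogan import (GanHyperparams, compute_losses, load_model,
                             save_model, train_encoder, train_wgan)
from conftest import TINY_HP


def test_hyperparameter_validation():
    with pytest.raises(ValueError):
        GanHyperparams(learning_rate=0.0)
    with pytest.raises(ValueError):
        GanHyperparams(beta1=1.0)
    with pytest.raises(ValueError):
        GanHyperparams(input_size=48)   # not a power of two
    with pytest.raises(ValueError):
        GanHyperparams(optimizer="sgd")


class TestWganTraining:
    def test_smoke_on_constant_images(self):
        hp = replace(TINY_HP, n_steps=50)
        images = np.full((64, 32, 32), 0.5)
        model = train_wgan(images, hp)
        rng = np.random.default_rng(0)
        z = rng.standard_normal((16, hp.latent_dim)).astype(np.float32)
        out = model.generator(z)
        assert np.isfinite(out).all()
        assert out.std() > 0.0
        assert len(model.training_log["critic_loss"]) == 50

    def test_seeded_determinism(self, tiny_images):
        hp = replace(TINY_HP, n_steps=30)
        a = train_wgan(tiny_images, hp)
        b = train_wgan(tiny_images, hp)
        assert a.training_log == b.training_log

    def test_too_few_images_rejected(self):
        with pytest.raises(ValueError, match="batch_size"):
            train_wgan(np.zeros((4, 32, 32)), TINY_HP)

    def test_image_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="input_size"):
            train_wgan(np.zeros((64, 16, 16)), TINY_HP)

    def test_critic_estimate_shrinks(self, tiny_images):
        # toy convergence: |Wasserstein estimate| over the last 50 steps
        # below the first 50
        hp = replace(TINY_HP, n_steps=200)
        model = train_wgan(tiny_images, hp)
        w = np.abs(model.training_log["wasserstein"])
        assert np.mean(w[-50:]) < np.mean(w[:50])


class TestEncoderTraining:
    def test_requires_trained_gan(self, tiny_images):
        from anoscore.anogan import GanModel
        untrained = train_wgan(tiny_images, replace(TINY_HP, n_steps=1))
        untrained.gan_trained = False
        with pytest.raises(ValueError, match="trained"):
            train_encoder(untrained, tiny_images)

    def test_loss_decomposition_identity(self, tiny_model):
        # loss_izi == loss_images + k * loss_features at every logged step
        log = tiny_model.training_log["encoder"]
        k = tiny_model.hp.k_feature_weight
        for li, lf, lz in zip(log["loss_images"], log["loss_features"],
                              log["loss_izi"]):
            assert lz == pytest.approx(li + k * lf, abs=1e-12)

    def test_k_zero_reduces_to_image_loss(self, tiny_images):
        hp = replace(TINY_HP, n_steps=20, encoder_steps=20,
                     k_feature_weight=0.0)
        model = train_encoder(train_wgan(tiny_images, hp), tiny_images, hp)
        log = model.training_log["encoder"]
        assert log["loss_izi"] == log["loss_images"]

    def test_encoder_loss_decreases(self, tiny_model):
        izi = tiny_model.training_log["encoder"]["loss_izi"]
        tail = max(1, len(izi) // 10)
        assert np.median(izi[-tail:]) < np.median(izi[:tail])


class TestComputeLosses:
    def test_perfect_reconstruction_gives_zero(self, tiny_model):
        x = np.zeros(tiny_model.hp.n_pixels)
        stub = SimpleNamespace(
            encoder_trained=True, hp=tiny_model.hp,
            reconstruct=lambda b: b.copy(),
            features=lambda b: np.zeros((len(b), 4)))
        li, lf = compute_losses(x, stub)
        assert li == 0.0 and lf == 0.0

    def test_hand_oracle_two_pixels_one_feature(self):
        # X=(0,0), X'=(1,1), f(X)=(0), f(X')=(2) -> (1.0, 4.0)
        hp = SimpleNamespace(n_pixels=2)
        stub = SimpleNamespace(
            encoder_trained=True, hp=hp,
            reconstruct=lambda b: np.ones_like(b),
            features=lambda b: np.full((len(b), 1), 0.0 if b.max() == 0 else 2.0))
        li, lf = compute_losses(np.zeros(2), stub)
        assert li == pytest.approx(1.0)
        assert lf == pytest.approx(4.0)

    def test_matches_brute_force_mse(self, tiny_model):
        rng = np.random.default_rng(3)
        x = rng.random((32, 32))
        li, lf = compute_losses(x, tiny_model)
        flat = x.reshape(1, -1).astype(np.float32)
        x_rec = tiny_model.reconstruct(flat)
        brute_li = float(np.mean((flat - x_rec) ** 2))
        assert li == pytest.approx(brute_li, rel=1e-6)
        assert li >= 0.0 and lf >= 0.0

    def test_untrained_encoder_rejected(self, tiny_images):
        model = train_wgan(tiny_images, replace(TINY_HP, n_steps=1))
        with pytest.raises(ValueError, match="encoder"):
            compute_losses(np.zeros((32, 32)), model)

    def test_size_mismatch_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            compute_losses(np.zeros((16, 16)), tiny_model)


def test_model_roundtrip_through_checkpoint(tiny_model, tmp_path):
    save_model(tiny_model, tmp_path / "ckpt")
    loaded = load_model(tmp_path / "ckpt")
    x = np.random.default_rng(1).random((32, 32))
    assert compute_losses(x, loaded) == compute_losses(x, tiny_model)
    with pytest.raises(FileNotFoundError):
        load_model(tmp_path / "nope")
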