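"""Fast anomaly GAN: WGAN-GP generator/critic plus an izi_f encoder.

The model is trained on normal images only.  Stage one trains a generator
G and a critic D under the Wasserstein objective with gradient penalty,
giving G a latent representation of normal anatomy.  Stage two freezes G
and D and trains an encoder E mapping images into the latent space by
minimizing

    Loss_izi = Loss_images + k * Loss_features
    Loss_images   = (1/n) ||X - G(E(X))||^2
    Loss_features = (1/m) ||f(X) - f(G(E(X)))||^2

where f(.) is the critic's hidden-layer activation (dimension m) and n the
number of pixels.  An image that is unlike the training distribution cannot
be reproduced from the latent space, so both residuals grow — they are the
two ingredients of the anomaly score in :mod:`anoscore.scoring`.

Networks are fully-connected (flattened pixels), implemented in numpy with
manual backpropagation; the gradient penalty's parameter gradient is exact
for the one-hidden-layer critic because leaky-ReLU slopes are locally
constant.  All randomness flows from the single seed in the hyperparameter
block, so training is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import Adam, Dense, LeakyReLU, ReLU, Sequential, Sigmoid

__all__ = ["GanHyperparams", "GanModel", "train_wgan", "train_encoder",
           "compute_losses", "save_model", "load_model"]


@dataclass(frozen=True)
class GanHyperparams:
    """Training configuration; defaults follow the published full-scale run
    (Adam, lr 0.001, batch 32, betas 0.5/0.999, latent 128, 256x256 input,
    7000 epochs) except where toy-scale overrides are passed explicitly."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    n_epochs: int = 7000
    latent_dim: int = 128
    input_size: int = 256
    beta1: float = 0.5
    beta2: float = 0.999
    hidden_dim: int = 256
    gradient_penalty_weight: float = 10.0
    k_feature_weight: float = 1.0
    n_critic: int = 5
    n_steps: int | None = None        # overrides epoch-derived generator steps
    encoder_steps: int | None = None  # defaults to generator step count
    seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("adam betas must lie in [0, 1)")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.input_size < 8 or (self.input_size & (self.input_size - 1)):
            raise ValueError("input_size must be a power of two >= 8")

    @property
    def n_pixels(self) -> int:
        return self.input_size * self.input_size


class Critic:
    """One-hidden-layer critic; the hidden activation is the feature map f."""

    def __init__(self, n_pixels: int, hidden_dim: int, rng: np.random.Generator):
        self.fc1 = Dense(n_pixels, hidden_dim, rng)
        self.act = LeakyReLU(0.2)
        self.fc2 = Dense(hidden_dim, 1, rng)

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (scores (B,), features (B, m))."""
        h = self.act.forward(self.fc1.forward(x))
        return self.fc2.forward(h)[:, 0], h

    def backward_from_score(self, grad_score: np.ndarray,
                            need_input_grad: bool = True):
        g = self.fc2.backward(grad_score[:, None])
        return self.fc1.backward(self.act.backward(g), need_input_grad)

    def backward_from_features(self, grad_feat: np.ndarray) -> np.ndarray:
        return self.fc1.backward(self.act.backward(grad_feat))

    @property
    def params(self):
        return self.fc1.params + self.fc2.params

    @property
    def grads(self):
        return self.fc1.grads + self.fc2.grads

    def zero_grad(self):
        self.fc1.zero_grad()
        self.fc2.zero_grad()

    def add_gradient_penalty_grads(self, x_hat: np.ndarray, weight: float) -> float:
        """Accumulate d/dtheta of weight * mean_b (||grad_x D(x_hat_b)|| - 1)^2.

        For D(x) = w2 . lrelu(W1 x + b1) + b2 the input gradient is
        g_b = W1 @ (s_b * w2) with s_b the local activation slopes; slopes
        are piecewise constant, so differentiating g through W1 and w2 is
        exact almost everywhere (the biases receive zero penalty gradient).
        Returns the penalty value.
        """
        W1, w2 = self.fc1.W, self.fc2.W[:, 0]
        h = x_hat @ W1 + self.fc1.b
        s = np.where(h > 0, 1.0, self.act.alpha)          # (B, m)
        sw = s * w2                                        # (B, m)
        g = sw @ W1.T                                      # (B, n)
        norms = np.sqrt((g * g).sum(axis=1) + 1e-12)       # (B,)
        B = len(x_hat)
        penalty = float(((norms - 1.0) ** 2).mean())
        dPdg = (2.0 * weight / B) * ((norms - 1.0) / norms)[:, None] * g
        self.fc1.dW += dPdg.T @ sw                         # (n, m)
        self.fc2.dW[:, 0] += (s * (dPdg @ W1)).sum(axis=0)
        return penalty


def _build_generator(hp: GanHyperparams, rng) -> Sequential:
    return Sequential([
        Dense(hp.latent_dim, hp.hidden_dim, rng), ReLU(),
        Dense(hp.hidden_dim, hp.n_pixels, rng), Sigmoid(),
    ])


def _build_encoder(hp: GanHyperparams, rng) -> Sequential:
    return Sequential([
        Dense(hp.n_pixels, hp.hidden_dim, rng), LeakyReLU(0.2),
        Dense(hp.hidden_dim, hp.latent_dim, rng),
    ])


@dataclass
class GanModel:
    generator: Sequential
    critic: Critic
    encoder: Sequential
    hp: GanHyperparams
    training_log: dict = field(default_factory=dict)
    gan_trained: bool = False
    encoder_trained: bool = False

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        """G(E(X)) for a (B, n_pixels) batch."""
        return self.generator(self.encoder(x))

    def features(self, x: np.ndarray) -> np.ndarray:
        return self.critic.forward(x)[1]

    @property
    def feature_dim(self) -> int:
        return self.hp.hidden_dim


def _as_batch_matrix(images, hp: GanHyperparams) -> np.ndarray:
    from .nn import DTYPE
    x = np.asarray(images, dtype=DTYPE)
    if x.ndim == 3:
        if x.shape[1] != hp.input_size or x.shape[2] != hp.input_size:
            raise ValueError(
                f"image size {x.shape[1:]} does not match input_size "
                f"{hp.input_size}")
        x = x.reshape(len(x), -1)
    elif x.ndim != 2 or x.shape[1] != hp.n_pixels:
        raise ValueError(
            f"expected (B, {hp.input_size}, {hp.input_size}) images or "
            f"(B, {hp.n_pixels}) flat batch, got shape {x.shape}")
    return x


def _n_generator_steps(hp: GanHyperparams, n_images: int) -> int:
    if hp.n_steps is not None:
        return int(hp.n_steps)
    steps_per_epoch = max(1, n_images // hp.batch_size)
    return hp.n_epochs * steps_per_epoch


def train_wgan(images, hp: GanHyperparams) -> GanModel:
    """Adversarial stage: alternating critic (``n_critic`` updates with
    gradient penalty) and generator updates; returns the model with per-step
    losses in ``training_log``.  The encoder is initialized but untrained.
    """
    x_all = _as_batch_matrix(images, hp)
    if len(x_all) < hp.batch_size:
        raise ValueError(
            f"need at least batch_size={hp.batch_size} images, got {len(x_all)}")

    rng = np.random.default_rng(hp.seed)
    G = _build_generator(hp, rng)
    D = Critic(hp.n_pixels, hp.hidden_dim, rng)
    E = _build_encoder(hp, rng)
    opt_G = Adam(G.params, G.grads, hp.learning_rate, hp.beta1, hp.beta2)
    opt_D = Adam(D.params, D.grads, hp.learning_rate, hp.beta1, hp.beta2)

    from .nn import DTYPE

    n_steps = _n_generator_steps(hp, len(x_all))
    log = {"critic_loss": [], "wasserstein": [], "gradient_penalty": [],
           "generator_loss": []}
    B = hp.batch_size
    for step in range(n_steps):
        w_est = gp_val = d_loss = 0.0
        for _ in range(hp.n_critic):
            idx = rng.integers(0, len(x_all), size=B)
            x_real = x_all[idx]
            z = rng.standard_normal((B, hp.latent_dim), dtype=DTYPE)
            x_fake = G(z)

            D.zero_grad()
            s_real, _ = D.forward(x_real)
            D.backward_from_score(np.full(B, -1.0 / B, dtype=DTYPE),
                                  need_input_grad=False)
            s_fake, _ = D.forward(x_fake)
            D.backward_from_score(np.full(B, +1.0 / B, dtype=DTYPE),
                                  need_input_grad=False)
            eps = rng.random((B, 1), dtype=DTYPE)
            x_hat = eps * x_real + (1.0 - eps) * x_fake
            gp_val = D.add_gradient_penalty_grads(
                x_hat, hp.gradient_penalty_weight)
            w_est = float(s_real.mean() - s_fake.mean())
            d_loss = -w_est + hp.gradient_penalty_weight * gp_val
            if not np.isfinite(d_loss):
                raise FloatingPointError(
                    f"non-finite critic loss at generator step {step}")
            opt_D.step()

        z = rng.standard_normal((B, hp.latent_dim), dtype=DTYPE)
        G.zero_grad()
        x_fake = G(z)
        s_fake, _ = D.forward(x_fake)
        g_loss = float(-s_fake.mean())
        if not np.isfinite(g_loss):
            raise FloatingPointError(
                f"non-finite generator loss at step {step}")
        D.zero_grad()
        grad_x = D.backward_from_score(np.full(B, -1.0 / B, dtype=DTYPE))
        D.zero_grad()                      # generator step must not touch D
        G.backward(grad_x)
        opt_G.step()

        log["critic_loss"].append(d_loss)
        log["wasserstein"].append(w_est)
        log["gradient_penalty"].append(gp_val)
        log["generator_loss"].append(g_loss)

    return GanModel(G, D, E, hp, training_log=log, gan_trained=True)


def train_encoder(model: GanModel, images, hp: GanHyperparams | None = None) -> GanModel:
    """izi_f stage: train E with G and D frozen.

    Logs ``loss_images``, ``loss_features`` and their weighted sum
    ``loss_izi`` at every step.
    """
    if not model.gan_trained:
        raise ValueError("generator/critic must be trained before the encoder")
    hp = hp or model.hp
    x_all = _as_batch_matrix(images, hp)
    rng = np.random.default_rng(hp.seed + 1)

    G, D, E = model.generator, model.critic, model.encoder
    opt_E = Adam(E.params, E.grads, hp.learning_rate, hp.beta1, hp.beta2)
    n_steps = hp.encoder_steps if hp.encoder_steps is not None \
        else _n_generator_steps(hp, len(x_all))
    k = hp.k_feature_weight
    n = hp.n_pixels
    m = D.fc1.W.shape[1]
    B = hp.batch_size

    log = {"loss_images": [], "loss_features": [], "loss_izi": []}
    for step in range(n_steps):
        idx = rng.integers(0, len(x_all), size=B)
        x = x_all[idx]
        E.zero_grad()
        z = E(x)
        x_rec = G(z)
        _, f_real = D.forward(x)
        _, f_rec = D.forward(x_rec)

        li = float(((x - x_rec) ** 2).sum() / (B * n))
        lf = float(((f_real - f_rec) ** 2).sum() / (B * m))
        lizi = li + k * lf
        if not np.isfinite(lizi):
            raise FloatingPointError(f"non-finite encoder loss at step {step}")

        # d loss / d x_rec: image term plus feature term routed through D
        grad_rec = 2.0 * (x_rec - x) / (B * n)
        if k != 0.0:
            D.zero_grad()
            grad_rec = grad_rec + D.backward_from_features(
                2.0 * k * (f_rec - f_real) / (B * m))
            D.zero_grad()
        G.zero_grad()
        grad_z = G.backward(grad_rec)
        G.zero_grad()
        E.backward(grad_z)
        opt_E.step()

        log["loss_images"].append(li)
        log["loss_features"].append(lf)
        log["loss_izi"].append(lizi)

    model.training_log["encoder"] = log
    model.encoder_trained = True
    return model


def compute_losses(X, model: GanModel) -> tuple[float, float]:
    """Per-image residuals (Loss_images, Loss_features) for X' = G(E(X)).

    ``X`` may be a single (s, s) image or flat pixel vector.  Both terms are
    mean squares (over n pixels and m feature channels) and hence >= 0.
    """
    if not model.encoder_trained:
        raise ValueError("encoder is untrained; run train_encoder first")
    x = np.asarray(X, dtype=float)
    single = x.ndim <= 2 and (x.ndim == 1 or x.shape[0] == x.shape[1])
    batch = x.reshape(1, -1) if single else _as_batch_matrix(x, model.hp)
    if batch.shape[1] != model.hp.n_pixels:
        raise ValueError(
            f"image has {batch.shape[1]} pixels, model expects {model.hp.n_pixels}")
    x_rec = model.reconstruct(batch)
    f_real = model.features(batch)
    f_rec = model.features(x_rec)
    li = float(((batch - x_rec) ** 2).mean())
    lf = float(((f_real - f_rec) ** 2).mean())
    return li, lf


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_model(model: GanModel, out_dir) -> None:
    """Write weights (npz) plus a JSON manifest of hyperparameters/state."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for tag, net in (("g", model.generator.params),
                     ("d", model.critic.params),
                     ("e", model.encoder.params)):
        for i, p in enumerate(net):
            arrays[f"{tag}{i}"] = p
    np.savez(out / "weights.npz", **arrays)
    manifest = {
        "hyperparams": asdict(model.hp),
        "gan_trained": model.gan_trained,
        "encoder_trained": model.encoder_trained,
        "n_gan_steps": len(model.training_log.get("critic_loss", [])),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if model.training_log.get("critic_loss"):
        import pandas as pd
        pd.DataFrame({k: v for k, v in model.training_log.items()
                      if isinstance(v, list)}).to_csv(
            out / "training_log.csv", index=False)


def load_model(model_dir) -> GanModel:
    model_dir = Path(model_dir)
    manifest_path = model_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no model manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    hp = GanHyperparams(**manifest["hyperparams"])
    rng = np.random.default_rng(hp.seed)
    model = GanModel(_build_generator(hp, rng),
                     Critic(hp.n_pixels, hp.hidden_dim, rng),
                     _build_encoder(hp, rng), hp)
    with np.load(model_dir / "weights.npz") as data:
        for tag, params in (("g", model.generator.params),
                            ("d", model.critic.params),
                            ("e", model.encoder.params)):
            for i, p in enumerate(params):
                p[...] = data[f"{tag}{i}"]
    model.gan_trained = manifest["gan_trained"]
    model.encoder_trained = manifest["encoder_trained"]
    return model
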