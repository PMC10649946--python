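"""A small multivariate GAN that synthesizes 3D MHD distortion templates.

The generator is recurrent: a dense layer expands a 250-dimensional latent
vector, which is reshaped into a length-250 univariate sequence, passed
through a bidirectional LSTM (24 hidden units, sum merge), dropout, and a
per-timestep dense layer with Tanh, yielding a 250 x 3 template in (-1, 1).

The discriminator is convolutional: four Conv1D layers (32/64/128/256
filters, kernel 16, stride 1, same padding, LeakyReLU) with max-pooling
after the 2nd and 4th, then flatten and a single sigmoid unit.

Both are trained adversarially with binary cross-entropy and Adam
(beta1=0.5, beta2=0.9); learning rates start at 2e-4 (discriminator) and
4e-4 (generator) and are halved every 5 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .mhd_extraction import (DistortionTemplate, TemplateDatabase,
                             TEMPLATE_COMPONENTS, TEMPLATE_LENGTH)
from .signal_io import ValidationError


@dataclass
class GanConfig:
    """Hyperparameters of the template GAN (defaults = published setup)."""

    latent_dim: int = 250
    batch_size: int = 32
    epochs: int = 100
    conv_filters: tuple[int, ...] = (32, 64, 128, 256)
    kernel_size: int = 16
    stride: int = 1
    pool_after_layers: frozenset = frozenset({2, 4})
    bilstm_units: int = 24
    dropout_rate: float = 0.5
    dense_init_std: float = 0.02
    beta1: float = 0.5
    beta2: float = 0.9
    lr_discriminator: float = 0.0002
    lr_generator: float = 0.0004
    lr_halving_period: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("latent_dim", "batch_size", "epochs", "kernel_size",
                     "stride", "bilstm_units", "lr_halving_period"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValidationError(f"{name} must be a positive integer, got {v!r}")
        if not (0 <= self.dropout_rate < 1):
            raise ValidationError(f"dropout_rate must be in [0, 1)")
        if min(self.lr_discriminator, self.lr_generator) <= 0:
            raise ValidationError("learning rates must be positive")

    def learning_rate_at(self, epoch_index: int, lr0: float) -> float:
        """Step decay: halve every ``lr_halving_period`` epochs (0-based
        epoch index; epochs 0-4 run at lr0, 5-9 at lr0/2, 10-14 at lr0/4...)."""
        return lr0 * 0.5 ** (epoch_index // self.lr_halving_period)


@dataclass
class GanModel:
    generator: nn.Sequential
    discriminator: nn.Sequential
    config: GanConfig
    loss_history: dict = field(default_factory=lambda: {"discriminator": [],
                                                        "generator": []})


def build_discriminator(cfg: GanConfig, rng: np.random.Generator | None = None
                        ) -> tuple[nn.Sequential, list[dict]]:
    """CNN discriminator: 250 x 3 template -> probability of being measured.

    Returns the network and a per-layer trainable-parameter report.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    layers: list[nn.Layer] = []
    in_ch = TEMPLATE_COMPONENTS
    for i, filters in enumerate(cfg.conv_filters, start=1):
        layers.append(nn.Conv1D(in_ch, filters, cfg.kernel_size, rng,
                                name=f"conv1d_{i}"))
        layers.append(nn.LeakyReLU())
        if i in cfg.pool_after_layers:
            layers.append(nn.MaxPool1D(2))
        in_ch = filters
    layers.append(nn.Flatten())
    pooled_len = TEMPLATE_LENGTH
    for i in range(1, len(cfg.conv_filters) + 1):
        if i in cfg.pool_after_layers:
            pooled_len //= 2
    layers.append(nn.Dense(pooled_len * in_ch, 1, rng, name="dense_out"))
    layers.append(nn.Sigmoid())
    net = nn.Sequential(layers)
    return net, net.parameter_report()


def build_generator(cfg: GanConfig, rng: np.random.Generator | None = None
                    ) -> tuple[nn.Sequential, list[dict]]:
    """RNN generator: latent vector (250) -> 250 x 3 template in (-1, 1)."""
    rng = rng or np.random.default_rng(cfg.seed)
    layers: list[nn.Layer] = [
        nn.Dense(cfg.latent_dim, TEMPLATE_LENGTH, rng,
                 init_std=cfg.dense_init_std, name="dense_latent"),
        nn.Reshape((TEMPLATE_LENGTH, 1)),
        nn.BiLSTM(1, cfg.bilstm_units, rng),
        nn.Dropout(cfg.dropout_rate, rng),
        nn.Dense(cfg.bilstm_units, TEMPLATE_COMPONENTS, rng, name="dense_out"),
        nn.Tanh(),
    ]
    net = nn.Sequential(layers)
    return net, net.parameter_report()


def train_gan(db: TemplateDatabase, cfg: GanConfig | None = None) -> GanModel:
    """Adversarial training on measured templates.

    Per batch: one discriminator update on an equal mix of measured and
    generated templates (labels 1/0), then one generator update driving the
    discriminator's output on fresh samples toward 1.  Losses are recorded
    per epoch (mean over batches); NaN loss aborts with a diagnostic.
    """
    cfg = cfg or GanConfig()
    if len(db) == 0:
        raise ValidationError("cannot train on an empty template database")
    real = db.stack().astype(nn.layers.DTYPE)
    if np.max(np.abs(real)) > 1.0 + 1e-6:
        raise ValidationError("training templates must lie in [-1, 1]")

    rng = np.random.default_rng(cfg.seed)
    gen, _ = build_generator(cfg, rng)
    disc, _ = build_discriminator(cfg, rng)
    opt_d = nn.Adam(disc.params, disc.grads, cfg.lr_discriminator,
                    cfg.beta1, cfg.beta2)
    opt_g = nn.Adam(gen.params, gen.grads, cfg.lr_generator,
                    cfg.beta1, cfg.beta2)
    model = GanModel(generator=gen, discriminator=disc, config=cfg)

    n = real.shape[0]
    for epoch in range(cfg.epochs):
        opt_d.lr = cfg.learning_rate_at(epoch, cfg.lr_discriminator)
        opt_g.lr = cfg.learning_rate_at(epoch, cfg.lr_generator)
        order = rng.permutation(n)
        d_losses, g_losses = [], []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            b = len(idx)

            # --- discriminator step: half measured, half generated ---
            z = rng.standard_normal((b, cfg.latent_dim)).astype(nn.layers.DTYPE)
            fake = gen(z, training=True)
            x = np.concatenate([real[idx], fake], axis=0)
            y = np.concatenate([np.ones((b, 1)), np.zeros((b, 1))]
                               ).astype(nn.layers.DTYPE)
            disc.zero_grad()
            p = disc(x, training=True)
            d_loss, dp = nn.binary_cross_entropy(p, y)
            disc.backward(dp)
            opt_d.step()

            # --- generator step: fool the discriminator ---
            z = rng.standard_normal((cfg.batch_size, cfg.latent_dim)
                                    ).astype(nn.layers.DTYPE)
            gen.zero_grad()
            disc.zero_grad()  # scratch gradients only; discriminator not updated
            fake = gen(z, training=True)
            p = disc(fake, training=True)
            g_loss, dp = nn.binary_cross_entropy(
                p, np.ones((cfg.batch_size, 1), dtype=nn.layers.DTYPE))
            dfake = disc.backward(dp)
            gen.backward(dfake)
            opt_g.step()

            if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
                raise FloatingPointError(
                    f"non-finite GAN loss at epoch {epoch}: "
                    f"d={d_loss}, g={g_loss}")
            d_losses.append(d_loss)
            g_losses.append(g_loss)
        model.loss_history["discriminator"].append(float(np.mean(d_losses)))
        model.loss_history["generator"].append(float(np.mean(g_losses)))
    return model


def sample_templates(model: GanModel, n: int, seed: int | None = None
                     ) -> TemplateDatabase:
    """Draw ``n`` synthesized templates (dropout off; values in (-1, 1))."""
    if n <= 0:
        raise ValidationError(f"number of templates must be positive, got {n}")
    rng = np.random.default_rng(model.config.seed if seed is None else seed)
    z = rng.standard_normal((n, model.config.latent_dim)).astype(nn.layers.DTYPE)
    out = model.generator(z, training=False)
    templates = [DistortionTemplate(window=np.asarray(w, dtype=float),
                                    provenance="synthesized",
                                    source_id=f"gan:{i}")
                 for i, w in enumerate(out)]
    return TemplateDatabase(templates=templates,
                            metadata={"provenance": "synthesized", "n": n,
                                      "seed": seed,
                                      "config": asdict(model.config)})


def median_curve(db: TemplateDatabase) -> np.ndarray:
    """Per-sample, per-component median across the database (250 x 3)."""
    return np.median(db.stack(), axis=0)
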