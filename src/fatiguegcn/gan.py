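"""Per-class GAN augmentation of normalized EEG windows.

One generator/discriminator pair is trained per fatigue class on that
class's (min-max normalized) training windows, then sampled to raise the
class's window count to a target (2,920 per class by default, matching
the augmentation the full-scale study applies to 1,250 real windows).

The generator is a four-stage 1-D convolutional stack whose temporal
lengths grow 128 -> 256 -> 512 -> window length, fed by a dense projection
of a 100-d latent vector; its output is sigmoid-squashed so synthetic
windows live in [0, 1] like the normalized real ones.  The discriminator
is four fully connected layers (512, 256, 128, 1) with dropout after the
first.  Training uses the non-saturating binary cross-entropy GAN loss
with Adam.  Real windows are normalized first, then augmented; synthetic
windows carry an ``is_augmented`` provenance flag that downstream splits
preserve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import WindowedDataset
from .nn import (
    Adam,
    Conv1d,
    Dense,
    Dropout,
    Flatten,
    LeakyReLU,
    ReLU,
    Reshape,
    Resize1d,
    Sequential,
    Sigmoid,
    bce_with_logits,
)

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "GANConfig",
    "GAN",
    "build_gan",
    "train_gan",
    "synthesize_windows",
    "augment_to_count",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """1-D convolutional generator: four conv stages at growing temporal lengths."""

    latent_dim: int = 100
    layer_widths: tuple[int, ...] = (128, 256, 512, 1250)
    hidden_channels: tuple[int, ...] = (16, 16, 8)
    kernel_size: int = 5

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if len(self.layer_widths) != 4 or any(w < 1 for w in self.layer_widths):
            raise ValueError("layer_widths must be four positive temporal lengths")
        if len(self.hidden_channels) != 3:
            raise ValueError("hidden_channels must list three conv channel counts")


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Four fully connected layers; dropout after the first."""

    layer_widths: tuple[int, ...] = (512, 256, 128, 1)
    dropout_rate_first_layer: float = 0.3

    def __post_init__(self) -> None:
        if len(self.layer_widths) != 4:
            raise ValueError("discriminator must have exactly 4 fully connected layers")
        if self.layer_widths[-1] != 1:
            raise ValueError("final discriminator width must be 1")
        if not 0.0 <= self.dropout_rate_first_layer < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")


@dataclass
class GANConfig:
    learning_rate: float = 0.001
    iterations: int = 500
    batch_size: int = 10
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.iterations < 1 or self.batch_size < 1:
            raise ValueError("GAN config values must be positive")


class GAN:
    """Generator/discriminator pair over windows of shape (n_channels, window_len)."""

    def __init__(self, gen_spec: GeneratorSpec, disc_spec: DiscriminatorSpec,
                 n_channels: int, window_len: int, seed: int = 0) -> None:
        if gen_spec.layer_widths[-1] != window_len:
            raise ValueError(
                f"final generator width {gen_spec.layer_widths[-1]} must equal "
                f"the real-window length {window_len}"
            )
        self.gen_spec = gen_spec
        self.disc_spec = disc_spec
        self.n_channels = n_channels
        self.window_len = window_len
        rng = np.random.default_rng(seed)
        w0, w1, w2, w3 = gen_spec.layer_widths
        c0, c1, c2 = gen_spec.hidden_channels
        k = gen_spec.kernel_size
        self.generator = Sequential(
            Dense(gen_spec.latent_dim, c0 * w0, rng, name="gen.project"),
            Reshape((c0, w0)),
            ReLU(),
            Conv1d(c0, c1, k, rng, name="gen.conv1"),
            ReLU(),
            Resize1d(w0, w1),
            Conv1d(c1, c2, k, rng, name="gen.conv2"),
            ReLU(),
            Resize1d(w1, w2),
            Conv1d(c2, c2, k, rng, name="gen.conv3"),
            ReLU(),
            Resize1d(w2, w3),
            Conv1d(c2, n_channels, k, rng, name="gen.conv4"),
            Sigmoid(),
        )
        d1, d2, d3, _ = disc_spec.layer_widths
        self.discriminator = Sequential(
            Flatten(),
            Dense(n_channels * window_len, d1, rng, name="disc.fc1"),
            Dropout(disc_spec.dropout_rate_first_layer, rng),
            LeakyReLU(0.2),
            Dense(d1, d2, rng, name="disc.fc2"),
            LeakyReLU(0.2),
            Dense(d2, d3, rng, name="disc.fc3"),
            LeakyReLU(0.2),
            Dense(d3, 1, rng, name="disc.fc4"),
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal((n, self.gen_spec.latent_dim))
        return self.generator.forward(z)

    def discriminate(self, windows: np.ndarray) -> np.ndarray:
        """P(real) per window, in (0, 1)."""
        logits = self.discriminator.forward(np.asarray(windows, dtype=float))
        return 1.0 / (1.0 + np.exp(-np.clip(logits[:, 0], -60, 60)))


def build_gan(gen_spec: GeneratorSpec, disc_spec: DiscriminatorSpec,
              n_channels: int = 4, window_len: int | None = None, seed: int = 0) -> GAN:
    """Instantiate the pair; the generator's final width must equal ``window_len``."""
    if window_len is None:
        window_len = gen_spec.layer_widths[-1]
    return GAN(gen_spec, disc_spec, n_channels, window_len, seed)


def _as_array(real_windows) -> np.ndarray:
    if isinstance(real_windows, WindowedDataset):
        return real_windows.X
    arr = np.asarray(real_windows, dtype=float)
    if arr.ndim != 3:
        raise ValueError("real windows must be (n, channels, samples)")
    return arr


def train_gan(real_windows, config: GANConfig,
              gen_spec: GeneratorSpec | None = None,
              disc_spec: DiscriminatorSpec | None = None) -> tuple[GAN, dict[str, list[float]]]:
    """Adversarial training on one class's windows; returns the pair and loss history.

    Runs exactly ``config.iterations`` generator steps (each preceded by one
    discriminator step). Deterministic given ``config.seed`` on a fixed platform.
    """
    X = _as_array(real_windows)
    n, n_channels, window_len = X.shape
    if n < config.batch_size:
        raise ValueError(f"{n} real windows < batch size {config.batch_size}")
    if gen_spec is None:
        gen_spec = GeneratorSpec(layer_widths=(128, 256, 512, window_len))
    if disc_spec is None:
        disc_spec = DiscriminatorSpec()
    gan = build_gan(gen_spec, disc_spec, n_channels, window_len, seed=config.seed)
    rng = np.random.default_rng(config.seed + 1)
    if config.optimizer.lower() != "adam":
        raise ValueError("GAN training supports the Adam optimizer")
    opt_d = Adam(gan.discriminator.parameters(), lr=config.learning_rate, betas=(0.5, 0.999))
    opt_g = Adam(gan.generator.parameters(), lr=config.learning_rate, betas=(0.5, 0.999))
    history: dict[str, list[float]] = {"d_loss": [], "g_loss": []}
    b = config.batch_size
    for _ in range(config.iterations):
        # discriminator step: real -> 1, fake -> 0
        idx = rng.choice(n, size=b, replace=False)
        real = X[idx]
        fake = gan.sample(b, rng)
        gan.discriminator.zero_grad()
        logits_r = gan.discriminator.forward(real)
        loss_r, grad_r = bce_with_logits(logits_r, np.ones_like(logits_r))
        gan.discriminator.backward(grad_r)
        logits_f = gan.discriminator.forward(fake)
        loss_f, grad_f = bce_with_logits(logits_f, np.zeros_like(logits_f))
        gan.discriminator.backward(grad_f)
        opt_d.step()
        d_loss = loss_r + loss_f

        # generator step: non-saturating loss, fake -> 1 through the discriminator
        z = rng.standard_normal((b, gen_spec.latent_dim))
        gan.generator.zero_grad()
        gan.discriminator.zero_grad()
        fake = gan.generator.forward(z)
        logits = gan.discriminator.forward(fake)
        g_loss, grad = bce_with_logits(logits, np.ones_like(logits))
        grad_windows = gan.discriminator.backward(grad)
        gan.discriminator.zero_grad()  # discriminator is a fixed critic here
        gan.generator.backward(grad_windows)
        opt_g.step()

        if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
            raise RuntimeError("non-finite GAN loss; training diverged")
        history["d_loss"].append(float(d_loss))
        history["g_loss"].append(float(g_loss))
    return gan, history


def synthesize_windows(gan: GAN, n: int, seed: int = 0) -> np.ndarray:
    """Draw ``n`` synthetic windows, batched to bound memory; deterministic in ``seed``."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return np.empty((0, gan.n_channels, gan.window_len))
    rng = np.random.default_rng(seed)
    out = []
    for start in range(0, n, 128):
        out.append(gan.sample(min(128, n - start), rng))
    return np.concatenate(out, axis=0)


def augment_to_count(class_windows: WindowedDataset, target_count: int,
                     config: GANConfig,
                     gen_spec: GeneratorSpec | None = None,
                     disc_spec: DiscriminatorSpec | None = None) -> WindowedDataset:
    """Raise one class's window count to ``target_count`` with GAN samples.

    All real windows pass through untouched; synthetic windows are appended
    with ``is_augmented=True`` provenance.
    """
    n_real = len(class_windows)
    if target_count < n_real:
        raise ValueError(f"target {target_count} below current count {n_real}")
    labels = set(class_windows.y.tolist())
    if len(labels) != 1:
        raise ValueError("augment_to_count expects windows from a single class")
    label = labels.pop()
    real = WindowedDataset(
        class_windows.X, class_windows.y, class_windows.ids,
        [dict(p, is_augmented=bool(p.get("is_augmented", False)))
         for p in class_windows.provenance],
    )
    n_new = target_count - n_real
    if n_new == 0:
        return real
    gan, _ = train_gan(real, config, gen_spec, disc_spec)
    fake = synthesize_windows(gan, n_new, seed=config.seed + 2)
    synth = WindowedDataset(
        fake,
        np.full(n_new, label, dtype=int),
        [f"c{label}gan{i:05d}" for i in range(n_new)],
        [
            {"class_id": int(label), "is_augmented": True, "source": "gan",
             "seed": config.seed}
            for i in range(n_new)
        ],
    )
    return WindowedDataset.concat([real, synth])
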