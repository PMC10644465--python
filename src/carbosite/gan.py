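"""GAN-based oversampling of the minority class in feature space.

A small generator/discriminator pair of multi-layer perceptrons is
trained adversarially on the (min-max-scaled) positive feature vectors:
the discriminator maximises log D(x) + log(1 - D(G(t))) on real and
generated batches, the generator is trained with the non-saturating
objective (maximise log D(G(t))) — a standard stability substitute for
literally minimising log(1 - D(G(t))), which starves the generator of
gradient early in training on tiny datasets. Noise t is standard normal;
the generator's sigmoid output keeps samples inside [0, 1]^d to match
the scaled feature space.

Both networks are plain numpy with hand-written backprop and Adam; the
whole procedure is seeded and reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .containers import FeatureMatrix

__all__ = ["GanConfig", "TrainedGenerator", "train_gan", "gan_oversample"]

_LEAK = 0.2


@dataclass
class GanConfig:
    noise_dim: int = 32
    hidden_sizes: tuple[int, ...] = (128, 128)
    epochs: int = 200
    min_updates: int = 2000  # floor on optimizer steps; tiny minorities
    # yield one minibatch per epoch, and 200 Adam steps at lr 2e-4
    # demonstrably leave the generator off-manifold
    batch_size: int = 32
    learning_rate: float = 2e-4
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(self.hidden_sizes)
        if min(self.noise_dim, self.epochs, self.min_updates, self.batch_size,
               *self.hidden_sizes) < 1:
            raise ValueError("all GAN size/count parameters must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({**asdict(self), "hidden_sizes": list(self.hidden_sizes)}, fh)

    @classmethod
    def from_yaml(cls, path) -> "GanConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


class _MLP:
    """Fully connected net with LeakyReLU hidden layers and a linear head.

    Keeps Adam state per parameter; `backward` returns the gradient with
    respect to the input so the generator can receive gradient through
    the discriminator.
    """

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.W, self.b = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            self.W.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self._adam = [
            {"mW": np.zeros_like(W), "vW": np.zeros_like(W),
             "mb": np.zeros_like(b), "vb": np.zeros_like(b)}
            for W, b in zip(self.W, self.b)
        ]
        self._t = 0

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._acts = [x]
        h = x
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < last:
                h = np.where(h > 0, h, _LEAK * h)
            self._acts.append(h)
        return h

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        """Accumulate parameter gradients for the last forward pass."""
        self.gW = [None] * len(self.W)
        self.gb = [None] * len(self.b)
        g = grad_out
        last = len(self.W) - 1
        for i in range(last, -1, -1):
            if i < last:
                post = self._acts[i + 1]  # post-activation output of layer i
                g = g * np.where(post > 0, 1.0, _LEAK)
            self.gW[i] = self._acts[i].T @ g
            self.gb[i] = g.sum(axis=0)
            g = g @ self.W[i].T
        return g

    def step(self, lr: float, beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self._t += 1
        t = self._t
        for W, b, gW, gb, st in zip(self.W, self.b, self.gW, self.gb, self._adam):
            for p, g, mk, vk in ((W, gW, "mW", "vW"), (b, gb, "mb", "vb")):
                st[mk] = beta1 * st[mk] + (1 - beta1) * g
                st[vk] = beta2 * st[vk] + (1 - beta2) * g * g
                mhat = st[mk] / (1 - beta1**t)
                vhat = st[vk] / (1 - beta2**t)
                p -= lr * mhat / (np.sqrt(vhat) + eps)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


@dataclass
class TrainedGenerator:
    """A fitted generator: maps standard-normal noise to [0,1]^d samples."""

    net: _MLP
    noise_dim: int
    d: int
    seed: int
    loss_history: list[dict] = field(default_factory=list)

    def generate(self, n: int, seed: int | None = None) -> np.ndarray:
        if n < 0:
            raise ValueError("n must be non-negative")
        if n == 0:
            return np.empty((0, self.d))
        rng = np.random.default_rng(self.seed + 1 if seed is None else seed)
        t = rng.standard_normal((n, self.noise_dim))
        return _sigmoid(self.net.forward(t))

    def save_loss_history(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch,d_loss,g_loss\n")
            for row in self.loss_history:
                fh.write(f"{row['epoch']},{row['d_loss']:.6f},{row['g_loss']:.6f}\n")


def train_gan(pos, config: GanConfig | None = None) -> TrainedGenerator:
    """Fit the generator/discriminator pair on minority-class vectors.

    Expects features scaled to [0, 1]; alternates one discriminator and
    one generator update per minibatch.
    """
    config = config or GanConfig()
    X = pos.X if isinstance(pos, FeatureMatrix) else np.asarray(pos, dtype=float)
    n, d = X.shape
    if n < 2:
        raise ValueError("too few samples for the generator to learn (need >= 2 positives)")
    if X.min() < -1e-9 or X.max() > 1 + 1e-9:
        raise ValueError("GAN oversampling expects min-max-scaled features in [0, 1]")

    rng = np.random.default_rng(config.seed)
    G = _MLP([config.noise_dim, *config.hidden_sizes, d], rng)
    D = _MLP([d, *config.hidden_sizes, 1], rng)
    # Start generation at the data's marginal means (sigmoid^-1 of the
    # column means); on sparse high-dimensional features the default 0.5
    # start is far from the data and the budgeted epochs cannot close it.
    mu = np.clip(X.mean(axis=0), 1e-3, 1.0 - 1e-3)
    G.b[-1] = np.log(mu / (1.0 - mu))
    batch = min(config.batch_size, n)
    lr = config.learning_rate
    history = []
    steps_per_epoch = -(-n // batch)
    n_epochs = max(config.epochs, -(-config.min_updates // steps_per_epoch))

    for epoch in range(n_epochs):
        order = rng.permutation(n)
        d_losses, g_losses = [], []
        for start in range(0, n, batch):
            real = X[order[start : start + batch]]
            nb = real.shape[0]

            # Discriminator step: real -> 1, generated -> 0.
            t = rng.standard_normal((nb, config.noise_dim))
            fake = _sigmoid(G.forward(t))
            logit_r = D.forward(real)
            grad_r = (_sigmoid(logit_r) - 1.0) / nb  # d BCE / d logit
            D.backward(grad_r)
            gWr, gbr = D.gW, D.gb
            logit_f = D.forward(fake)
            grad_f = _sigmoid(logit_f) / nb
            D.backward(grad_f)
            for i in range(len(D.W)):
                D.gW[i] += gWr[i]
                D.gb[i] += gbr[i]
            D.step(lr)
            d_losses.append(
                float(
                    np.mean(np.logaddexp(0, -logit_r)) + np.mean(np.logaddexp(0, logit_f))
                )
            )

            # Generator step (non-saturating): fool D toward 1.
            t = rng.standard_normal((nb, config.noise_dim))
            z = G.forward(t)
            fake = _sigmoid(z)
            logit = D.forward(fake)
            g_losses.append(float(np.mean(np.logaddexp(0, -logit))))
            grad = (_sigmoid(logit) - 1.0) / nb
            grad_fake = D.backward(grad)  # input grad; D params not stepped
            G.backward(grad_fake * fake * (1.0 - fake))  # through output sigmoid
            G.step(lr)

        history.append(
            {"epoch": epoch, "d_loss": float(np.mean(d_losses)), "g_loss": float(np.mean(g_losses))}
        )

    return TrainedGenerator(net=G, noise_dim=config.noise_dim, d=d, seed=config.seed,
                            loss_history=history)


def gan_oversample(pos, n_new: int, config: GanConfig | None = None) -> FeatureMatrix:
    """Return the real positives stacked with n_new generated positives."""
    if n_new < 0:
        raise ValueError("n_new must be non-negative")
    X = pos.X if isinstance(pos, FeatureMatrix) else np.asarray(pos, dtype=float)
    names = pos.feature_names if isinstance(pos, FeatureMatrix) else None
    gen = train_gan(X, config)
    stacked = np.vstack([X, gen.generate(n_new)])
    return FeatureMatrix(
        X=stacked, y=np.ones(stacked.shape[0], dtype=int),
        feature_names=names, scaling_state="minmax",
    )
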