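"""Variational autoencoder for tabular augmentation of small plant groups.

Architecture (per the augmentation protocol): fully connected encoder
and decoder with two hidden layers each (64 and 32 units, mirrored in
the decoder), batch normalization, LeakyReLU and dropout on every hidden
layer.  The encoder emits a latent mean mu and log-variance logvar over
an 8-dimensional latent space; a reparameterized draw
``z = mu + exp(logvar/2) * eps`` feeds the decoder.  Training minimizes

    MSE(x, xhat)  +  lambda * KL(q(z|x) || N(0, I))

with the analytic Gaussian KL, Adam, fixed epoch count.  Sampling
decodes standard-normal latent draws (inference mode: running batch-norm
statistics, no dropout).

Inputs are expected pre-standardized by the caller (the augmentation
layer z-scores each group before training and de-standardizes samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, BatchNorm, Dense, Dropout, LeakyReLU, Sequential, minibatches

__all__ = ["VAEConfig", "TrainedVAE", "gaussian_kl", "train_vae_on_matrix", "decode_samples"]


@dataclass(frozen=True)
class VAEConfig:
    """Hyperparameters of the augmentation VAE."""

    latent_dim: int = 8
    hidden: tuple[int, int] = (64, 32)
    epochs: int = 500
    batch_size: int = 32
    learning_rate: float = 1e-3
    kl_weight: float = 0.1  # lambda
    dropout: float = 0.1
    #: draw from the full Gaussian likelihood p(x|z) = N(decoder(z), resid^2)
    #: rather than the decoder mean alone.  On by default: the mean-only
    #: draw under-disperses the synthetic marginals (the latent space does
    #: not carry the residual variance), which the KL quality control
    #: flags; sampling the likelihood restores the original spread.
    sample_observation_noise: bool = True

    def validate(self, input_dim: int) -> None:
        if min(self.latent_dim, *self.hidden, self.epochs, self.batch_size) <= 0:
            raise ValueError("all VAE size/epoch parameters must be positive")
        if self.learning_rate <= 0 or self.kl_weight < 0:
            raise ValueError("learning_rate must be > 0 and kl_weight >= 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.latent_dim >= input_dim and input_dim > 1:
            raise ValueError(
                f"latent_dim ({self.latent_dim}) must be < input dim ({input_dim})"
            )


def gaussian_kl(mu: np.ndarray, logvar: np.ndarray) -> float:
    """Analytic KL(N(mu, diag(exp(logvar))) || N(0, I)), mean over rows.

    -1/2 * sum(1 + logvar - mu^2 - exp(logvar)); exactly 0 when mu = 0
    and logvar = 0.
    """
    per_row = -0.5 * np.sum(1.0 + logvar - mu**2 - np.exp(logvar), axis=1)
    return float(np.mean(per_row))


def _hidden_block(n_in: int, n_out: int, dropout: float, rng) -> list:
    return [Dense(n_in, n_out, rng), BatchNorm(n_out), LeakyReLU(), Dropout(dropout, rng)]


@dataclass
class TrainedVAE:
    """A trained generator plus its loss trace.

    ``resid_sd`` is the per-feature standard deviation of the decoder's
    reconstruction residuals on the training data (inference mode): the
    observation-noise scale of the Gaussian likelihood the MSE loss
    implies, available for full p(x|z) sampling.
    """

    encoder: Sequential
    dec: Sequential
    latent_dim: int
    input_dim: int
    loss_trace: list[float] = field(default_factory=list)
    resid_sd: np.ndarray | None = None


def train_vae_on_matrix(
    X: np.ndarray, config: VAEConfig, rng: np.random.Generator
) -> TrainedVAE:
    """Train a VAE on a standardized (n, d) matrix; deterministic given rng."""
    n, d = X.shape
    config.validate(d)
    h1, h2 = config.hidden

    # encoder trunk -> one head producing [mu | logvar]
    enc = Sequential(
        [
            *_hidden_block(d, h1, config.dropout, rng),
            *_hidden_block(h1, h2, config.dropout, rng),
            Dense(h2, 2 * config.latent_dim, rng),
        ]
    )
    dec = Sequential(
        [
            *_hidden_block(config.latent_dim, h2, config.dropout, rng),
            *_hidden_block(h2, h1, config.dropout, rng),
            Dense(h1, d, rng),
        ]
    )
    opt = Adam(enc.params + dec.params, lr=config.learning_rate)

    trace = []
    lam = config.kl_weight
    zdim = config.latent_dim
    for _ in range(config.epochs):
        epoch_loss, n_seen = 0.0, 0
        for idx in minibatches(n, config.batch_size, rng):
            xb = X[idx]
            m = len(idx)
            stats = enc.forward(xb, train=True)
            mu, logvar = stats[:, :zdim], stats[:, zdim:]
            logvar = np.clip(logvar, -15.0, 15.0)
            eps = rng.standard_normal(mu.shape)
            std = np.exp(0.5 * logvar)
            z = mu + std * eps
            xhat = dec.forward(z, train=True)

            diff = xhat - xb
            recon = float(np.mean(diff**2))
            kl = gaussian_kl(mu, logvar)
            loss = recon + lam * kl

            # backward: d(recon)/d(xhat) = 2*diff / (m*d)
            gz = dec.backward(2.0 * diff / diff.size)
            # reparameterization: z = mu + exp(logvar/2)*eps
            gmu = gz + lam * mu / m  # KL grad wrt mu: mu/m (mean over rows)
            glogvar = gz * std * eps * 0.5 + lam * 0.5 * (np.exp(logvar) - 1.0) / m
            enc.backward(np.concatenate([gmu, glogvar], axis=1))
            opt.step(enc.grads + dec.grads)

            epoch_loss += loss * m
            n_seen += m
        trace.append(epoch_loss / n_seen)
        if not np.isfinite(trace[-1]):
            raise RuntimeError(f"VAE training diverged (non-finite loss); trace={trace}")

    # observation-noise scale: reconstruction residual sd per feature
    stats = enc.forward(X, train=False)
    mu = stats[:, :zdim]
    xhat = dec.forward(mu, train=False)
    resid_sd = np.sqrt(np.mean((X - xhat) ** 2, axis=0))
    return TrainedVAE(
        encoder=enc, dec=dec, latent_dim=zdim, input_dim=d,
        loss_trace=trace, resid_sd=resid_sd,
    )


def decode_samples(
    gen: TrainedVAE, m: int, rng: np.random.Generator,
    observation_noise: bool = False,
) -> np.ndarray:
    """Sample m rows by decoding standard-normal latent draws (inference
    mode).  With ``observation_noise`` the residual Gaussian noise of the
    decoder likelihood is added on top of the decoder mean."""
    if m == 0:
        return np.empty((0, gen.input_dim))
    z = rng.standard_normal((m, gen.latent_dim))
    x = gen.dec.forward(z, train=False)
    if observation_noise and gen.resid_sd is not None:
        x = x + rng.standard_normal(x.shape) * gen.resid_sd
    return x
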