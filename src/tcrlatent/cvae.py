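"""Capacity-controlled beta-VAE over physicochemical TCR arrays.

The encoder is a light 3-layer 1-D CNN (channels 32/64/128, kernels 5/3/3,
stride 1, He init, each followed by batch normalization and leaky ReLU)
whose flattened output feeds two parallel dense heads for the posterior
mean and log-variance.  The decoder maps a latent vector through a dense
ReLU layer to an L_max x 128 array, then three length-preserving
"deconvolutions" (channels 128/64/32, kernels 3/3/5, batch norm + leaky
ReLU) and a final 8-channel width-1 deconvolution with no activation.

Training minimizes

    L = L_recon + beta * | L_KL - n_latent * C |

with Adam: the capacity ``C`` (nats per latent dimension) pins the average
information content of the posterior rather than annealing it.  ``beta = 0``
is the plain-autoencoder limit used as a comparison baseline: sampling and
the KL penalty are disabled and the latent code is the deterministic mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import nn
from .nn.autodiff import Tensor
from .physchem import (AminoAcidFeatureTable, PWM, array_to_pwm,
                       default_feature_table, N_FEATURES)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CVAEConfig:
    n_latent: int = 16
    capacity: float = 2.0           # nats per latent dimension
    beta: float | None = None       # None -> 1, or 10 when capacity == 1
    learning_rate: float = 1e-3
    patience: int = 10
    l_max: int = 28
    seed: int = 0
    batch_size: int = 512
    max_epochs: int = 500
    leaky_slope: float = 0.2
    logvar_bias_init: float = -3.0  # small initial posterior noise

    def __post_init__(self):
        if self.n_latent < 1:
            raise ConfigError("n_latent must be >= 1")
        if self.capacity < 0:
            raise ConfigError("capacity must be >= 0")
        if self.beta is not None and self.beta < 0:
            raise ConfigError("beta must be >= 0 (0 = autoencoder limit)")

    @property
    def resolved_beta(self) -> float:
        if self.beta is not None:
            return float(self.beta)
        return 10.0 if self.capacity == 1 else 1.0


class CVAE(nn.Module):
    def __init__(self, config: CVAEConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        L, slope = config.l_max, config.leaky_slope
        self.slope = slope
        # encoder
        self.enc_conv1 = nn.Conv1d(N_FEATURES, 32, 5, rng)
        self.enc_bn1 = nn.BatchNorm1d(32)
        self.enc_conv2 = nn.Conv1d(32, 64, 3, rng)
        self.enc_bn2 = nn.BatchNorm1d(64)
        self.enc_conv3 = nn.Conv1d(64, 128, 3, rng)
        self.enc_bn3 = nn.BatchNorm1d(128)
        self.fc_mu = nn.Dense(L * 128, config.n_latent, rng)
        self.fc_logvar = nn.Dense(L * 128, config.n_latent, rng)
        # start with a tight posterior so early decoder gradients are not
        # swamped by sampling noise; the capacity penalty re-balances it
        self.fc_logvar.b.data[:] = config.logvar_bias_init
        # decoder
        self.dec_fc = nn.Dense(config.n_latent, L * 128, rng)
        self.dec_conv1 = nn.Conv1d(128, 128, 3, rng)
        self.dec_bn1 = nn.BatchNorm1d(128)
        self.dec_conv2 = nn.Conv1d(128, 64, 3, rng)
        self.dec_bn2 = nn.BatchNorm1d(64)
        self.dec_conv3 = nn.Conv1d(64, 32, 5, rng)
        self.dec_bn3 = nn.BatchNorm1d(32)
        self.dec_out = nn.Conv1d(32, N_FEATURES, 1, rng)

    def encode(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = self.enc_bn1(self.enc_conv1(x)).leaky_relu(self.slope)
        h = self.enc_bn2(self.enc_conv2(h)).leaky_relu(self.slope)
        h = self.enc_bn3(self.enc_conv3(h)).leaky_relu(self.slope)
        flat = h.reshape(h.shape[0], -1)
        return self.fc_mu(flat), self.fc_logvar(flat)

    def decode(self, z: Tensor) -> Tensor:
        L = self.config.l_max
        h = self.dec_fc(z).relu().reshape(z.shape[0], L, 128)
        h = self.dec_bn1(self.dec_conv1(h)).leaky_relu(self.slope)
        h = self.dec_bn2(self.dec_conv2(h)).leaky_relu(self.slope)
        h = self.dec_bn3(self.dec_conv3(h)).leaky_relu(self.slope)
        return self.dec_out(h)

    def reparameterize(self, mu: Tensor, logvar: Tensor,
                       rng: np.random.Generator) -> Tensor:
        eps = rng.standard_normal(mu.shape).astype(mu.data.dtype)
        return mu + (logvar * 0.5).exp() * Tensor(eps)


def build_cvae(config: CVAEConfig | None = None) -> CVAE:
    return CVAE(config or CVAEConfig())


def capacity_loss(x, x_hat, mu, logvar, beta: float, capacity: float,
                  n_latent: int) -> tuple[Tensor, Tensor, Tensor]:
    """(total, recon, kl): recon is per-sample mean squared error, kl the
    closed-form Gaussian-to-standard-normal divergence summed over latent
    dimensions, both averaged over the batch; the penalty is
    ``beta * |kl - n_latent * capacity|``."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    x_hat = x_hat if isinstance(x_hat, Tensor) else Tensor(x_hat)
    mu = mu if isinstance(mu, Tensor) else Tensor(mu)
    logvar = logvar if isinstance(logvar, Tensor) else Tensor(logvar)
    if not (np.isfinite(x.data).all() and np.isfinite(x_hat.data).all()
            and np.isfinite(mu.data).all() and np.isfinite(logvar.data).all()):
        raise FloatingPointError("non-finite inputs to capacity_loss")
    diff = x - x_hat
    recon = (diff * diff).mean()
    kl_per_sample = ((mu * mu + logvar.exp() - 1.0 - logvar) * 0.5).sum(axis=-1)
    kl = kl_per_sample.mean()
    total = recon + (kl - float(n_latent) * float(capacity)).abs() * float(beta)
    return total, recon, kl


@dataclass
class TrainingHistory:
    epochs: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.epochs.append(kwargs)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.epochs)


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train(model: CVAE, train_x: np.ndarray, val_x: np.ndarray,
          config: CVAEConfig | None = None,
          verbose: bool = False) -> tuple[CVAE, TrainingHistory]:
    """Train with Adam + early stopping; restores the best-validation weights.

    ``train_x``/``val_x``: (n, L_max, 8) float arrays of encoded features.
    Validation uses the deterministic posterior mean.
    """
    config = config or model.config
    if len(train_x) == 0:
        raise ValueError("empty training set")
    beta = config.resolved_beta
    train_x = np.asarray(train_x, dtype=nn.get_dtype())
    val_x = np.asarray(val_x, dtype=nn.get_dtype())
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    history = TrainingHistory()
    best_val = np.inf
    best_state: dict[str, np.ndarray] | None = None
    wait = 0
    nC = config.n_latent * config.capacity

    for epoch in range(config.max_epochs):
        model.train()
        tot = rec = klv = 0.0
        nb = 0
        for idx in _iter_batches(len(train_x), config.batch_size, rng):
            xb = Tensor(train_x[idx])
            mu, logvar = model.encode(xb)
            if beta == 0.0:
                z = mu
            else:
                z = model.reparameterize(mu, logvar, rng)
            xhat = model.decode(z)
            total, recon, kl = capacity_loss(
                xb, xhat, mu, logvar, beta, config.capacity, config.n_latent)
            opt.zero_grad()
            total.backward()
            opt.step()
            tot += float(total.data)
            rec += float(recon.data)
            klv += float(kl.data)
            nb += 1
        model.eval()
        v_total, v_recon, v_kl = evaluate(model, val_x, config)
        history.append(epoch=epoch, train_total=tot / nb, train_recon=rec / nb,
                       train_kl=klv / nb, val_total=v_total,
                       val_recon=v_recon, val_kl=v_kl)
        if verbose:
            print(f"epoch {epoch}: train {tot / nb:.4f} "
                  f"val {v_total:.4f} kl/dim {v_kl / config.n_latent:.3f}")
        if v_total < best_val - 1e-6:
            best_val = v_total
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
            wait = 0
        else:
            wait += 1
            if wait >= config.patience:
                break
    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()
    return model, history


def evaluate(model: CVAE, x: np.ndarray,
             config: CVAEConfig | None = None,
             batch_size: int = 1024) -> tuple[float, float, float]:
    """Validation-style loss (deterministic z = mu) in inference mode."""
    config = config or model.config
    beta = config.resolved_beta
    model.eval()
    tot = rec = klv = 0.0
    n = len(x)
    for start in range(0, n, batch_size):
        xb = Tensor(np.asarray(x[start:start + batch_size],
                               dtype=nn.get_dtype()))
        mu, logvar = model.encode(xb)
        xhat = model.decode(mu)
        total, recon, kl = capacity_loss(
            xb, xhat, mu, logvar, beta, config.capacity, config.n_latent)
        w = xb.shape[0] / n
        tot += float(total.data) * w
        rec += float(recon.data) * w
        klv += float(kl.data) * w
    return tot, rec, klv


def embed(model: CVAE, arrays: np.ndarray, batch_size: int = 2048) -> np.ndarray:
    """Deterministic posterior means, (n, n_latent)."""
    arrays = np.asarray(arrays, dtype=nn.get_dtype())
    if arrays.ndim == 2:
        arrays = arrays[None]
    if arrays.shape[1] != model.config.l_max or arrays.shape[2] != N_FEATURES:
        raise ValueError(f"expected (n, {model.config.l_max}, {N_FEATURES}) "
                         f"input, got {arrays.shape}")
    model.eval()
    out = []
    for start in range(0, len(arrays), batch_size):
        mu, _ = model.encode(Tensor(arrays[start:start + batch_size]))
        out.append(mu.data.astype(np.float64))
    return np.concatenate(out, axis=0)


def decode_latents(model: CVAE, z: np.ndarray) -> np.ndarray:
    """Decode latent vectors to raw physicochemical arrays (n, L_max, 8)."""
    z = np.atleast_2d(np.asarray(z, dtype=nn.get_dtype()))
    if z.shape[1] != model.config.n_latent:
        raise ValueError(f"latent width {z.shape[1]} != {model.config.n_latent}")
    model.eval()
    return model.decode(Tensor(z)).data.astype(np.float64)


def decode_to_pwm(model: CVAE, z: np.ndarray,
                  table: AminoAcidFeatureTable | None = None) -> PWM:
    """Decode one latent vector and project onto a PWM."""
    arr = decode_latents(model, z)
    if arr.shape[0] != 1:
        raise ValueError("decode_to_pwm takes a single latent vector")
    return array_to_pwm(arr[0], table or default_feature_table())


def generate_meta_tcr(model: CVAE, cluster_latents: np.ndarray,
                      table: AminoAcidFeatureTable | None = None) -> PWM:
    """PWM decoded from the arithmetic mean latent of a cluster."""
    latents = np.atleast_2d(np.asarray(cluster_latents))
    if latents.size == 0:
        raise ValueError("empty latent list")
    return decode_to_pwm(model, latents.mean(axis=0), table)


def save_model(model: CVAE, path: str | Path) -> None:
    """Checkpoint: .npz weights plus a JSON config sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_arrays())
    path.with_suffix(".json").write_text(json.dumps(asdict(model.config)))


def load_model(path: str | Path) -> CVAE:
    path = Path(path)
    config = CVAEConfig(**json.loads(path.with_suffix(".json").read_text()))
    model = CVAE(config)
    with np.load(path.with_suffix(".npz")) as state:
        model.load_state_arrays({k: state[k] for k in state.files})
    model.eval()
    return model
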