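"""Transformer-based variational autoencoder for 2-D trajectories.

The encoder embeds a trajectory — presented as a single-channel sequence of
length 2T (x series followed by y series) — through a strided "patch"
convolution that lifts the channel dimension from 1 to ``embed_dim``, adds a
learned positional embedding, applies a stack of multi-headed self-attention
blocks, and compresses the result through a two-layer strided convolutional
encoder (kernel sizes 7 and 2) and a dense layer into the mean and log-SD
of a 12-dimensional Gaussian posterior.  The decoder mirrors the path:
dense upsampling, two transpose convolutions inverting the encoder strides,
one attention block, and a final transpose convolution back to the 2T
sequence, which is split into the (x, y) components.

Training minimizes the physics-informed objective of :mod:`lptraj.loss`
with the reparameterization trick; everything is seeded and deterministic.
"""

from __future__ import annotations

import csv
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .core import LabeledTrajectoryDataset, Trajectory
from .loss import LossBreakdown, LossWeights, physics_informed_loss
from .nn import (Adam, Conv1d, ConvTranspose1d, Linear, Module, Tensor,
                 TransformerBlock)

__all__ = ["ModelConfig", "LatentCode", "TrajectoryVAE", "build_model",
           "encode", "sample_and_decode", "reconstruct", "train_vae",
           "generate_trajectories", "evaluate_loss", "save_model", "load_model",
           "GENERATED_LABEL"]

GENERATED_LABEL = "GENERATED"


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    ``patch`` is the stride/kernel of the embedding convolution; the token
    sequence seen by the attention blocks has length ``2 T / patch`` and
    must be divisible by 4 (the two stride-2 encoder convolutions).
    """

    T: int = 200
    embed_dim: int = 128
    n_heads: int = 8
    n_attn_layers: int = 2
    conv_kernels: tuple[int, int] = (7, 2)
    latent_dim: int = 12
    patch: int = 4
    epochs: int = 200
    batch_size: int = 128
    learning_rate: float = 1e-3
    val_frac: float = 0.1
    seed: int = 0
    #: "increments": the decoder emits per-frame steps and positions are
    #: their in-graph cumulative sum (step statistics are then directly
    #: controlled by the output layer); "positions": raw decoder output.
    decoder_output: str = "increments"

    def __post_init__(self):
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if (2 * self.T) % self.patch:
            raise ValueError("2*T must be divisible by patch")
        if (2 * self.T // self.patch) % 4:
            raise ValueError("token length 2*T/patch must be divisible by 4")
        if self.decoder_output not in ("increments", "positions"):
            raise ValueError("decoder_output must be 'increments' or "
                             "'positions'")


@dataclass(frozen=True)
class LatentCode:
    """Posterior mean and SD plus (optionally) a sampled latent vector."""

    mu: np.ndarray
    sigma: np.ndarray
    z: np.ndarray | None = None

    def __post_init__(self):
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma shapes differ")
        if (self.sigma <= 0).any():
            raise ValueError("sigma must be positive")


class TrajectoryVAE(Module):
    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        E = config.embed_dim
        N = 2 * config.T // config.patch
        k1, k2 = config.conv_kernels
        self.n_tokens = N
        self.embed = Conv1d(1, E, config.patch, rng, stride=config.patch)
        self.pos_enc = Tensor(rng.standard_normal((N, E)) * 0.02,
                              requires_grad=True)
        self.enc_blocks = [TransformerBlock(E, config.n_heads, rng)
                           for _ in range(config.n_attn_layers)]
        self.enc_conv1 = Conv1d(E, E, k1, rng, stride=2, padding=k1 // 2)
        self.enc_conv2 = Conv1d(E, E, k2, rng, stride=2)
        self.flat_dim = (N // 4) * E
        self.to_latent = Linear(self.flat_dim, 2 * config.latent_dim, rng)
        self.from_latent = Linear(config.latent_dim, self.flat_dim, rng)
        self.dec_conv1 = ConvTranspose1d(E, E, k2, rng, stride=2)
        self.dec_conv2 = ConvTranspose1d(E, E, k1, rng, stride=2,
                                         padding=k1 // 2,
                                         output_padding=1)
        self.pos_dec = Tensor(rng.standard_normal((N, E)) * 0.02,
                              requires_grad=True)
        self.dec_block = TransformerBlock(E, config.n_heads, rng)
        self.unembed = ConvTranspose1d(E, 1, config.patch, rng,
                                       stride=config.patch)

    # -- paths ------------------------------------------------------------
    def encode_tensors(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """(B, 2, T) -> posterior (mu, log_sigma), each (B, latent_dim)."""
        B = x.shape[0]
        cfg = self.config
        seq = x.reshape(B, 1, 2 * cfg.T)       # x series then y series
        h = self.embed(seq)                     # (B, E, N)
        h = h.transpose(0, 2, 1) + self.pos_enc
        for block in self.enc_blocks:
            h = block(h)
        h = h.transpose(0, 2, 1)
        h = self.enc_conv1(h).gelu()
        h = self.enc_conv2(h).gelu()
        h = h.reshape(B, self.flat_dim)
        out = self.to_latent(h)
        mu = out[:, :cfg.latent_dim]
        log_sigma = out[:, cfg.latent_dim:]
        return mu, log_sigma

    def decode_tensors(self, z: Tensor) -> Tensor:
        """(B, latent_dim) -> reconstructed batch (B, 2, T)."""
        B = z.shape[0]
        cfg = self.config
        E = cfg.embed_dim
        h = self.from_latent(z).gelu().reshape(B, E, self.n_tokens // 4)
        h = self.dec_conv1(h).gelu()
        h = self.dec_conv2(h).gelu()            # (B, E, N)
        h = h.transpose(0, 2, 1) + self.pos_dec
        h = self.dec_block(h)
        h = h.transpose(0, 2, 1)
        seq = self.unembed(h)                   # (B, 1, 2T)
        out = seq.reshape(B, 2, cfg.T)
        if cfg.decoder_output == "increments":
            out = out.cumsum(axis=-1)           # steps -> positions
        return out

    def forward(self, x: Tensor, eps: np.ndarray) -> tuple[Tensor, Tensor, Tensor]:
        mu, log_sigma = self.encode_tensors(x)
        sigma = log_sigma.exp()
        z = mu + sigma * Tensor(eps)            # reparameterization
        return self.decode_tensors(z), mu, sigma


def build_model(config: ModelConfig) -> TrajectoryVAE:
    """Build a seeded, untrained model from a validated config."""
    return TrajectoryVAE(config)


def _batch_positions(batch, T: int) -> np.ndarray:
    if isinstance(batch, LabeledTrajectoryDataset):
        pos = batch.positions()
    elif isinstance(batch, Trajectory):
        pos = np.stack([batch.xs, batch.ys])[None]
    else:
        pos = np.asarray(batch, dtype=float)
        if pos.ndim == 2:
            pos = pos[None]
    if pos.ndim != 3 or pos.shape[1] != 2:
        raise ValueError("expected (B, 2, T) positions")
    if pos.shape[2] != T:
        raise ValueError(f"trajectory length {pos.shape[2]} != model T {T}")
    return pos


def encode(model: TrajectoryVAE, batch) -> LatentCode:
    """Deterministic posterior parameters for a batch of trajectories."""
    pos = _batch_positions(batch, model.config.T)
    mu, log_sigma = model.encode_tensors(Tensor(pos))
    return LatentCode(mu=mu.data.copy(), sigma=np.exp(log_sigma.data))


def sample_and_decode(model: TrajectoryVAE, code: LatentCode | np.ndarray,
                      seed: int | None = None) -> LabeledTrajectoryDataset:
    """Decode explicit latent vectors, or sample z = mu + sigma * eps first.

    Passing an array decodes it deterministically; passing a
    :class:`LatentCode` draws eps ~ N(0, I) with the given seed.
    """
    if isinstance(code, LatentCode):
        rng = np.random.default_rng(seed)
        z = code.mu + code.sigma * rng.standard_normal(code.mu.shape)
    else:
        z = np.asarray(code, dtype=float)
        if z.ndim == 1:
            z = z[None]
    if z.shape[-1] != model.config.latent_dim:
        raise ValueError("latent dimension mismatch")
    chunks = [model.decode_tensors(Tensor(z[i:i + 256])).data
              for i in range(0, len(z), 256)]
    out = np.concatenate(chunks, axis=0)
    trajs = [Trajectory(out[i, 0], out[i, 1]) for i in range(out.shape[0])]
    return LabeledTrajectoryDataset(trajs, [GENERATED_LABEL] * out.shape[0])


def reconstruct(model: TrajectoryVAE, batch) -> LabeledTrajectoryDataset:
    """Posterior-mean reconstruction (z = mu): deterministic."""
    code = encode(model, batch)
    return sample_and_decode(model, code.mu)


def generate_trajectories(model: TrajectoryVAE, n: int, seed: int
                          ) -> LabeledTrajectoryDataset:
    """Decode n i.i.d. standard-normal latent draws into new trajectories."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, model.config.latent_dim))
    return sample_and_decode(model, z)


def evaluate_loss(model: TrajectoryVAE, batch, weights: LossWeights,
                  kl_weight: float | None = None) -> LossBreakdown:
    """Loss breakdown at the posterior mean (no sampling), without gradients."""
    pos = _batch_positions(batch, model.config.T)
    x = Tensor(pos)
    mu, log_sigma = model.encode_tensors(x)
    recon = model.decode_tensors(mu)
    _, breakdown = physics_informed_loss(pos, recon, mu, log_sigma.exp(),
                                         weights, kl_weight=kl_weight)
    return breakdown


def train_vae(dataset: LabeledTrajectoryDataset, config: ModelConfig,
              weights: LossWeights | None = None, *,
              model: TrajectoryVAE | None = None, verbose: bool = False,
              ) -> tuple[TrajectoryVAE, list[dict[str, float]]]:
    """Train on a dataset of equal-length (T) normalized trajectories.

    A ``val_frac`` tail of a seeded shuffle is held out for validation; the
    per-epoch history records train and validation values of every loss
    term, and the parameters with the lowest total validation loss are the
    ones left in the returned model.  Pass an existing ``model`` to resume
    training.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    weights = weights or LossWeights()
    pos = dataset.positions()
    if pos.shape[2] != config.T:
        raise ValueError("dataset trajectory length != config.T")
    rng = np.random.default_rng(config.seed + 1)
    n = pos.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.val_frac * n))) if n > 1 else 0
    val_idx, train_idx = perm[n - n_val:], perm[:n - n_val]
    if len(train_idx) == 0:
        train_idx = perm
    x_train, x_val = pos[train_idx], pos[val_idx]

    if model is None:
        model = build_model(config)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history: list[dict[str, float]] = []
    best_val = np.inf
    best_state = model.state_dict()

    for epoch in range(config.epochs):
        kl_w = weights.scaled_kl(epoch, config.epochs)
        order = rng.permutation(len(x_train))
        epoch_terms: dict[str, float] = {}
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = x_train[idx]
            eps = rng.standard_normal((len(idx), config.latent_dim))
            recon, mu, sigma = model(Tensor(xb), eps)
            total, bd = physics_informed_loss(xb, recon, mu, sigma, weights,
                                              kl_weight=kl_w)
            if not np.isfinite(total.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            total.backward()
            opt.step()
            for k, v in bd.as_dict().items():
                epoch_terms[k] = epoch_terms.get(k, 0.0) + v
            n_batches += 1
        row = {"epoch": epoch}
        row.update({f"train_{k}": v / n_batches for k, v in epoch_terms.items()})
        if len(x_val):
            val_bd = evaluate_loss(model, x_val, weights, kl_weight=kl_w)
            row.update({f"val_{k}": v for k, v in val_bd.as_dict().items()})
            if val_bd.total <= best_val:
                best_val = val_bd.total
                best_state = model.state_dict()
        history.append(row)
        if verbose:
            print(f"epoch {epoch}: train {row.get('train_total'):.4f}"
                  f" val {row.get('val_total', float('nan')):.4f}")
    if len(x_val):
        model.load_state_dict(best_state)
    return model, history


# ---------------------------------------------------------------------------
# persistence: config YAML + weights npz + loss-history CSV
# ---------------------------------------------------------------------------

def save_model(model: TrajectoryVAE, path,
               history: list[dict[str, float]] | None = None) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cfg = asdict(model.config)
    cfg["conv_kernels"] = list(cfg["conv_kernels"])
    (path / "config.yaml").write_text(yaml.safe_dump(cfg))
    np.savez(path / "weights.npz", **model.state_dict())
    if history:
        keys = sorted({k for row in history for k in row})
        with open(path / "history.csv", "w", newline="") as f:
            writer = csv.DictWriter(f, fieldnames=keys)
            writer.writeheader()
            writer.writerows(history)


def load_model(path) -> TrajectoryVAE:
    path = Path(path)
    cfg = yaml.safe_load((path / "config.yaml").read_text())
    cfg["conv_kernels"] = tuple(cfg["conv_kernels"])
    model = build_model(ModelConfig(**cfg))
    with np.load(path / "weights.npz") as state:
        model.load_state_dict({k: state[k] for k in state.files})
    return model
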