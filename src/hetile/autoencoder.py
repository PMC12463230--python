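"""Convolutional autoencoder family over 128x128x3 tiles.

Five members with bottleneck element counts 16384, 4096, 512, 64 and 2,
obtained from 3, 5, 6, 7 and 7 stride-2 convolution layers respectively
(each halving spatial resolution from 128), with bottleneck tensor shapes
(64,16,16), (256,4,4), (128,2,2), (64,1,1) and (2,1,1). The decoder
mirrors the encoder with 2x2-stride-2 transposed convolutions back to
128x128x3 and a logistic output so reconstructions live in [0, 1].

Hidden channel widths halve backwards from the bottleneck channel count
with a floor of 8 (e.g. 3->16->32->64 for the 3-layer member). Hidden
activations are rectifiers; the bottleneck itself is linear so latent
vectors are unconstrained in sign. Training follows MSE reconstruction
loss, Adam at learning rate 0.001, batch size 16, 40 epochs, keeping the
checkpoint with the smallest validation MSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .tiling import Tile

__all__ = [
    "AutoencoderSpec",
    "LatentVector",
    "Autoencoder",
    "build_autoencoder",
    "train_autoencoder",
    "encode_tiles",
    "reconstruction_report",
    "tiles_to_array",
    "FAMILY",
]

# latent_dim -> (n_conv_layers, (channels, h, w))
FAMILY: dict[int, tuple[int, tuple[int, int, int]]] = {
    16384: (3, (64, 16, 16)),
    4096: (5, (256, 4, 4)),
    512: (6, (128, 2, 2)),
    64: (7, (64, 1, 1)),
    2: (7, (2, 1, 1)),
}

TILE_SIDE = 128
MIN_WIDTH = 8


@dataclass(frozen=True)
class AutoencoderSpec:
    latent_dim: int
    n_conv_layers: int
    latent_shape: tuple[int, int, int]
    epochs: int = 40
    learning_rate: float = 1e-3
    batch_size: int = 16

    def __post_init__(self):
        c, h, w = self.latent_shape
        if c * h * w != self.latent_dim:
            raise ValueError(f"latent_shape {self.latent_shape} has {c * h * w} "
                             f"elements, expected latent_dim={self.latent_dim}")
        if TILE_SIDE // (2 ** self.n_conv_layers) != h:
            raise ValueError(f"{self.n_conv_layers} halvings of {TILE_SIDE} do not "
                             f"reach spatial size {h}")

    @classmethod
    def from_latent_dim(cls, latent_dim: int, **kw) -> "AutoencoderSpec":
        if latent_dim not in FAMILY:
            raise ValueError(f"latent_dim must be one of {sorted(FAMILY)}, "
                             f"got {latent_dim}")
        n, shape = FAMILY[latent_dim]
        return cls(latent_dim=latent_dim, n_conv_layers=n, latent_shape=shape, **kw)


@dataclass
class LatentVector:
    slide_id: str
    row: int
    col: int
    dim: int
    values: np.ndarray
    model_id: str = ""


def _channel_plan(n_layers: int, bottleneck_channels: int) -> list[int]:
    """Widths halve backwards from the bottleneck, floored at MIN_WIDTH."""
    widths = [bottleneck_channels]
    for _ in range(n_layers - 1):
        widths.append(max(MIN_WIDTH, widths[-1] // 2))
    return widths[::-1]


class Autoencoder:
    """Encoder/decoder pair; ``model_id`` names the member for provenance."""

    def __init__(self, spec: AutoencoderSpec, seed: int = 0):
        self.spec = spec
        self.model_id = f"ae{spec.latent_dim}_seed{seed}"
        rng = np.random.default_rng(seed)
        widths = _channel_plan(spec.n_conv_layers, spec.latent_shape[0])
        enc: list[nn.Layer] = []
        cin, side = 3, TILE_SIDE
        for i, cout in enumerate(widths):
            # a 2->1 halving uses a 2x2 valid kernel; all others 3x3/stride2/pad1
            if side == 2:
                enc.append(nn.Conv2d(cin, cout, kernel=2, stride=2, pad=0, rng=rng))
            else:
                enc.append(nn.Conv2d(cin, cout, kernel=3, stride=2, pad=1, rng=rng))
            if i < len(widths) - 1:          # linear bottleneck
                enc.append(nn.ReLU())
            cin, side = cout, side // 2
        self.encoder = nn.Sequential(enc)
        dec: list[nn.Layer] = []
        rev = widths[::-1]
        for i in range(len(rev)):
            cout = rev[i + 1] if i + 1 < len(rev) else 3
            dec.append(nn.ConvTranspose2d(rev[i], cout, rng=rng))
            dec.append(nn.ReLU() if i + 1 < len(rev) else nn.Sigmoid())
        self.decoder = nn.Sequential(dec)
        self._net = nn.Sequential([self.encoder, self.decoder])

    def encode(self, x: np.ndarray) -> np.ndarray:
        """x: (N,3,128,128) in [0,1] -> latent tensor (N, C, h, w)."""
        return self.encoder.forward(x.astype(np.float32))

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self._net.forward(x.astype(np.float32))

    def backward(self, dy: np.ndarray) -> None:
        self._net.backward(dy)

    def params(self):
        return self._net.params()

    def grads(self):
        return self._net.grads()

    def state(self):
        return self._net.state()

    def load_state(self, state):
        self._net.load_state(state)


def build_autoencoder(spec: AutoencoderSpec, seed: int = 0) -> Autoencoder:
    return Autoencoder(spec, seed=seed)


def tiles_to_array(tiles: list[Tile] | np.ndarray) -> np.ndarray:
    """Stack tiles to (N, 3, H, W) float32 scaled to [0, 1]."""
    if isinstance(tiles, np.ndarray):
        x = tiles
        if x.ndim == 4 and x.shape[-1] == 3:          # NHWC -> NCHW
            x = x.transpose(0, 3, 1, 2)
        x = x.astype(np.float32)
        return x / 255.0 if x.max() > 1.5 else x
    return np.stack([t.pixels for t in tiles]).transpose(0, 3, 1, 2).astype(np.float32) / 255.0


def _batched_mse(model: Autoencoder, x: np.ndarray, batch: int = 32) -> float:
    total, n = 0.0, 0
    for i in range(0, len(x), batch):
        xb = x[i:i + batch]
        rec = model.forward(xb)
        total += float(np.sum((rec.astype(np.float64) - xb) ** 2))
        n += xb.size
    return total / n


@dataclass
class AETrainResult:
    model: Autoencoder
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def best_val_loss(self) -> float:
        return self.val_losses[self.best_epoch]


def train_autoencoder(model: Autoencoder, train_tiles, val_tiles,
                      epochs: int | None = None, seed: int = 0) -> AETrainResult:
    """Train with Adam/MSE and return the checkpoint minimizing validation MSE."""
    if len(train_tiles) == 0 or len(val_tiles) == 0:
        raise ValueError("train and validation tile sets must be nonempty")
    xtr = tiles_to_array(train_tiles)
    xva = tiles_to_array(val_tiles)
    spec = model.spec
    epochs = spec.epochs if epochs is None else epochs
    opt = nn.Adam(model.params(), lr=spec.learning_rate)
    rng = np.random.default_rng(seed)
    result = AETrainResult(model=model)
    best_state, best_val = None, np.inf
    for epoch in range(epochs):
        order = rng.permutation(len(xtr))
        ep_loss, n_batches = 0.0, 0
        for i in range(0, len(order), spec.batch_size):
            xb = xtr[order[i:i + spec.batch_size]]
            rec = model.forward(xb)
            loss, dloss = nn.mse_loss(rec, xb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite reconstruction loss at epoch {epoch}, "
                    f"batch {n_batches}: {loss}")
            model.backward(dloss.astype(np.float32))
            opt.step(model.grads())
            ep_loss += loss
            n_batches += 1
        result.train_losses.append(ep_loss / max(n_batches, 1))
        val = _batched_mse(model, xva)
        result.val_losses.append(val)
        if val < best_val:
            best_val, best_state = val, model.state()
            result.best_epoch = epoch
    model.load_state(best_state)
    return result


def encode_tiles(model: Autoencoder, tiles: list[Tile], batch: int = 64) -> list[LatentVector]:
    """One latent vector per tile, flattened channel-major from the latent tensor."""
    x = tiles_to_array(tiles)
    out: list[LatentVector] = []
    for i in range(0, len(x), batch):
        z = model.encode(x[i:i + batch])
        flat = z.reshape(z.shape[0], -1)
        for j, t in enumerate(tiles[i:i + batch]):
            out.append(LatentVector(slide_id=t.slide_id, row=t.row, col=t.col,
                                    dim=model.spec.latent_dim,
                                    values=flat[j].astype(np.float64),
                                    model_id=model.model_id))
    return out


def reconstruction_report(model: Autoencoder, tiles) -> dict:
    """Per-tile reconstruction MSE plus median/quartile summary."""
    x = tiles_to_array(tiles)
    per_tile = []
    for i in range(0, len(x), 32):
        xb = x[i:i + 32]
        rec = model.forward(xb).astype(np.float64)
        per_tile.extend(((rec - xb) ** 2).mean(axis=(1, 2, 3)).tolist())
    per_tile = np.array(per_tile)
    return {
        "per_tile_mse": per_tile,
        "median": float(np.median(per_tile)),
        "q1": float(np.quantile(per_tile, 0.25)),
        "q3": float(np.quantile(per_tile, 0.75)),
        "latent_dim": model.spec.latent_dim,
    }
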