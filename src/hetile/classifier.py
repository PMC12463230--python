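"""Binary tile classifiers on raw tiles or latent vectors.

The default raw-tile backbone is a small 4-conv-block CNN (stride-2
convolutions, global average pooling, single-logit head) sized to train on
one CPU; latent inputs use a 2-hidden-layer perceptron over per-feature
standardized vectors. Training uses binary cross entropy on logits with
Adam at learning rate 0.001 and batch size 8 for 20 epochs, and returns
the epoch checkpoint with the best validation accuracy (ties go to the
earliest epoch). Scores are logistic probabilities thresholded at 0.5.

ImageNet-pretrained backbones (Resnet50, Densenet121, InceptionV3) are an
optional adapter interface; when their weights are not available the
adapter raises :class:`AdapterUnavailableError` and the pipeline runs on
the built-in backbones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autoencoder import LatentVector, tiles_to_array
from .tiling import Tile

__all__ = [
    "ClassifierConfig",
    "TilePrediction",
    "TileClassifier",
    "train_classifier",
    "predict_tiles",
    "external_backbone_adapter",
    "AdapterUnavailableError",
]

ADAPTER_EXIT_CODE = 42  # CLI exit code distinct from generic failures


class AdapterUnavailableError(RuntimeError):
    """Raised when a named pretrained backbone's weights are not available."""


@dataclass(frozen=True)
class ClassifierConfig:
    input_kind: str = "raw_tile"            # "raw_tile" | "latent"
    latent_dim: int | None = None
    backbone: str = "smallcnn"              # "smallcnn" | "mlp" | adapter name
    epochs: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.input_kind not in ("raw_tile", "latent"):
            raise ValueError(f"unknown input_kind {self.input_kind!r}")
        if self.input_kind == "latent" and self.backbone == "smallcnn":
            raise ValueError("latent inputs require an mlp (or adapter) backbone")
        if self.input_kind == "raw_tile" and self.backbone == "mlp":
            raise ValueError("raw tiles require a convolutional backbone")
        if self.input_kind == "latent" and not self.latent_dim:
            raise ValueError("latent input_kind requires latent_dim")


@dataclass
class TilePrediction:
    slide_id: str
    row: int
    col: int
    score: float                            # P(label = 1)
    label_hat: int
    truth: int


def _smallcnn(rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    cin = 3
    for cout in (8, 16, 32, 64):
        layers += [nn.Conv2d(cin, cout, kernel=3, stride=2, pad=1, rng=rng),
                   nn.ReLU()]
        cin = cout
    layers += [nn.GlobalAvgPool(), nn.Dense(64, 1, rng=rng)]
    return nn.Sequential(layers)


def _mlp(nin: int, rng: np.random.Generator) -> nn.Sequential:
    h1, h2 = 64, 32
    return nn.Sequential([
        nn.Dense(nin, h1, rng=rng), nn.ReLU(),
        nn.Dense(h1, h2, rng=rng), nn.ReLU(),
        nn.Dense(h2, 1, rng=rng),
    ])


class TileClassifier:
    """Backbone + input normalization; produces one logit per input."""

    def __init__(self, config: ClassifierConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        if config.backbone == "smallcnn":
            self.net = _smallcnn(rng)
        elif config.backbone == "mlp":
            self.net = _mlp(config.latent_dim, rng)
        else:
            self.net = external_backbone_adapter(config.backbone)
        self.feature_mean: np.ndarray | None = None
        self.feature_std: np.ndarray | None = None

    def fit_normalizer(self, x: np.ndarray) -> None:
        if self.config.input_kind == "latent":
            self.feature_mean = x.mean(axis=0)
            self.feature_std = x.std(axis=0) + 1e-8

    def prepare(self, x: np.ndarray) -> np.ndarray:
        if self.config.input_kind == "latent":
            return ((x - self.feature_mean) / self.feature_std).astype(np.float32)
        return x.astype(np.float32)

    def logits(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        out = [self.net.forward(x[i:i + batch]).ravel()
               for i in range(0, len(x), batch)]
        return np.concatenate(out) if out else np.empty(0)

    def scores(self, x: np.ndarray) -> np.ndarray:
        z = self.logits(self.prepare(x))
        return 1.0 / (1.0 + np.exp(-z.astype(np.float64)))


def _to_matrix(inputs, config: ClassifierConfig) -> np.ndarray:
    """Tiles -> (N,3,128,128) in [0,1]; latent vectors -> (N, dim)."""
    if config.input_kind == "raw_tile":
        return tiles_to_array(inputs)
    if isinstance(inputs, np.ndarray):
        return inputs.astype(np.float64)
    return np.stack([lv.values for lv in inputs]).astype(np.float64)


def _identities(inputs) -> list[tuple[str, int, int]]:
    out = []
    for item in inputs:
        if isinstance(item, (Tile, LatentVector)):
            out.append((item.slide_id, item.row, item.col))
        else:
            out.append(("", -1, -1))
    return out


@dataclass
class ClassifierTrainResult:
    model: TileClassifier
    train_losses: list[float] = field(default_factory=list)
    val_accuracies: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def best_val_accuracy(self) -> float:
        return self.val_accuracies[self.best_epoch]


def train_classifier(config: ClassifierConfig, train_inputs, train_labels,
                     val_inputs, val_labels) -> ClassifierTrainResult:
    """Train and return the checkpoint with maximal validation accuracy.

    Expects balanced (downsampled) train/val sets with both classes
    present; raises on single-class input or non-finite loss.
    """
    ytr = np.asarray(train_labels, dtype=np.float32)
    yva = np.asarray(val_labels, dtype=np.float32)
    for name, y in (("train", ytr), ("val", yva)):
        if len(y) == 0 or np.unique(y).size < 2:
            raise ValueError(f"{name} set must contain both classes")
    model = TileClassifier(config)
    xtr = _to_matrix(train_inputs, config)
    xva = _to_matrix(val_inputs, config)
    model.fit_normalizer(xtr)
    xtr_p = model.prepare(xtr)
    xva_p = model.prepare(xva)
    opt = nn.Adam(model.net.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    result = ClassifierTrainResult(model=model)
    best_state, best_acc = None, -1.0
    for epoch in range(config.epochs):
        order = rng.permutation(len(xtr_p))
        ep_loss, n_batches = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            sel = order[i:i + config.batch_size]
            z = model.net.forward(xtr_p[sel])
            loss, dz = nn.bce_with_logits(z, ytr[sel][:, None])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite classification loss at epoch {epoch}")
            model.net.backward(dz)
            opt.step(model.net.grads())
            ep_loss += loss
            n_batches += 1
        result.train_losses.append(ep_loss / max(n_batches, 1))
        val_pred = (model.logits(xva_p) >= 0.0).astype(np.float32)
        acc = float((val_pred == yva).mean())
        result.val_accuracies.append(acc)
        if acc > best_acc:                   # strict > : ties keep earliest epoch
            best_acc, best_state = acc, model.net.state()
            result.best_epoch = epoch
    model.net.load_state(best_state)
    return result


def predict_tiles(model: TileClassifier, inputs, truths=None) -> list[TilePrediction]:
    """Score each tile/latent input; ``label_hat = 1`` iff score >= 0.5."""
    x = _to_matrix(inputs, model.config)
    if model.config.input_kind == "latent" and x.shape[1] != model.config.latent_dim:
        raise ValueError(f"latent dim mismatch: model expects "
                         f"{model.config.latent_dim}, got {x.shape[1]}")
    scores = model.scores(x)
    ids = _identities(inputs)
    if truths is None:
        truths = [-1] * len(scores)
    return [TilePrediction(slide_id=s, row=r, col=c, score=float(p),
                           label_hat=int(p >= 0.5), truth=int(t))
            for (s, r, c), p, t in zip(ids, scores, truths)]


def external_backbone_adapter(name: str):
    """Wrap a named ImageNet-pretrained backbone with a fresh binary head.

    No pretrained weights ship with this package and none are downloaded,
    so the adapter reports itself unavailable unless a deep-learning
    runtime with the named weights is importable.
    """
    known = {"resnet50", "densenet121", "inceptionv3"}
    if name.lower() not in known:
        raise ValueError(f"unknown backbone {name!r}; known adapters: {sorted(known)}")
    raise AdapterUnavailableError(
        f"adapter unavailable: pretrained weights for {name!r} are not "
        "installed; use the built-in 'smallcnn' or 'mlp' backbones")
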