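"""3D residual convolutional classifier over active-site feature grids.

Two architectures are provided. ``tiny3d`` — the default and the one the
test suite trains — is a desk-scale residual network: average-pool the
20-voxel cube by 4, a stem convolution, three residual blocks, global
average pooling and a softmax head.  ``resnet50_3d`` keeps the canonical
[3, 4, 6, 3] bottleneck layout of ResNet-50 translated to 3D at configurable
(small, by default) widths; it is provided for architectural fidelity but is
far beyond what a CPU-only session needs for the synthetic benchmark.

The final layer is zero-initialized, so an untrained model predicts the
uniform distribution over classes.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import VoxsiteError
from .features import FeatureGrid, GridDataset, N_FEATURES
from . import network as nn

ARCHITECTURES = ("tiny3d", "resnet50_3d")


@dataclass
class ModelConfig:
    architecture: str = "tiny3d"
    n_classes: int = 2
    epochs: int = 30
    learning_rate: float = 3e-3
    batch_size: int = 16
    seed: int = 0
    width: int = 16          # base channel count
    pool: int = 4            # leading average-pool factor (tiny3d)
    patience: int = 8        # early-stopping patience on validation accuracy
    stop_accuracy: float = 1.0   # stop as soon as validation reaches this
    restore_best: bool = True    # return best-validation weights, not final
    class_weights: bool = False  # inverse-frequency weighting of the loss

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise VoxsiteError(f"unknown architecture {self.architecture!r}")
        if self.n_classes < 2:
            raise VoxsiteError("n_classes must be >= 2")
        for name in ("epochs", "learning_rate", "batch_size", "width", "pool", "patience"):
            if getattr(self, name) <= 0:
                raise VoxsiteError(f"{name} must be positive")


@dataclass
class ClassProbabilities:
    """Normalized class-probability vector aligned with ``class_names``."""

    probs: np.ndarray
    class_names: list[str]

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or len(p) != len(self.class_names):
            raise VoxsiteError("probs must be 1-D and aligned with class_names")
        if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
            raise VoxsiteError("probabilities must be in [0,1] and sum to 1")
        self.probs = p

    @property
    def argmax(self) -> str:
        return self.class_names[int(np.argmax(self.probs))]


def _build_layers(cfg: ModelConfig, rng: np.random.Generator) -> nn.Sequential:
    w = cfg.width
    if cfg.architecture == "tiny3d":
        body = nn.Sequential([
            nn.AvgPool3D(cfg.pool),
            nn.Conv3D(N_FEATURES, w, 3, rng), nn.BatchNorm(w), nn.ReLU(),
            nn.ResidualBlock(w, w, 3, rng),
            nn.ResidualBlock(w, w, 3, rng),
            nn.ResidualBlock(w, w, 3, rng),
            nn.GlobalAvgPool(),
        ])
        layers = [
            nn.WithGlobalSummary(body),
            # normalize the concatenated features: raw channel means are
            # orders of magnitude smaller than the CNN activations
            nn.BatchNorm(w + N_FEATURES),
            nn.Dense(w + N_FEATURES, cfg.n_classes, rng, zero_init=True),
        ]
    else:  # resnet50_3d: canonical [3,4,6,3] bottleneck stages, desk-scale widths
        layers = [nn.AvgPool3D(2), nn.Conv3D(N_FEATURES, w, 3, rng),
                  nn.BatchNorm(w), nn.ReLU()]
        c_in = w
        for stage, n_blocks in enumerate((3, 4, 6, 3)):
            c_mid = w * 2 ** stage
            c_out = 4 * c_mid
            for _ in range(n_blocks):
                layers.append(nn.BottleneckBlock(c_in, c_mid, c_out, rng))
                c_in = c_out
            if stage < 3:
                layers.append(nn.AvgPool3D(2) if stage == 0 else nn.ReLU())
        layers += [nn.GlobalAvgPool(), nn.Dense(c_in, cfg.n_classes, rng, zero_init=True)]
    return nn.Sequential(layers)


class VoxNet:
    """A trained (or trainable) grid classifier handle."""

    def __init__(self, cfg: ModelConfig, class_names: list[str]):
        if len(class_names) != cfg.n_classes:
            raise VoxsiteError("class_names length must equal cfg.n_classes")
        self.cfg = cfg
        self.class_names = list(class_names)
        self.net = _build_layers(cfg, np.random.default_rng(cfg.seed))
        self.expected_edge: int | None = None
        # per-channel standardization (fit on the train split; identity until then)
        self.channel_mean = np.zeros(N_FEATURES, dtype=np.float32)
        self.channel_scale = np.ones(N_FEATURES, dtype=np.float32)

    def fit_normalization(self, grids: np.ndarray) -> None:
        """Store per-channel input scales (1 / channel RMS, floored).

        Sparse occupancy makes raw voxel values tiny, which stalls the
        optimizer, and channel densities span an order of magnitude, so
        sparse-but-informative channels need boosting — bounded, to keep the
        optimization stable."""
        sq = np.square(grids.reshape(-1, N_FEATURES), dtype=np.float64)
        rms_c = np.sqrt(sq.mean(axis=0))
        rms_g = max(float(np.sqrt(sq.mean())), 1e-9)
        # floor at 0.1x the global RMS: rare channels are boosted, but never
        # by more than 10x relative to the dense ones
        self.channel_mean = np.zeros(N_FEATURES, dtype=np.float32)
        self.channel_scale = (1.0 / np.maximum(rms_c, 0.1 * rms_g)).astype(np.float32)

    def _normalize(self, grids: np.ndarray) -> np.ndarray:
        return (grids - self.channel_mean) * self.channel_scale

    # -- inference -----------------------------------------------------------
    def predict_proba(self, grids: np.ndarray) -> np.ndarray:
        """Softmax probabilities for a batch of grids (N, n, n, n, 13)."""
        grids = np.asarray(grids, dtype=np.float32)
        if grids.ndim == 4:
            grids = grids[None]
        if grids.ndim != 5 or grids.shape[-1] != N_FEATURES:
            raise VoxsiteError(f"bad grid batch shape {grids.shape}")
        if self.expected_edge is not None and grids.shape[1] != self.expected_edge:
            raise VoxsiteError(
                f"grid edge {grids.shape[1]} does not match model input "
                f"edge {self.expected_edge}")
        return nn.softmax(self.net.forward(self._normalize(grids)).astype(np.float64))

    def predict(self, grid: FeatureGrid | np.ndarray) -> ClassProbabilities:
        values = grid.values if isinstance(grid, FeatureGrid) else grid
        p = self.predict_proba(values)[0]
        return ClassProbabilities(probs=p, class_names=self.class_names)

    # -- persistence ---------------------------------------------------------
    def save(self, path: str) -> None:
        arrays = {f"p{i}": p for i, (p, _) in enumerate(self.net.params)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.net.buffers)})
        meta = json.dumps({"cfg": asdict(self.cfg), "class_names": self.class_names,
                           "expected_edge": self.expected_edge})
        np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8),
                 channel_mean=self.channel_mean, channel_scale=self.channel_scale,
                 **arrays)

    @classmethod
    def load(cls, path: str) -> "VoxNet":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            model = cls(ModelConfig(**meta["cfg"]), meta["class_names"])
            model.expected_edge = meta["expected_edge"]
            model.channel_mean = z["channel_mean"]
            model.channel_scale = z["channel_scale"]
            for i, (p, _) in enumerate(model.net.params):
                p[...] = z[f"p{i}"]
            for i, b in enumerate(model.net.buffers):
                b[...] = z[f"b{i}"]
        return model


@dataclass
class EpochLog:
    epoch: int
    loss: float
    val_accuracy: float


def train(ds: GridDataset, cfg: ModelConfig) -> tuple[VoxNet, list[EpochLog]]:
    """Train a classifier on the train split, early-stopping on validation.

    Deterministic given ``cfg.seed`` and a fixed BLAS thread count (bitwise
    reproducibility across platforms is not guaranteed for float32 matmuls).
    Returns the model restored to its best-validation-accuracy weights and a
    per-epoch log of training loss and validation accuracy.
    """
    if cfg.n_classes != len(ds.class_names):
        raise VoxsiteError(
            f"cfg.n_classes={cfg.n_classes} but dataset has {len(ds.class_names)} classes")
    # index-based access: the grid array is large, so partitions are never
    # materialized as whole copies — only per-batch slices
    itr = ds.partition_indices("train")
    iva = ds.partition_indices("validation")
    ytr = ds.labels[itr]

    model = VoxNet(cfg, ds.class_names)
    model.expected_edge = ds.grids.shape[1]
    model.fit_normalization(ds.grids[itr[:: max(1, len(itr) // 256)]])
    opt = nn.Adam(model.net.params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)

    weights = None
    if cfg.class_weights:
        counts = np.bincount(ytr, minlength=cfg.n_classes).astype(float)
        w_class = counts.sum() / (len(counts) * np.maximum(counts, 1.0))
        weights = w_class[ytr]

    log: list[EpochLog] = []
    best_acc, best_params, since_best = -1.0, None, 0
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(ytr))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            batch = ds.grids[itr[sel]]
            logits = model.net.forward(model._normalize(batch), train=True)
            loss, dlogits = nn.cross_entropy_grad(
                logits, ytr[sel], None if weights is None else weights[sel])
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_acc = _accuracy_on_indices(model, ds, iva)
        log.append(EpochLog(epoch=epoch, loss=float(np.mean(losses)), val_accuracy=val_acc))
        if val_acc > best_acc + 1e-12:
            best_acc = val_acc
            best_params = ([p.copy() for p, _ in model.net.params],
                           [b.copy() for b in model.net.buffers])
            since_best = 0
            if val_acc >= cfg.stop_accuracy:
                break
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if cfg.restore_best and best_params is not None:
        for (p, _), bp in zip(model.net.params, best_params[0]):
            p[...] = bp
        for b, bb in zip(model.net.buffers, best_params[1]):
            b[...] = bb
    return model, log


def accuracy(model: VoxNet, grids: np.ndarray, labels: np.ndarray,
             batch_size: int = 256) -> float:
    """Fraction of argmax-correct predictions, computed in batches."""
    if len(labels) == 0:
        raise VoxsiteError("empty partition")
    correct = 0
    for start in range(0, len(labels), batch_size):
        p = model.predict_proba(grids[start:start + batch_size])
        correct += int((p.argmax(axis=1) == labels[start:start + batch_size]).sum())
    return correct / len(labels)


def _accuracy_on_indices(model: VoxNet, ds: GridDataset, idx: np.ndarray,
                         batch_size: int = 256) -> float:
    # batched fancy indexing: never materializes the whole partition
    correct = 0
    for start in range(0, len(idx), batch_size):
        sel = idx[start:start + batch_size]
        p = model.predict_proba(ds.grids[sel])
        correct += int((p.argmax(axis=1) == ds.labels[sel]).sum())
    return correct / len(idx)


def evaluate_accuracy(model: VoxNet, ds: GridDataset, split: str = "test") -> float:
    return _accuracy_on_indices(model, ds, ds.partition_indices(split))
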