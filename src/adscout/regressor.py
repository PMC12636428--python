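"""The activity regressor: a residual convolutional network trained on
encoded tiles with z-scored labels, MSE loss, Adam, and early stopping.

The architecture follows the conv stem -> residual blocks -> global average
pool -> dense head topology. Labels are z-score normalized on the training
split only; predictions are de-normalized back to the assay scale. Splitting
is stratified on the above-median activity indicator so each split carries the
global active/inactive balance; an out-of-distribution split via spectral
clustering of the encodings is also provided for generalization studies.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import SpectralClustering
from sklearn.model_selection import train_test_split

from . import nn

# ---------------------------------------------------------------------------
# Configuration types


@dataclass(frozen=True)
class RegressorSpec:
    """Architecture hyperparameters (topology fixed, sizes configurable)."""

    in_channels: int = 20
    stem_kernel: int = 5
    stem_channels: int = 64
    n_blocks: int = 3
    block_kernel: int = 3

    def __post_init__(self):
        if min(self.in_channels, self.stem_channels, self.n_blocks + 1,
               self.stem_kernel, self.block_kernel) < 1:
            raise ValueError("all architecture sizes must be positive")

    @classmethod
    def compact(cls) -> "RegressorSpec":
        """A small, fast variant for simulation studies and tests."""
        return cls(stem_channels=16, n_blocks=1)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RegressorSpec":
        return cls(**d)


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class NormalizationParams:
    """Training-split activity mean/sd; applied inversely at prediction."""

    mean: float
    std: float

    def __post_init__(self):
        if not self.std > 0:
            raise ValueError("activity standard deviation must be positive "
                             "(constant labels cannot be z-scored)")

    def z(self, y: np.ndarray) -> np.ndarray:
        return (y - self.mean) / self.std

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return z * self.std + self.mean


@dataclass(frozen=True)
class MetricsReport:
    rmse: float
    pearson_r: float
    spearman_rho: float
    n: int


@dataclass(frozen=True)
class SplitIndices:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


# ---------------------------------------------------------------------------
# Splits


def dedup_labeled(frame: pd.DataFrame) -> pd.DataFrame:
    """Drop duplicate tile sequences (first kept) before splitting."""
    return frame.drop_duplicates(subset="sequence", keep="first").reset_index(
        drop=True)


def stratified_split(labels: np.ndarray,
                     fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                     seed: int = 0) -> SplitIndices:
    """Train/validation/test split stratified on the above-median indicator.

    Activity is continuous, so it is binarized at the median purely to drive
    stratified shuffling; each split then carries the global active/inactive
    balance. Deterministic given ``seed``.
    """
    labels = np.asarray(labels, dtype=float)
    n = len(labels)
    if n < 10:
        raise ValueError(f"need >= 10 labeled tiles to stratify, got {n}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    above = labels > np.median(labels)
    idx = np.arange(n)
    train_idx, rest_idx = train_test_split(
        idx, test_size=fractions[1] + fractions[2], random_state=seed,
        stratify=above)
    val_share = fractions[1] / (fractions[1] + fractions[2])
    val_idx, test_idx = train_test_split(
        rest_idx, train_size=val_share, random_state=seed,
        stratify=above[rest_idx])
    return SplitIndices(np.sort(train_idx), np.sort(val_idx),
                        np.sort(test_idx))


def spectral_ood_split(encodings: np.ndarray, n_clusters: int,
                       held_out_cluster: int = 0, seed: int = 0
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Out-of-distribution partition by spectral clustering of encodings.

    Tiles are mean-pooled over positions; the affinity is an RBF kernel with
    bandwidth set to the median pairwise distance. The entire held-out cluster
    becomes the test set. Returns (train_idx, test_idx, cluster_labels).
    """
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    x = np.asarray(encodings, dtype=float)
    if x.ndim == 3:
        x = x.mean(axis=1)
    dists = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    bandwidth = np.median(dists[np.triu_indices(len(x), k=1)])
    if not bandwidth > 0:
        raise ValueError("degenerate similarity matrix: median pairwise "
                         "distance is zero (all encodings identical?)")
    affinity = np.exp(-(dists / bandwidth) ** 2)
    model = SpectralClustering(n_clusters=n_clusters, affinity="precomputed",
                               random_state=seed, assign_labels="discretize")
    clusters = model.fit_predict(affinity)
    test_idx = np.flatnonzero(clusters == held_out_cluster)
    train_idx = np.flatnonzero(clusters != held_out_cluster)
    if len(test_idx) == 0:
        raise ValueError(f"held-out cluster {held_out_cluster} is empty")
    return train_idx, test_idx, clusters


# ---------------------------------------------------------------------------
# Model


def build_network(spec: RegressorSpec, rng: np.random.Generator) -> nn.Network:
    layers: list[nn.Layer] = [
        nn.Conv1d(spec.in_channels, spec.stem_channels, spec.stem_kernel, rng),
        nn.BatchNorm(spec.stem_channels),
        nn.ReLU(),
    ]
    for _ in range(spec.n_blocks):
        layers.append(nn.ResidualBlock(spec.stem_channels, spec.block_kernel,
                                       rng))
    layers.append(nn.GlobalAvgPool())
    layers.append(nn.Dense(spec.stem_channels, 1, rng))
    return nn.Network(layers)


@dataclass
class TrainedRegressor:
    network: nn.Network
    spec: RegressorSpec
    config: TrainingConfig
    norm: NormalizationParams
    history: list[dict] = field(default_factory=list)

    def predict(self, encodings: np.ndarray, batch_size: int = 256
                ) -> np.ndarray:
        """De-normalized activity predictions (evaluation mode)."""
        x = np.asarray(encodings, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.shape[2] != self.spec.in_channels:
            raise ValueError(
                f"encoding has {x.shape[2]} channels, model expects "
                f"{self.spec.in_channels}")
        outs = [self.network.forward(x[i:i + batch_size], train=False)
                for i in range(0, len(x), batch_size)]
        return self.norm.inverse(np.concatenate(outs)[:, 0])


def fit_regressor(encodings: np.ndarray, labels: np.ndarray,
                  train_idx: np.ndarray, val_idx: np.ndarray,
                  config: TrainingConfig | None = None,
                  spec: RegressorSpec | None = None) -> TrainedRegressor:
    """Train a regressor with early stopping on validation MSE.

    Labels are z-scored with training-split statistics. Training stops when
    the validation loss has not improved for ``patience`` epochs; the weights
    of the best validation epoch (not the last) are restored.
    """
    if config is None:
        config = TrainingConfig()
    if spec is None:
        spec = RegressorSpec()
    x = np.asarray(encodings, dtype=float)
    y = np.asarray(labels, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("labels must be finite")
    y_train = y[train_idx]
    std = float(y_train.std())
    if std == 0:
        raise ValueError("zero label variance on the training split: "
                         "z-scoring is undefined")
    norm = NormalizationParams(float(y_train.mean()), std)
    z = norm.z(y)

    rng = np.random.default_rng(config.seed)
    net = build_network(spec, rng)
    optimizer = nn.Adam(net.parameters(), lr=config.learning_rate)

    x_val, z_val = x[val_idx], z[val_idx][:, None]
    best_val = np.inf
    best_state = net.state_dict()
    best_epoch = -1
    history: list[dict] = []
    order = np.array(train_idx)
    for epoch in range(config.max_epochs):
        rng.shuffle(order)
        train_loss = 0.0
        for i in range(0, len(order), config.batch_size):
            batch = order[i:i + config.batch_size]
            xb, zb = x[batch], z[batch][:, None]
            net.zero_grad()
            out = net.forward(xb, train=True)
            err = out - zb
            loss = float((err ** 2).mean())
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}")
            net.backward(2.0 * err / err.size)
            optimizer.step()
            train_loss += loss * len(batch)
        train_loss /= len(order)
        val_pred = np.concatenate(
            [net.forward(x_val[i:i + 256], train=False)
             for i in range(0, len(x_val), 256)])
        val_loss = float(((val_pred - z_val) ** 2).mean())
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss})
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = net.state_dict()
            best_epoch = epoch
        elif epoch - best_epoch >= config.patience:
            break
    net.load_state_dict(best_state)
    return TrainedRegressor(net, spec, config, norm, history)


def predict_activity(model: TrainedRegressor, encodings: np.ndarray
                     ) -> np.ndarray:
    return model.predict(encodings)


# ---------------------------------------------------------------------------
# Metrics


def evaluate_metrics(predictions: np.ndarray, labels: np.ndarray
                     ) -> MetricsReport:
    """RMSE, Pearson r, Spearman rho; pairs with missing labels are dropped."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError("predictions and labels must have equal length")
    keep = np.isfinite(p) & np.isfinite(y)
    p, y = p[keep], y[keep]
    if len(p) < 2:
        raise ValueError("need at least 2 valid pairs")
    rmse = float(np.sqrt(((p - y) ** 2).mean()))
    pearson = float(stats.pearsonr(p, y).statistic)
    spearman = float(stats.spearmanr(p, y).statistic)
    return MetricsReport(rmse, pearson, spearman, int(len(p)))


# ---------------------------------------------------------------------------
# Checkpointing


def save_checkpoint(model: TrainedRegressor, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **model.network.state_dict())
    manifest = {
        "spec": model.spec.to_dict(),
        "config": model.config.to_dict(),
        "normalization": {"mean": model.norm.mean, "std": model.norm.std},
        "history": model.history,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(directory) -> TrainedRegressor:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    spec = RegressorSpec.from_dict(manifest["spec"])
    config = TrainingConfig(**manifest["config"])
    norm = NormalizationParams(**manifest["normalization"])
    net = build_network(spec, np.random.default_rng(config.seed))
    with np.load(directory / "weights.npz") as data:
        net.load_state_dict(dict(data))
    return TrainedRegressor(net, spec, config, norm, manifest["history"])
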