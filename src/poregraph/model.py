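"""Architecture definition, training and prediction for the kmer regressor.

The network maps a padded molecular graph (adjacency ``A`` and atom features
``X``) to one scalar ionic current in pA:

    GCN stack (ELU)  ->  1-D CNN stack (ReLU) with 2x2 stride-1 average
    pooling after every convolution  ->  row-wise flatten  ->  dense layer
    ->  scalar linear output

Layer widths follow the scaling rule ``n = 16 * 2**(l-1)`` counted from the
output end of each group, so a depth-4 GCN stack is 128/64/32/16 wide, and
the final GCN width N' sets the channel count entering the CNN stack.  A 10%
dropout follows every layer during training only.

Training minimizes mean-squared error with Adam (canonical defaults),
monitoring a held-out validation fraction of the training kmers for early
stopping.  Targets are z-scored internally using training-set statistics
and un-scaled at prediction time; reported losses are on the pA scale.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from . import nn
from .alphabet import Kmer
from .chem import N_FEATURES, encode_kmers
from .io import KmerModel

logger = logging.getLogger(__name__)

__all__ = [
    "ArchitectureConfig",
    "TrainConfig",
    "TrainedModel",
    "ConfigurationError",
    "TrainingDivergedError",
    "node_counts",
    "layer_dimensions",
    "build_network",
    "train",
    "train_on_kmers",
    "predict_kmers",
    "grid_search",
    "table3_grid",
    "DNA_OPTIMAL",
    "RNA_OPTIMAL",
    "RNA_MODIFIED_OPTIMAL",
    "REDUCED",
    "save_model",
    "load_model",
]


class ConfigurationError(ValueError):
    """Architecture cannot be built (e.g. a dimension collapses below 1)."""


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during training."""


@dataclass(frozen=True)
class ArchitectureConfig:
    """Hyperparameters of one architecture.

    The grid-searched space is {2..6} GCN layers, {2..6} CNN layers, kernel
    size in {2, 4, 10, 20} and dense width in {32, 128, 512, 2048, 8192}.
    """

    n_gcn_layers: int
    n_cnn_layers: int
    kernel_size: int
    dense_nodes: int
    pool_size: int = 2

    def __post_init__(self) -> None:
        if self.n_gcn_layers < 1 or self.n_cnn_layers < 0:
            raise ConfigurationError("layer counts must be positive")
        if self.kernel_size < 1:
            raise ConfigurationError("kernel size must be >= 1")
        if self.dense_nodes < 1:
            raise ConfigurationError("dense width must be >= 1")


#: Best grid-search architectures reported for each model family.
DNA_OPTIMAL = ArchitectureConfig(4, 3, 10, 8192)
RNA_OPTIMAL = ArchitectureConfig(4, 5, 10, 8192)
RNA_MODIFIED_OPTIMAL = ArchitectureConfig(6, 6, 10, 8192)
#: Small configuration for desk-scale experiments and tests.
REDUCED = ArchitectureConfig(2, 2, 4, 128)


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 500
    early_stop_patience: int = 10
    dropout_rate: float = 0.10
    validation_fraction: float = 0.10
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1 or self.early_stop_patience < 1:
            raise ValueError("epochs and patience must be positive")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")


def node_counts(group_depth: int) -> list[int]:
    """Layer widths for a group of *group_depth* layers, input -> output.

    Widths follow ``16 * 2**(l-1)`` counted from the output end, so depth 4
    gives ``[128, 64, 32, 16]``.
    """
    if group_depth < 1:
        raise ValueError(f"depth must be >= 1, got {group_depth}")
    return [16 * 2 ** (l - 1) for l in range(group_depth, 0, -1)]


def layer_dimensions(config: ArchitectureConfig, P: int) -> list[tuple[str, tuple[int, int]]]:
    """Output (rows, cols) of every GCN/CNN/pool stage, checking validity.

    The first CNN layer outputs {P - K + 1, N'} and every subsequent stage
    follows the recurrence {m - K + 1 - 2 + 1, n - 2 + 1} (convolution then
    2x2 stride-1 pooling shrinking both dimensions by one).
    """
    dims: list[tuple[str, tuple[int, int]]] = []
    gcn_widths = node_counts(config.n_gcn_layers)
    for i, w in enumerate(gcn_widths):
        dims.append((f"gcn{i}", (P, w)))
    m, n = P, gcn_widths[-1]
    cnn_channels = node_counts(config.n_cnn_layers) if config.n_cnn_layers else []
    for i, c_out in enumerate(cnn_channels):
        m = m - config.kernel_size + 1
        if m < 1:
            raise ConfigurationError(
                f"cnn{i}: convolution output length {m} < 1 (K={config.kernel_size})"
            )
        dims.append((f"cnn{i}", (m, c_out)))
        m, n = m - 1, c_out - 1
        if m < 1 or n < 1:
            raise ConfigurationError(f"pool{i}: pooled dims ({m}, {n}) collapse below 1")
        dims.append((f"pool{i}", (m, n)))
    dims.append(("flatten", (1, m * n)))
    dims.append(("dense", (1, config.dense_nodes)))
    dims.append(("out", (1, 1)))
    return dims


def build_network(
    config: ArchitectureConfig,
    P: int,
    n_features: int = N_FEATURES,
    dropout_rate: float = 0.10,
    seed: int = 0,
) -> nn.Network:
    """Instantiate the network for padding size *P* with seeded init."""
    layer_dimensions(config, P)  # validate before allocating anything
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    widths = node_counts(config.n_gcn_layers)
    c_in = n_features
    for w in widths:
        layers.append(nn.GraphConv(c_in, w, rng))
        layers.append(nn.Dropout(dropout_rate))
        c_in = w
    m, n = P, widths[-1]
    for c_out in node_counts(config.n_cnn_layers) if config.n_cnn_layers else []:
        layers.append(nn.Conv1D(n, c_out, config.kernel_size, rng))
        layers.append(nn.AvgPool2())
        layers.append(nn.Dropout(dropout_rate))
        m = m - config.kernel_size + 1 - 1
        n = c_out - 1
    layers.append(nn.Flatten())
    layers.append(nn.Dense(m * n, config.dense_nodes, rng, activation=None))
    layers.append(nn.Dropout(dropout_rate))
    layers.append(nn.Dense(config.dense_nodes, 1, rng, activation=None))
    return nn.Network(layers)


@dataclass
class TrainedModel:
    """A fitted network plus everything needed to reproduce predictions."""

    config: ArchitectureConfig
    train_config: TrainConfig
    network: nn.Network
    padding: int
    y_mean: float
    y_sd: float
    history: dict[str, list[float]]
    train_fingerprint: str = ""

    def predict_tensors(self, A: np.ndarray, X: np.ndarray,
                        batch_size: int = 256) -> np.ndarray:
        """Predict pA values from pre-normalized adjacency + features."""
        out = []
        for start in range(0, len(A), batch_size):
            sl = slice(start, start + batch_size)
            pred = self.network.forward(A[sl], X[sl], train=False)
            out.append(pred[:, 0])
        return np.concatenate(out) * self.y_sd + self.y_mean


def _fingerprint(kmers: Sequence[Kmer]) -> str:
    import hashlib

    h = hashlib.sha256("\n".join(sorted(map(str, kmers))).encode())
    return h.hexdigest()[:16]


def train(
    network: nn.Network,
    A_hat: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    config: ArchitectureConfig,
    train_config: TrainConfig,
    padding: int,
    fingerprint: str = "",
) -> TrainedModel:
    """Fit *network* on normalized-adjacency tensors and pA targets.

    A validation fraction of the samples is held out for early stopping:
    training stops after `early_stop_patience` epochs without improvement
    in validation loss, and the best-validation weights are restored.
    Deterministic for a fixed seed on a single thread.
    """
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 training samples")
    y = np.asarray(y, dtype=np.float64)
    rng = np.random.default_rng(train_config.seed)

    n_val = max(1, int(round(train_config.validation_fraction * n)))
    if n_val >= n:
        raise ValueError("validation split leaves no training samples")
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    y_mean = float(y[tr_idx].mean())
    y_sd = float(y[tr_idx].std())
    if y_sd == 0.0:
        y_sd = 1.0
    yn = (y - y_mean) / y_sd

    opt = nn.Adam(network, learning_rate=train_config.learning_rate)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = network.get_weights()
    epochs_since_improvement = 0
    bs = train_config.batch_size

    for epoch in range(train_config.max_epochs):
        order = rng.permutation(tr_idx)
        epoch_loss, n_seen = 0.0, 0
        for start in range(0, len(order), bs):
            idx = order[start : start + bs]
            pred = network.forward(A_hat[idx], X[idx], train=True, rng=rng)[:, 0]
            resid = pred - yn[idx]
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
            network.backward((2.0 * resid / len(idx))[:, None])
            opt.step()
            epoch_loss += loss * len(idx)
            n_seen += len(idx)
        train_loss = epoch_loss / n_seen * y_sd**2

        val_pred = _predict_normalized(network, A_hat, X, val_idx)
        val_loss = float(np.mean((val_pred - yn[val_idx]) ** 2)) * y_sd**2
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)

        if val_loss < best_val:
            best_val = val_loss
            best_weights = network.get_weights()
            epochs_since_improvement = 0
        else:
            epochs_since_improvement += 1
            if epochs_since_improvement >= train_config.early_stop_patience:
                logger.info("early stop at epoch %d (best val %.4f)", epoch, best_val)
                break

    network.set_weights(best_weights)
    return TrainedModel(
        config=config,
        train_config=train_config,
        network=network,
        padding=padding,
        y_mean=y_mean,
        y_sd=y_sd,
        history=history,
        train_fingerprint=fingerprint,
    )


def _predict_normalized(network, A_hat, X, idx, batch_size: int = 256):
    out = []
    for start in range(0, len(idx), batch_size):
        sl = idx[start : start + batch_size]
        out.append(network.forward(A_hat[sl], X[sl], train=False)[:, 0])
    return np.concatenate(out)


def encode_and_normalize(kmers: Sequence[Kmer], P: int) -> tuple[np.ndarray, np.ndarray]:
    """Encode kmers and return (Â, X) ready for the network."""
    A, X, _ = encode_kmers(kmers, P)
    return nn.normalize_adjacency(A), X


def train_on_kmers(
    kmers: Sequence[Kmer],
    reference: KmerModel,
    config: ArchitectureConfig,
    train_config: TrainConfig,
    P: int,
) -> TrainedModel:
    """Convenience wrapper: encode *kmers*, look up targets, build and fit."""
    A_hat, X = encode_and_normalize(kmers, P)
    y = reference.values_for(kmers)
    network = build_network(
        config, P, dropout_rate=train_config.dropout_rate, seed=train_config.seed
    )
    return train(
        network, A_hat, X, y, config, train_config, P,
        fingerprint=_fingerprint(kmers),
    )


def predict_kmers(model: TrainedModel, kmers: Sequence[Kmer]) -> KmerModel:
    """Predict one pA value per kmer (dropout disabled, deterministic)."""
    A_hat, X = encode_and_normalize(kmers, model.padding)
    values = model.predict_tensors(A_hat, X)
    return KmerModel.from_pairs(kmers, values, provenance="predicted")


def table3_grid() -> list[ArchitectureConfig]:
    """The full 500-combination hyperparameter grid."""
    return [
        ArchitectureConfig(g, c, k, d)
        for g, c, k, d in itertools.product(
            (2, 3, 4, 5, 6), (2, 3, 4, 5, 6), (2, 4, 10, 20),
            (32, 128, 512, 2048, 8192),
        )
    ]


def grid_search(
    grid: Sequence[ArchitectureConfig],
    kmers: Sequence[Kmer],
    reference: KmerModel,
    P: int,
    train_config: Optional[TrainConfig] = None,
    folds: int = 10,
    seed: int = 0,
) -> tuple[ArchitectureConfig, list[dict]]:
    """K-fold cross-validated grid search; lowest mean fold RMSE wins.

    Invalid configurations (dimension collapse at the given padding) are
    skipped with a logged reason.  Returns the best configuration and the
    full results table (one dict per evaluated configuration).
    """
    if len(kmers) < folds:
        raise ValueError(f"dataset of {len(kmers)} kmers cannot be split into {folds} folds")
    tc = train_config or TrainConfig()
    A_hat, X = encode_and_normalize(kmers, P)
    y = reference.values_for(kmers)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(kmers))
    fold_ids = np.array_split(perm, folds)

    results: list[dict] = []
    best: Optional[ArchitectureConfig] = None
    best_rmse = np.inf
    for config in grid:
        try:
            layer_dimensions(config, P)
        except ConfigurationError as e:
            logger.info("skipping %s: %s", config, e)
            results.append({"config": config, "mean_rmse": None, "skipped": str(e)})
            continue
        fold_rmses = []
        for f, test_ids in enumerate(fold_ids):
            train_ids = np.setdiff1d(perm, test_ids)
            net = build_network(config, P, dropout_rate=tc.dropout_rate,
                                seed=tc.seed + f)
            fitted = train(
                net, A_hat[train_ids], X[train_ids], y[train_ids],
                config, TrainConfig(**{**asdict(tc), "seed": tc.seed + f}), P,
            )
            pred = fitted.predict_tensors(A_hat[test_ids], X[test_ids])
            fold_rmses.append(float(np.sqrt(np.mean((pred - y[test_ids]) ** 2))))
        mean_rmse = float(np.mean(fold_rmses))
        results.append({"config": config, "mean_rmse": mean_rmse,
                        "fold_rmses": fold_rmses})
        if mean_rmse < best_rmse:
            best, best_rmse = config, mean_rmse
    if best is None:
        raise ConfigurationError("no valid configuration in grid")
    return best, results


def save_model(model: TrainedModel, path) -> None:
    """Serialize config + weights + history to a single ``.npz`` archive."""
    meta = {
        "config": asdict(model.config),
        "train_config": asdict(model.train_config),
        "padding": model.padding,
        "y_mean": model.y_mean,
        "y_sd": model.y_sd,
        "history": model.history,
        "train_fingerprint": model.train_fingerprint,
    }
    arrays = {f"w/{k}": v for k, v in model.network.get_weights().items()}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        weights = {
            k[len("w/"):]: data[k] for k in data.files if k.startswith("w/")
        }
    config = ArchitectureConfig(**meta["config"])
    tc = TrainConfig(**meta["train_config"])
    network = build_network(
        config, meta["padding"], dropout_rate=tc.dropout_rate, seed=tc.seed
    )
    network.set_weights(weights)
    return TrainedModel(
        config=config,
        train_config=tc,
        network=network,
        padding=meta["padding"],
        y_mean=meta["y_mean"],
        y_sd=meta["y_sd"],
        history=meta["history"],
        train_fingerprint=meta["train_fingerprint"],
    )
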