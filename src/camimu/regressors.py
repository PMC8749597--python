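"""Acceleration regressors: DNN, CNN and deep bidirectional LSTM.

All three consume a window of per-frame joint features (shape
``window × feature_dim``) and emit the tri-axial wrist acceleration of the
window's center frame through a 3-unit linear head.  The DNN flattens the
window; the CNN treats it as a one-channel image and convolves over the
time × feature plane; the DBLSTM reads it as a sequence — a bidirectional
LSTM layer followed by a unidirectional LSTM whose final state feeds the
head.  Batch normalization follows every hidden layer and dropout sits at
the positions listed in each architecture's layer table.

Training minimizes the mean squared error between predicted and target
acceleration with the Nadam optimizer (initial learning rate 5e-4), early
stopping on a held-out contiguous validation block, and returns the weights
of the best validation epoch.

Two width profiles exist: ``full`` (the complete layer sizes: DNN
36-324-324-324-36, CNN filters 32-64-128-256, DBLSTM 128/256) and ``desk``
(all widths divided by 4) so the full pipeline trains in minutes on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ConfigError, DivergenceError, ShapeError
from .features import NormStats, WindowedDataset
from .nn import (
    BatchNorm,
    BiLSTM,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    LSTM,
    Nadam,
    ReLU,
    Reshape,
    Sequential,
)

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "TrainedModel",
    "NeuralRegressor",
    "build_model",
    "train",
    "predict",
    "save_model",
    "load_model",
]

KINDS = ("DNN", "CNN", "DBLSTM")

_DNN_WIDTHS = (36, 324, 324, 324, 36)
_DNN_DROPOUT = (None, 0.3, 0.2, None, None)
_CNN_FILTERS = (32, 64, 128, 256)
_CNN_DROPOUT = (None, 0.3, 0.2, None)
_DBLSTM_UNITS = (128, 256)
_DBLSTM_DROPOUT = (0.3, 0.2)


@dataclass
class ModelSpec:
    """Architecture selector: kind, window geometry and width profile."""

    kind: str
    input_dim: int  # per-frame feature dimension (9 for 2D, 12 for 3D)
    window: int = 25
    output_dim: int = 3
    scale_profile: str = "desk"  # "full" | "desk"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigError(f"unknown model kind {self.kind!r}; expected {KINDS}")
        if self.scale_profile not in ("full", "desk"):
            raise ConfigError(f"unknown scale_profile {self.scale_profile!r}")
        if self.input_dim < 1 or self.window < 1:
            raise ConfigError("input_dim and window must be >= 1")

    @property
    def width_divisor(self) -> int:
        return 1 if self.scale_profile == "full" else 4


@dataclass
class TrainConfig:
    """Optimization settings; the full profile uses batch size 1024, the desk
    default 256."""

    learning_rate: float = 5e-4
    batch_size: int = 256
    epochs: int = 40
    optimizer: str = "nadam"
    seed: int = 0
    patience: int = 10
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")


class NeuralRegressor:
    """A built (possibly untrained) network plus its spec and RNG."""

    def __init__(self, spec: ModelSpec, net: Sequential, rng: np.random.Generator):
        self.spec = spec
        self.net = net
        self.rng = rng

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[1] != self.spec.window or X.shape[2] != self.spec.input_dim:
            raise ShapeError(
                f"expected windows of shape (N, {self.spec.window}, "
                f"{self.spec.input_dim}), got {X.shape}"
            )
        return X

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(self.check_input(X), train=train)


@dataclass
class TrainedModel:
    """Weights at the best validation epoch, training history and the
    normalization statistics the features were standardized with.

    ``target_stats`` holds the per-axis mean/SD the acceleration targets
    were standardized with during optimization (so every axis contributes
    comparably to the loss); predictions are mapped back to m/s².
    """

    model: NeuralRegressor
    history: list[dict] = field(default_factory=list)
    norm_stats: NormStats | None = None
    target_stats: NormStats | None = None

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec


def build_model(spec: ModelSpec, seed: int = 0) -> NeuralRegressor:
    """Assemble the network for ``spec`` with seeded initialization."""
    rng = np.random.default_rng(seed)
    d = spec.width_divisor
    D, T = spec.input_dim, spec.window
    layers: list = []
    if spec.kind == "DNN":
        layers.append(Flatten())
        n_in = T * D
        for width, drop in zip(_DNN_WIDTHS, _DNN_DROPOUT):
            w = max(width // d, 1)
            layers += [Dense(n_in, w, rng), BatchNorm(w), ReLU()]
            if drop:
                layers.append(Dropout(drop, rng))
            n_in = w
        layers.append(Dense(n_in, spec.output_dim, rng))
    elif spec.kind == "CNN":
        # conv stack over the time x feature plane, full resolution retained
        # (the layer table lists convolutions and dropout only; pooling would
        # blur the temporal localization of the center-frame target)
        layers.append(Reshape((1, T, D)))
        c_in = 1
        for filt, drop in zip(_CNN_FILTERS, _CNN_DROPOUT):
            c_out = max(filt // d, 1)
            layers += [Conv2D(c_in, c_out, rng), BatchNorm(c_out, channel_axis=1),
                       ReLU()]
            if drop:
                layers.append(Dropout(drop, rng))
            c_in = c_out
        layers.append(Flatten())
        layers.append(Dense(c_in * T * D, spec.output_dim, rng))
    else:  # DBLSTM
        u1 = max(_DBLSTM_UNITS[0] // d, 1)
        u2 = max(_DBLSTM_UNITS[1] // d, 1)
        layers += [
            BiLSTM(D, u1, rng),
            BatchNorm(2 * u1),
            Dropout(_DBLSTM_DROPOUT[0], rng),
            LSTM(2 * u1, u2, rng, return_sequences=False),
            BatchNorm(u2),
            Dropout(_DBLSTM_DROPOUT[1], rng),
            Dense(u2, spec.output_dim, rng),
        ]
    return NeuralRegressor(spec, Sequential(layers), rng)


def _split_train_val(n: int, val_fraction: float, gap: int) -> tuple[np.ndarray, np.ndarray]:
    """Contiguous-block train/validation split with a gap of ``gap`` windows
    dropped at the boundary so overlapping windows cannot leak across it."""
    n_val = max(int(round(n * val_fraction)), 1)
    cut = n - n_val
    train_idx = np.arange(0, max(cut - gap, 1))
    val_idx = np.arange(cut, n)
    return train_idx, val_idx


def train(
    model: NeuralRegressor,
    dataset: WindowedDataset,
    cfg: TrainConfig,
    norm_stats: NormStats | None = None,
    verbose: bool = False,
) -> TrainedModel:
    """Minimize MSE on the windowed dataset; return best-validation weights.

    The last ``val_fraction`` of windows (a contiguous block, separated from
    the training block by one window length) is used for validation and
    early stopping.  Targets are standardized per axis during optimization
    so that low-amplitude axes are not drowned out of the loss; reported
    train/val MSE are on the standardized scale, with ``val_mse_raw`` in
    (m/s²)² alongside.  Raises :class:`DivergenceError` if the loss becomes
    non-finite.
    """
    if dataset.y is None or len(dataset) == 0:
        raise ValueError("training requires a non-empty labelled dataset")
    X = model.check_input(dataset.X)
    y = np.asarray(dataset.y, dtype=np.float32)
    tr_idx, va_idx = _split_train_val(len(X), cfg.val_fraction, gap=dataset.window)
    target_stats = NormStats.fit(y[tr_idx].astype(float))
    y = target_stats.apply(y).astype(np.float32)
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xva, yva = X[va_idx], y[va_idx]
    rng = np.random.default_rng(cfg.seed)
    opt = Nadam(model.net.params, model.net.grads, lr=cfg.learning_rate)
    history: list[dict] = []
    best_val = np.inf
    best_weights = model.net.get_weights()
    since_best = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(Xtr))
        train_loss = 0.0
        n_seen = 0
        for start in range(0, len(Xtr), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            model.net.zero_grad()
            pred = model.net.forward(xb, train=True)
            err = pred - yb
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            model.net.backward((2.0 * err / err.size).astype(np.float32))
            opt.step()
            train_loss += loss * len(xb)
            n_seen += len(xb)
        train_loss /= max(n_seen, 1)
        val_pred = _forward_batched(model, Xva)
        val_loss = float(np.mean((val_pred - yva) ** 2))
        if not np.isfinite(val_loss):
            raise DivergenceError(epoch)
        val_raw = float(
            np.mean(
                (val_pred * target_stats.std + target_stats.mean
                 - (yva * target_stats.std + target_stats.mean)) ** 2
            )
        )
        history.append({"epoch": epoch, "train_mse": train_loss,
                        "val_mse": val_loss, "val_mse_raw": val_raw})
        if verbose:
            print(f"epoch {epoch:3d}  train {train_loss:.5f}  val {val_loss:.5f}")
        if val_loss < best_val - 1e-7:
            best_val = val_loss
            best_weights = model.net.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    model.net.set_weights(best_weights)
    return TrainedModel(model=model, history=history, norm_stats=norm_stats,
                        target_stats=target_stats)


def _forward_batched(model: NeuralRegressor, X: np.ndarray, batch: int = 1024) -> np.ndarray:
    outs = [model.net.forward(X[i:i + batch], train=False)
            for i in range(0, len(X), batch)]
    return np.concatenate(outs, axis=0) if outs else np.empty((0, model.spec.output_dim))


def predict(trained: TrainedModel | NeuralRegressor, windows) -> np.ndarray:
    """Deterministic inference (dropout off, batch norm on running stats).

    Accepts a :class:`WindowedDataset` or a raw (N, window, D) array and
    returns (N, 3) predicted accelerations aligned to window centers.
    """
    model = trained.model if isinstance(trained, TrainedModel) else trained
    X = windows.X if isinstance(windows, WindowedDataset) else np.asarray(windows)
    X = model.check_input(X)
    out = _forward_batched(model, X).astype(float)
    if isinstance(trained, TrainedModel) and trained.target_stats is not None:
        out = out * trained.target_stats.std + trained.target_stats.mean
    return out


# ---------------------------------------------------------------------------
# checkpointing


def save_model(trained: TrainedModel, stem) -> None:
    """Write weights to ``<stem>.npz`` and a JSON sidecar ``<stem>.json``
    holding the spec, history and normalization statistics."""
    stem = Path(stem)
    weights = {f"w{i}": w for i, w in enumerate(trained.model.net.get_weights())}
    # batch-norm running statistics travel with the weights
    running = {}
    for li, layer in enumerate(trained.model.net.layers):
        if isinstance(layer, BatchNorm):
            running[f"rm{li}"] = layer.running_mean
            running[f"rv{li}"] = layer.running_var
    np.savez(stem.with_suffix(".npz"), **weights, **running)
    sidecar = {
        "spec": asdict(trained.spec),
        "history": trained.history,
        "norm_stats": trained.norm_stats.to_dict() if trained.norm_stats else None,
        "target_stats": trained.target_stats.to_dict() if trained.target_stats else None,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_model(stem) -> TrainedModel:
    stem = Path(stem)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    spec = ModelSpec(**sidecar["spec"])
    model = build_model(spec, seed=0)
    data = np.load(stem.with_suffix(".npz"))
    model.net.set_weights([data[f"w{i}"] for i in range(len(model.net.params))])
    for li, layer in enumerate(model.net.layers):
        if isinstance(layer, BatchNorm):
            layer.running_mean = data[f"rm{li}"]
            layer.running_var = data[f"rv{li}"]
    stats = sidecar.get("norm_stats")
    tstats = sidecar.get("target_stats")
    return TrainedModel(
        model=model,
        history=sidecar.get("history", []),
        norm_stats=NormStats.from_dict(stats) if stats else None,
        target_stats=NormStats.from_dict(tstats) if tstats else None,
    )
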