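"""Multi-output convolutional regressor for growth-trait estimation.

Maps a 128x128x3 top-view image directly to the three growth traits (LFW g,
LDW g, LA cm^2) with a single network: five 5x5 convolutional layers (32, 64,
128, 216, 512 kernels; zero padding on the second and third so every pooled
feature map keeps an integer side), 2x2 stride-2 average pooling after the
first four, dropout 0.5 on the flattened 512-vector, and one fully connected
layer with three outputs.  Training is SGD (momentum 0.9) with a step
learning-rate schedule: lr(epoch) = lr0 * drop_factor**floor(epoch / drop_every).

Organised statsmodels-style: :class:`CNNTraitModel` is built from data and
``fit()`` returns a :class:`CNNTraitResults` carrying the fitted weights,
training history, target scaling and prediction/summary methods.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _nn
from .exceptions import ConfigurationError, DomainError, PipelineError
from .synthdata import TraitVector

logger = logging.getLogger(__name__)

TRAIT_NAMES = ("lfw", "ldw", "la")

__all__ = [
    "CNNConfig",
    "TrainConfig",
    "layer_shape_plan",
    "learning_rate",
    "CNNTraitModel",
    "CNNTraitResults",
    "TRAIT_NAMES",
]


@dataclass(frozen=True)
class CNNConfig:
    """Architecture hyperparameters (defaults are the reference network)."""

    input_side: int = 128
    conv_kernel: int = 5
    conv_channels: tuple[int, ...] = (32, 64, 128, 216, 512)
    padded_layers: frozenset[int] = frozenset({2, 3})  # 1-based conv indices
    pool: str = "average"  # or "max"
    dropout_rate: float = 0.5
    outputs: int = 3

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 5:
            raise ConfigurationError("expected exactly 5 convolutional layers")
        if self.pool not in ("average", "max"):
            raise ConfigurationError(f"unknown pool {self.pool!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.input_side <= 0 or self.outputs <= 0:
            raise ConfigurationError("input_side and outputs must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation schedule (defaults are the reference schedule)."""

    lr0: float = 0.001
    lr_drop_every: int = 20
    lr_drop_factor: float = 0.1
    momentum: float = 0.9
    clip_norm: float | None = 5.0  # global gradient-norm clip; None disables
    batch_size: int = 128
    max_epochs: int = 300
    rng_seed: int = 0
    target_scaling: str = "standardize"  # or "none"

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ConfigurationError("lr0 must be positive")
        if not 0.0 < self.lr_drop_factor < 1.0:
            raise ConfigurationError("lr_drop_factor must be in (0, 1)")
        if self.target_scaling not in ("standardize", "none"):
            raise ConfigurationError(
                f"unknown target_scaling {self.target_scaling!r}")


def learning_rate(epoch: int, config: TrainConfig) -> float:
    """Step schedule: lr0 * drop_factor ** floor(epoch / drop_every)."""
    return config.lr0 * config.lr_drop_factor ** (epoch // config.lr_drop_every)


def layer_shape_plan(config: CNNConfig) -> list[tuple[str, int, int]]:
    """Feature-map side and channel count after every layer.

    Pooling is only legal on an even side (2x2, stride 2, no padding), so the
    plan rejects any configuration whose pooled sides would be non-integer,
    naming the offending layer.
    """
    k = config.conv_kernel
    side = config.input_side
    plan: list[tuple[str, int, int]] = [("input", side, 3)]
    n_conv = len(config.conv_channels)
    for i, ch in enumerate(config.conv_channels, start=1):
        pad = 1 if i in config.padded_layers else 0
        new_side = side + 2 * pad - (k - 1)
        if new_side <= 0:
            raise ConfigurationError(
                f"conv{i}: input side {side} smaller than kernel {k}")
        side = new_side
        plan.append((f"conv{i}", side, ch))
        if i < n_conv:  # pooling after conv layers 1..4
            if side % 2 != 0:
                raise ConfigurationError(
                    f"pool{i}: feature-map side {side} is odd; "
                    "pooled side would be non-integer")
            side //= 2
            plan.append((f"pool{i}", side, ch))
    plan.append(("fc", 1, config.outputs))
    return plan


def _build_network(config: CNNConfig,
                   rng: np.random.Generator) -> _nn.Sequential:
    plan = layer_shape_plan(config)  # validates shapes
    pool_cls = _nn.AvgPool2 if config.pool == "average" else _nn.MaxPool2
    layers: list[_nn.Layer] = []
    in_ch = 3
    final_side = dict((name, side) for name, side, _ in plan)["conv5"]
    for i, ch in enumerate(config.conv_channels, start=1):
        pad = 1 if i in config.padded_layers else 0
        layers.append(_nn.Conv2D(in_ch, ch, config.conv_kernel, pad, rng))
        layers.append(_nn.ReLU())
        if i < len(config.conv_channels):
            layers.append(pool_cls())
        in_ch = ch
    layers.append(_nn.Flatten())
    layers.append(_nn.Dropout(config.dropout_rate))
    layers.append(_nn.Dense(in_ch * final_side * final_side, config.outputs, rng))
    return _nn.Sequential(layers)


def _to_nchw(images: np.ndarray, input_side: int) -> np.ndarray:
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[None]
    if images.ndim != 4 or images.shape[-1] != 3:
        raise DomainError("expected images shaped (N, H, W, 3)")
    if images.shape[1] != input_side or images.shape[2] != input_side:
        raise DomainError(
            f"images must be {input_side}x{input_side}, got "
            f"{images.shape[1]}x{images.shape[2]}")
    x = images.astype(np.float32)
    if x.max() > 1.5:  # 8-bit input
        x = x / 255.0
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


class CNNTraitModel:
    """Convolutional trait-regression model built from image/trait pairs.

    Parameters
    ----------
    images, targets:
        Training images ``(N, side, side, 3)`` (uint8 or [0,1] float) and
        targets ``(N, 3)`` ordered (LFW, LDW, LA).
    val_images, val_targets:
        Optional held-out pairs used to retain the best-validation-loss
        weights; when absent the training loss plays that role.
    """

    def __init__(self, images: np.ndarray, targets: np.ndarray,
                 config: CNNConfig | None = None,
                 val_images: np.ndarray | None = None,
                 val_targets: np.ndarray | None = None) -> None:
        self.config = config or CNNConfig()
        self.x = _to_nchw(images, self.config.input_side)
        self.y = np.asarray(targets, dtype=np.float32).reshape(len(self.x), -1)
        if self.y.shape[1] != self.config.outputs:
            raise DomainError(
                f"targets must have {self.config.outputs} columns")
        if not np.isfinite(self.y).all():
            raise DomainError("targets must be finite")
        if val_images is not None:
            self.x_val = _to_nchw(val_images, self.config.input_side)
            self.y_val = np.asarray(val_targets, dtype=np.float32) \
                .reshape(len(self.x_val), -1)
        else:
            self.x_val = None
            self.y_val = None

    def fit(self, train_config: TrainConfig | None = None) -> "CNNTraitResults":
        """Train with SGD + momentum under the step learning-rate schedule.

        Returns results holding the best-validation-loss weights, the
        per-epoch (lr, train_loss, val_loss) history and the target-scaling
        constants.  Deterministic for a fixed ``rng_seed``.
        """
        tc = train_config or TrainConfig()
        rng = np.random.default_rng(np.random.SeedSequence(tc.rng_seed))
        net = _build_network(self.config, rng)
        opt = _nn.SGDMomentum(net.layers, momentum=tc.momentum,
                              clip_norm=tc.clip_norm)

        if tc.target_scaling == "standardize":
            mu = self.y.mean(axis=0)
            sd = self.y.std(axis=0)
            sd = np.where(sd < 1e-8, 1.0, sd)
        else:
            mu = np.zeros(self.y.shape[1], dtype=np.float32)
            sd = np.ones(self.y.shape[1], dtype=np.float32)
        y_s = ((self.y - mu) / sd).astype(np.float32)
        y_val_s = None
        if self.x_val is not None:
            y_val_s = ((self.y_val - mu) / sd).astype(np.float32)

        n = len(self.x)
        batch = tc.batch_size
        if batch > n:
            warnings.warn(f"batch size {batch} larger than dataset ({n}); "
                          "clipping", stacklevel=2)
            batch = n

        history = []
        best_loss = np.inf
        best_params = net.get_params()
        for epoch in range(tc.max_epochs):
            lr = learning_rate(epoch, tc)
            order = rng.permutation(n)
            ep_loss = 0.0
            n_batches = 0
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                pred = net.forward(self.x[idx], train=True, rng=rng)
                loss, dpred = _nn.mse_loss(pred, y_s[idx])
                if not np.isfinite(loss):
                    raise PipelineError(
                        f"NaN/inf loss at epoch {epoch}; lower the learning "
                        "rate or check target scaling")
                net.backward(dpred)
                opt.step(lr)
                ep_loss += loss
                n_batches += 1
            train_loss = ep_loss / max(n_batches, 1)
            if self.x_val is not None and len(self.x_val):
                val_pred = _forward_eval(net, self.x_val)
                val_loss, _ = _nn.mse_loss(val_pred, y_val_s)
            else:
                val_loss = train_loss
            if val_loss < best_loss:
                best_loss = val_loss
                best_params = net.get_params()
            history.append({"epoch": epoch, "lr": lr,
                            "train_loss": train_loss, "val_loss": val_loss})
        net.set_params(best_params)
        return CNNTraitResults(model=self, network=net,
                               history=pd.DataFrame(history),
                               target_mean=mu.astype(np.float64),
                               target_sd=sd.astype(np.float64),
                               train_config=tc)


def _forward_eval(net: _nn.Sequential, x: np.ndarray,
                  batch: int = 64) -> np.ndarray:
    outs = [net.forward(x[i:i + batch], train=False)
            for i in range(0, len(x), batch)]
    return np.concatenate(outs, axis=0)


class CNNTraitResults:
    """Fitted network plus training history and target scaling."""

    def __init__(self, model: CNNTraitModel | None, network: _nn.Sequential,
                 history: pd.DataFrame, target_mean: np.ndarray,
                 target_sd: np.ndarray, train_config: TrainConfig,
                 config: CNNConfig | None = None) -> None:
        self.model = model
        self.network = network
        self.history = history
        self.target_mean = target_mean
        self.target_sd = target_sd
        self.train_config = train_config
        self.config = config or (model.config if model else CNNConfig())

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Predicted (LFW, LDW, LA) per image, in physical units.

        Negative raw outputs are clamped to zero (count logged): weights and
        areas cannot be negative.
        """
        x = _to_nchw(np.asarray(images), self.config.input_side)
        raw = _forward_eval(self.network, x)
        pred = raw * self.target_sd + self.target_mean
        n_neg = int((pred < 0).sum())
        if n_neg:
            logger.info("clamped %d negative trait predictions to 0", n_neg)
            pred = np.clip(pred, 0.0, None)
        return pred

    def predict_traits(self, images: np.ndarray) -> list[TraitVector]:
        return [TraitVector(*row) for row in self.predict(images)]

    def weights_hash(self) -> str:
        """SHA-256 over all parameters; changes iff any weight changes."""
        h = hashlib.sha256()
        for layer in self.network.layers:
            for key in sorted(layer.params):
                h.update(np.ascontiguousarray(layer.params[key]).tobytes())
        return h.hexdigest()

    def summary(self) -> str:
        plan = layer_shape_plan(self.config)
        lines = ["CNN trait regressor", "=" * 40]
        lines += [f"{name:>8s}: {side:4d} x {side:<4d} x {ch}"
                  for name, side, ch in plan]
        hist = self.history
        if len(hist):
            lines.append("-" * 40)
            lines.append(f"epochs trained : {len(hist)}")
            lines.append(f"final train MSE: {hist['train_loss'].iloc[-1]:.6g}")
            lines.append(f"best val MSE   : {hist['val_loss'].min():.6g}")
        lines.append(f"target mean    : {np.round(self.target_mean, 4).tolist()}")
        lines.append(f"target sd      : {np.round(self.target_sd, 4).tolist()}")
        return "\n".join(lines)

    # --- persistence: single .npz archive with weights + configs -----------

    def save(self, path: Path | str) -> None:
        arrays: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.network.layers):
            for key, val in layer.params.items():
                arrays[f"layer{i}:{key}"] = val
        meta = {
            "config": {**asdict(self.config),
                       "padded_layers": sorted(self.config.padded_layers)},
            "train_config": asdict(self.train_config),
            "target_mean": self.target_mean.tolist(),
            "target_sd": self.target_sd.tolist(),
        }
        arrays["__meta__"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: Path | str) -> "CNNTraitResults":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg_d = dict(meta["config"])
        cfg_d["conv_channels"] = tuple(cfg_d["conv_channels"])
        cfg_d["padded_layers"] = frozenset(cfg_d["padded_layers"])
        config = CNNConfig(**cfg_d)
        tc = TrainConfig(**meta["train_config"])
        net = _build_network(config, np.random.default_rng(0))
        for i, layer in enumerate(net.layers):
            for key in layer.params:
                layer.params[key] = data[f"layer{i}:{key}"]
        return cls(model=None, network=net, history=pd.DataFrame(),
                   target_mean=np.asarray(meta["target_mean"]),
                   target_sd=np.asarray(meta["target_sd"]),
                   train_config=tc, config=config)
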