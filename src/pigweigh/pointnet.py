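"""Permutation-invariant point-set regressor for body weight.

The architecture follows the classic PointNet recipe adapted for scalar
regression: an optional input T-Net predicts a 3x3 linear transform that
canonicalizes the cloud's orientation; a stack of *shared* MLP layers (the
same dense+batchnorm+ReLU applied to every point) lifts each point to a
feature vector; channel-wise max pooling collapses the point dimension into a
global shape descriptor (this symmetric function is what makes the network
invariant to point order); and a dense head ending in a single rectified unit
outputs weight in kg. The feature-transform block of the original
classification network is omitted, and the classification top is replaced by
the rectified scalar head.

Input featurization deliberately preserves absolute scale: coordinates are
centered at the cloud's xy centroid and z is re-expressed as height above the
floor plane, but clouds are *not* rescaled to a unit sphere — the animal's
physical size is the weight signal.

Everything is pure numpy (see :mod:`pigweigh.nn`) with explicit seeds, so
training is bit-reproducible under fixed threading.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .cloud import PointCloud, PointCloudError
from .nn import Adam, BatchNorm, Dense, Param, relu, relu_backward
from .volume import DEFAULT_PLANE_DISTANCE

logger = logging.getLogger(__name__)

__all__ = [
    "PointNetRegressorConfig",
    "TrainConfig",
    "TrainingHistory",
    "PointNetRegressor",
    "ConfigurationError",
    "TrainingDivergedError",
    "build_regressor",
    "predict_weights",
    "train_regressor",
    "save_model",
    "load_model",
]


class ConfigurationError(ValueError):
    """Invalid architecture configuration."""


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during training."""

    def __init__(self, epoch: int):
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")
        self.epoch = epoch


def _scaled(widths: Sequence[int], scale: float) -> tuple[int, ...]:
    return tuple(max(4, int(round(w * scale))) for w in widths)


@dataclass(frozen=True)
class PointNetRegressorConfig:
    """Architecture of the point-set weight regressor.

    ``width_scale`` multiplies every layer width (rounded, floor 4) so that
    desk-scale experiments and tests can run the same architecture at a
    fraction of the compute.
    """

    n_points: int = 1500
    use_input_transform: bool = True
    use_feature_transform: bool = False
    shared_mlp_widths: tuple[int, ...] = (64, 64, 64, 128, 1024)
    head_widths: tuple[int, ...] = (512, 256)
    tnet_shared_widths: tuple[int, ...] = (32, 64, 128)
    tnet_head_widths: tuple[int, ...] = (64, 32)
    width_scale: float = 1.0
    plane_distance: float = DEFAULT_PLANE_DISTANCE

    def __post_init__(self) -> None:
        if self.n_points < 8:
            raise ConfigurationError("n_points must be >= 8")
        for ws in (self.shared_mlp_widths, self.head_widths,
                   self.tnet_shared_widths, self.tnet_head_widths):
            if not ws or any(w < 1 for w in ws):
                raise ConfigurationError("layer widths must be positive and nonempty")
        if self.width_scale <= 0:
            raise ConfigurationError("width_scale must be positive")
        if self.use_feature_transform:
            raise ConfigurationError(
                "the feature-transform block is omitted from this architecture "
                "(removed for computational simplicity); only the input transform "
                "is available"
            )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    Defaults: Adam at a constant learning rate 0.01, MSE loss (kg^2) with RMSE
    (kg) as the tracked metric, up to 1000 epochs with early stopping at
    patience 10 on validation RMSE, a 9:1 train/validation split, batch size
    32, and uniform per-coordinate jitter of +/-5 mm applied afresh each epoch to
    training clouds only. ``early_stop_patience=None`` disables early stopping.
    """

    learning_rate: float = 0.01
    max_epochs: int = 1000
    early_stop_patience: int | None = 10
    val_fraction: float = 0.1
    batch_size: int = 32
    jitter_amplitude: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.val_fraction < 1.0):
            raise ConfigurationError("val_fraction must lie in (0, 1)")
        if self.early_stop_patience is not None and self.early_stop_patience < 1:
            raise ConfigurationError("patience must be >= 1 (or None to disable)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ConfigurationError("batch_size and max_epochs must be >= 1")


@dataclass
class TrainingHistory:
    """Per-epoch training/validation RMSE (kg) and early-stopping summary."""

    train_rmse: list[float] = field(default_factory=list)
    val_rmse: list[float] = field(default_factory=list)
    best_epoch: int = 0          # 1-based epoch with the lowest validation RMSE
    stopped_epoch: int = 0       # last epoch actually run
    best_val_rmse: float = float("inf")


class _MLPStack:
    """Dense -> BatchNorm -> ReLU blocks applied to 2D row batches.

    The training path fuses batchnorm and the rectifier into two array passes
    (numba kernels) because these elementwise stages, not the matrix products,
    dominate wall time on wide shared layers; the numpy fallback is
    semantically identical.
    """

    def __init__(self, n_in: int, widths: Sequence[int], rng: np.random.Generator):
        self.blocks = []
        for w in widths:
            self.blocks.append((Dense(n_in, w, rng), BatchNorm(w)))
            n_in = w
        self.n_out = n_in
        self._cache: list[tuple] = []

    @property
    def params(self) -> list[Param]:
        return [p for d, bn in self.blocks for p in (*d.params, *bn.params)]

    @property
    def batchnorms(self) -> list[BatchNorm]:
        return [bn for _, bn in self.blocks]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training:
            for dense, bn in self.blocks:
                x = np.maximum(bn.forward(dense.forward(x, False), False), 0.0)
            return x
        self._cache = []
        for dense, bn in self.blocks:
            h = dense.forward(x, True)
            if nn.HAVE_NUMBA:
                mean, var = nn.bn_batch_stats(h)
                inv_std = (1.0 / np.sqrt(var + bn.eps)).astype(np.float32)
                bn.running_mean = (
                    bn.momentum * bn.running_mean + (1 - bn.momentum) * mean
                ).astype(np.float32)
                bn.running_var = (
                    bn.momentum * bn.running_var + (1 - bn.momentum) * var
                ).astype(np.float32)
                out = np.empty_like(h)
                nn.bn_relu_forward(h, mean, inv_std, bn.gamma.value, bn.beta.value, out)
                self._cache.append((bn, h, inv_std, out))  # h now holds xhat
            else:
                out, mask = relu(bn.forward(h, True))
                self._cache.append((bn, None, None, mask))
            x = out
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for (dense, _), (bn, xhat, inv_std, aux) in zip(
            reversed(self.blocks), reversed(self._cache)
        ):
            if nn.HAVE_NUMBA:
                coef = bn.gamma.value * inv_std
                dbeta, dgamma = nn.bn_relu_backward(dy, aux, xhat, coef)
                bn.beta.grad += dbeta
                bn.gamma.grad += dgamma
            else:
                dy = bn.backward(relu_backward(dy, aux))
            dy = dense.backward(dy)
        return dy


class _TNet:
    """Mini point network predicting a 3x3 input transform (identity at init)."""

    def __init__(self, config: PointNetRegressorConfig, rng: np.random.Generator):
        s = config.width_scale
        self.shared = _MLPStack(3, _scaled(config.tnet_shared_widths, s), rng)
        self.head = _MLPStack(self.shared.n_out, _scaled(config.tnet_head_widths, s), rng)
        # zero weights + identity bias => the transform starts as the identity
        self.out = Dense(self.head.n_out, 9, rng, weight_scale=0.0)
        self.out.b.value = np.eye(3, dtype=np.float32).ravel().copy()
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return self.shared.params + self.head.params + self.out.params

    @property
    def batchnorms(self) -> list[BatchNorm]:
        return self.shared.batchnorms + self.head.batchnorms

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, n, _ = x.shape
        feats = self.shared.forward(x.reshape(b * n, 3), training).reshape(b, n, -1)
        pooled, argmax = nn.maxpool_points(feats)
        t = self.out.forward(self.head.forward(pooled, training), training)
        if training:
            self._cache = (b, n, feats.shape[2], argmax)
        return t.reshape(b, 3, 3)

    def backward(self, dt: np.ndarray) -> np.ndarray:
        b, n, c, argmax = self._cache
        dpooled = self.head.backward(self.out.backward(dt.reshape(b, 9)))
        dfeats = np.zeros((b, n, c), dtype=np.float32)
        np.put_along_axis(dfeats, argmax[:, None, :], dpooled[:, None, :], axis=1)
        return self.shared.backward(dfeats.reshape(b * n, c)).reshape(b, n, 3)


class PointNetRegressor:
    """Point-set weight regressor; see module docstring for the architecture."""

    def __init__(self, config: PointNetRegressorConfig = PointNetRegressorConfig(),
                 seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        s = config.width_scale
        self.tnet = _TNet(config, rng) if config.use_input_transform else None
        self.shared = _MLPStack(3, _scaled(config.shared_mlp_widths, s), rng)
        self.head = _MLPStack(self.shared.n_out, _scaled(config.head_widths, s), rng)
        # positive bias keeps the rectified scalar output alive at initialization
        self.out = Dense(self.head.n_out, 1, rng, bias_init=10.0)
        self._cache = None

    # ------------------------------------------------------------------ params

    @property
    def params(self) -> list[Param]:
        ps = [] if self.tnet is None else list(self.tnet.params)
        return ps + self.shared.params + self.head.params + self.out.params

    def num_parameters(self) -> int:
        """Total trainable parameter count (weights, biases, BN scale/shift)."""
        return sum(p.value.size for p in self.params)

    def _batchnorms(self) -> list[BatchNorm]:
        bns = [] if self.tnet is None else list(self.tnet.batchnorms)
        return bns + self.shared.batchnorms + self.head.batchnorms

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, p in enumerate(self.params):
            state[f"param_{i}"] = p.value.copy()
        for i, bn in enumerate(self._batchnorms()):
            state[f"bn_{i}_mean"] = bn.running_mean.copy()
            state[f"bn_{i}_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params):
            p.value[...] = state[f"param_{i}"]
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean[...] = state[f"bn_{i}_mean"]
            bn.running_var[...] = state[f"bn_{i}_var"]

    # ----------------------------------------------------------------- forward

    def featurize(self, raw_points: np.ndarray) -> np.ndarray:
        """Camera-frame coordinates -> network input.

        Center x, y at the per-cloud centroid; express z as height above the
        floor plane (``L - z``). No unit-sphere rescaling: absolute size is
        the signal.
        """
        x = np.asarray(raw_points, dtype=np.float32).copy()
        x[:, :, :2] -= x[:, :, :2].mean(axis=1, keepdims=True)
        x[:, :, 2] = self.config.plane_distance - x[:, :, 2]
        return x

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Featurized input ``(B, N, 3)`` -> predictions ``(B,)``."""
        b, n, _ = x.shape
        t = None
        if self.tnet is not None:
            t = self.tnet.forward(x, training)
            xt = np.einsum("bni,bij->bnj", x, t)
        else:
            xt = x
        feats = self.shared.forward(xt.reshape(b * n, 3), training)
        c = feats.shape[1]
        feats3 = feats.reshape(b, n, c)
        pooled, argmax = nn.maxpool_points(feats3)
        h = self.head.forward(pooled, training)
        pre = self.out.forward(h, training)
        y, mask = relu(pre)
        if training:
            self._cache = (x, t, b, n, c, argmax, mask)
        return y[:, 0]

    def backward(self, dy: np.ndarray) -> None:
        x, t, b, n, c, argmax, mask = self._cache
        dpre = relu_backward(dy[:, None], mask)
        dpooled = self.head.backward(self.out.backward(dpre))
        dfeats3 = np.zeros((b, n, c), dtype=np.float32)
        np.put_along_axis(dfeats3, argmax[:, None, :], dpooled[:, None, :], axis=1)
        dxt = self.shared.backward(dfeats3.reshape(b * n, c)).reshape(b, n, 3)
        if self.tnet is not None:
            dt = np.einsum("bni,bnj->bij", x, dxt)
            # gradient w.r.t. the input is not needed (x is data), but the
            # T-Net branch consumes x and must receive its share
            self.tnet.backward(dt)


def build_regressor(
    config: PointNetRegressorConfig = PointNetRegressorConfig(), seed: int = 0
) -> PointNetRegressor:
    """Construct an untrained regressor from an architecture config."""
    return PointNetRegressor(config, seed=seed)


def _clouds_to_array(clouds: Sequence[PointCloud], n_points: int) -> np.ndarray:
    arrays = []
    for i, cloud in enumerate(clouds):
        if len(cloud) != n_points:
            raise PointCloudError(
                f"cloud {cloud.source_id or i!r} has {len(cloud)} points, "
                f"model expects exactly {n_points}"
            )
        arrays.append(cloud.points)
    return np.stack(arrays)


def predict_weights(
    model: PointNetRegressor,
    clouds: Sequence[PointCloud],
    batch_size: int = 32,
) -> np.ndarray:
    """Deterministic inference: one nonnegative kg prediction per cloud."""
    raw = _clouds_to_array(clouds, model.config.n_points)
    out = np.empty(len(raw), dtype=np.float64)
    for start in range(0, len(raw), batch_size):
        x = model.featurize(raw[start : start + batch_size])
        out[start : start + batch_size] = model.forward(x, training=False)
    return out


def train_regressor(
    model: PointNetRegressor,
    dataset: Sequence[tuple[PointCloud, float]],
    config: TrainConfig = TrainConfig(),
) -> TrainingHistory:
    """Train on (cloud, weight-kg) pairs with early stopping on validation RMSE.

    The dataset is split ``val_fraction : 1 - val_fraction`` with the config
    seed; each epoch applies fresh uniform jitter to *training* clouds only
    (validation is never augmented), minimizes MSE with Adam, and tracks RMSE.
    Training halts when validation RMSE has not improved for
    ``early_stop_patience`` consecutive epochs (or at ``max_epochs``), and the
    best-epoch weights are restored.
    """
    if len(dataset) < 10:
        raise ValueError(f"need >= 10 training samples, got {len(dataset)}")
    raw = _clouds_to_array([c for c, _ in dataset], model.config.n_points).astype(np.float32)
    labels = np.array([w for _, w in dataset], dtype=np.float32)

    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(raw))
    n_val = max(1, int(round(config.val_fraction * len(raw))))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    x_train_raw, y_train = raw[train_idx], labels[train_idx]
    x_val = model.featurize(raw[val_idx])
    y_val = labels[val_idx].astype(np.float64)
    logger.info("training on %d clouds, validating on %d", len(train_idx), n_val)

    optimizer = Adam(model.params, learning_rate=config.learning_rate)
    history = TrainingHistory()
    best_state: dict[str, np.ndarray] | None = None
    since_best = 0
    patience = config.early_stop_patience

    for epoch in range(1, config.max_epochs + 1):
        epoch_rng = np.random.default_rng([config.seed, epoch])
        jitter = epoch_rng.uniform(
            -config.jitter_amplitude, config.jitter_amplitude, size=x_train_raw.shape
        ).astype(np.float32)
        x_epoch = model.featurize(x_train_raw + jitter)
        order = epoch_rng.permutation(len(x_epoch))
        sq_err_sum, n_seen = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            xb, yb = x_epoch[batch], y_train[batch]
            pred = model.forward(xb, training=True)
            err = pred - yb
            loss = float(np.mean(err ** 2))
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            optimizer.zero_grad()
            model.backward((2.0 / len(batch)) * err.astype(np.float32))
            optimizer.step()
            sq_err_sum += loss * len(batch)
            n_seen += len(batch)

        train_rmse = float(np.sqrt(sq_err_sum / n_seen))
        val_pred = model.forward(x_val, training=False)
        val_rmse = float(np.sqrt(np.mean((val_pred - y_val) ** 2)))
        history.train_rmse.append(train_rmse)
        history.val_rmse.append(val_rmse)
        history.stopped_epoch = epoch
        logger.info("epoch %d: train RMSE %.3f kg, val RMSE %.3f kg", epoch, train_rmse, val_rmse)

        if val_rmse < history.best_val_rmse:
            history.best_val_rmse = val_rmse
            history.best_epoch = epoch
            best_state = model.state_dict()
            since_best = 0
        else:
            since_best += 1
            if patience is not None and since_best >= patience:
                logger.info("early stop at epoch %d (best epoch %d)", epoch, history.best_epoch)
                break

    # restore best-epoch weights under early stopping; with patience disabled the
    # final-epoch weights stand (matching the usual callback semantics)
    if patience is not None and best_state is not None:
        model.load_state_dict(best_state)
    return history


# ------------------------------------------------------------------ checkpoints

def save_model(model: PointNetRegressor, path: str | Path) -> None:
    """Write an ``.npz`` checkpoint embedding the architecture config."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_model(path: str | Path) -> PointNetRegressor:
    """Rebuild a regressor from an ``.npz`` checkpoint."""
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        for key in ("shared_mlp_widths", "head_widths", "tnet_shared_widths", "tnet_head_widths"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = PointNetRegressor(PointNetRegressorConfig(**cfg_dict))
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
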