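"""CNN and FNN °Brix regressors: construction, loss, metrics, training.

Four model families are supported:

* ``cnn_multi`` — 3-D multispectral input (ROI × ROI × bands-as-channels):
  two Conv(64)→ReLU→BN blocks each followed by max pooling, then
  FC→ReLU→BN→Dropout ×2 and a ReLU-activated scalar head.
* ``fnn_multi`` — 1-D mean-spectrum input: four FC→ReLU→BN→Dropout
  blocks (widths 256/128/64/32) and the scalar head.
* ``cnn_signature`` — six-band 3-D input: four Conv(64)→ReLU→BN blocks,
  one average pooling, FC→ReLU→BN→Dropout ×2, scalar head.
* ``fnn_signature`` — six-band 1-D input: four FC→ReLU→BN blocks
  (512/256/128/64, no dropout), scalar head.

Training minimizes RMSLE with Adam under per-epoch exponential
learning-rate decay lr_j = lr0·exp(−k·j); the weights with the lowest
validation RMSLE seen so far are checkpointed and returned.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import _nn


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    family: str                      # cnn_multi | fnn_multi | cnn_signature | fnn_signature
    input_shape: tuple               # (C,) for FNN, (H, W, C) for CNN
    fc_units: tuple = ()
    conv_kernel: tuple = (1, 5)
    pool_kind: str = "max"
    pool_sizes: tuple = ((1, 2), (1, 2))
    conv_filters: int = 64
    dropout_rate: float = 0.3
    l2_lambda: float = 1e-10

    def __post_init__(self):
        if self.fc_units and self.fc_units[-1] != 1:
            raise ValueError(
                f"fc_units must end in the scalar output 1, got {self.fc_units}"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class TrainConfig:
    initial_lr: float = 1e-3
    decay_k: float = 1e-6            # per-epoch exponential decay rate
    batch_size: int = 32
    max_epochs: int = 500
    patience: int = 100              # early stop after this many non-improving epochs
    seed: int = 0

    def __post_init__(self):
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if self.decay_k < 0 or self.batch_size < 1:
            raise ValueError("decay_k must be >= 0 and batch_size >= 1")


@dataclass
class Metrics:
    mae: float
    r2: float
    train_loss: list = field(default_factory=list)
    valid_loss: list = field(default_factory=list)
    epochs_run: int = 0
    best_epoch: int = -1


# ---------------------------------------------------------------------------
# published hyperparameter presets, keyed by spectral-range label
# ---------------------------------------------------------------------------

CNN_MULTI_PRESETS = {
    "VISWIR": dict(conv_kernel=(1, 5), pool_sizes=((1, 2), (1, 2)),
                   fc_units=(2048, 512, 1), batch_size=32,
                   dropout_rate=0.3, initial_lr=0.0006),
    "VISNIR": dict(conv_kernel=(1, 2), pool_sizes=((1, 2), (2, 1)),
                   fc_units=(1024, 256, 1), batch_size=64,
                   dropout_rate=0.3, initial_lr=0.0006),
    "VIS": dict(conv_kernel=(1, 2), pool_sizes=((2, 1), (2, 1)),
                fc_units=(1024, 512, 1), batch_size=128,
                dropout_rate=0.2, initial_lr=0.0006),
    "SWIR": dict(conv_kernel=(1, 5), pool_sizes=((2, 2), (2, 2)),
                 fc_units=(1024, 512, 1), batch_size=32,
                 dropout_rate=0.1, initial_lr=0.001),
}

FNN_MULTI_PRESETS = {
    "VISWIR": dict(fc_units=(256, 128, 64, 32, 1), batch_size=32,
                   dropout_rate=0.3, initial_lr=0.001),
    "VISNIR": dict(fc_units=(256, 128, 64, 32, 1), batch_size=64,
                   dropout_rate=0.3, initial_lr=0.001),
    "VIS": dict(fc_units=(256, 128, 64, 32, 1), batch_size=128,
                dropout_rate=0.3, initial_lr=0.001),
    "SWIR": dict(fc_units=(256, 128, 64, 32, 1), batch_size=64,
                 dropout_rate=0.3, initial_lr=0.001),
}

CNN_SIGNATURE_PRESETS = {
    "VISWIR": dict(conv_kernel=(4, 1), pool_sizes=((2, 2),),
                   fc_units=(1024, 512, 1), batch_size=16,
                   initial_lr=0.0004),
    "VISNIR": dict(conv_kernel=(4, 1), pool_sizes=((2, 2),),
                   fc_units=(1024, 512, 1), batch_size=128,
                   initial_lr=0.0008),
    "VIS": dict(conv_kernel=(4, 1), pool_sizes=((1, 4),),
                fc_units=(1024, 512, 1), batch_size=64,
                initial_lr=0.0004),
}

FNN_SIGNATURE_PRESETS = {
    "VISWIR": dict(fc_units=(512, 256, 128, 64, 1), batch_size=64,
                   initial_lr=0.0008),
    "VISNIR": dict(fc_units=(512, 256, 128, 64, 1), batch_size=128,
                   initial_lr=0.0008),
    "VIS": dict(fc_units=(512, 256, 128, 64, 1), batch_size=128,
                initial_lr=0.0008),
}


def preset_spec(family: str, range_label: str, input_shape: tuple
                ) -> tuple[ModelSpec, dict]:
    """Published (ModelSpec, training kwargs) for a family and range."""
    tables = {
        "cnn_multi": (CNN_MULTI_PRESETS, "max"),
        "fnn_multi": (FNN_MULTI_PRESETS, None),
        "cnn_signature": (CNN_SIGNATURE_PRESETS, "average"),
        "fnn_signature": (FNN_SIGNATURE_PRESETS, None),
    }
    if family not in tables:
        raise ValueError(f"unknown model family {family!r}")
    presets, pool_kind = tables[family]
    if range_label not in presets:
        raise ValueError(
            f"no {family} preset for range {range_label!r} "
            f"(have {sorted(presets)})"
        )
    p = dict(presets[range_label])
    train_kwargs = {"batch_size": p.pop("batch_size"),
                    "initial_lr": p.pop("initial_lr")}
    spec = ModelSpec(family=family, input_shape=tuple(input_shape),
                     pool_kind=pool_kind or "max",
                     dropout_rate=p.pop("dropout_rate", 0.2), **p)
    return spec, train_kwargs


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_fnn(spec: ModelSpec, seed: int = 0) -> _nn.Sequential:
    """Stack of FC→ReLU→BN(→Dropout) blocks ending in a ReLU scalar head."""
    if len(spec.input_shape) != 1:
        raise ValueError("FNN input_shape must be (n_bands,)")
    if not spec.fc_units or spec.fc_units[-1] != 1:
        raise ValueError("fc_units must end in 1")
    rng = np.random.default_rng(seed)
    with_dropout = spec.family != "fnn_signature"
    layers: list[_nn.Layer] = []
    n_in = spec.input_shape[0]
    for width in spec.fc_units[:-1]:
        layers += [_nn.Dense(n_in, width, rng), _nn.ReLU(),
                   _nn.BatchNorm(width)]
        if with_dropout and spec.dropout_rate > 0:
            layers.append(_nn.Dropout(spec.dropout_rate))
        n_in = width
    layers += [_nn.Dense(n_in, 1, rng), _nn.ReLU()]
    return _nn.Sequential(layers)


def build_cnn(spec: ModelSpec, seed: int = 0) -> _nn.Sequential:
    """Convolutional °Brix regressor over an ROI with bands as channels."""
    if len(spec.input_shape) != 3:
        raise ValueError("CNN input_shape must be (H, W, n_bands)")
    h, w, c = spec.input_shape
    rng = np.random.default_rng(seed)
    layers: list[_nn.Layer] = []
    n_conv = 4 if spec.family == "cnn_signature" else 2
    pool_cls = (_nn.AvgPool2D if spec.pool_kind == "average"
                else _nn.MaxPool2D)
    pools = list(spec.pool_sizes)
    c_in = c
    for i in range(n_conv):
        layers += [
            _nn.Conv2D(c_in, spec.conv_filters, spec.conv_kernel, rng,
                       l2_lambda=spec.l2_lambda),
            _nn.ReLU(), _nn.BatchNorm(spec.conv_filters),
        ]
        c_in = spec.conv_filters
        # multispectral family: a pool follows every conv block;
        # signature family: a single pool after the conv stack
        if spec.family == "cnn_multi" and i < len(pools):
            ph, pw = pools[i]
            if h // ph < 1 or w // pw < 1:
                raise ValueError(
                    f"pool {i + 1} of size {ph}x{pw} collapses a spatial "
                    f"axis of {h}x{w}"
                )
            layers.append(pool_cls((ph, pw)))
            h, w = h // ph, w // pw
    if spec.family == "cnn_signature":
        ph, pw = pools[0]
        if h // ph < 1 or w // pw < 1:
            raise ValueError(
                f"average pool of size {ph}x{pw} collapses a spatial axis "
                f"of {h}x{w}"
            )
        layers.append(pool_cls((ph, pw)))
        h, w = h // ph, w // pw
    layers.append(_nn.Flatten())
    n_in = h * w * spec.conv_filters
    for width in spec.fc_units[:-1]:
        layers += [_nn.Dense(n_in, width, rng), _nn.ReLU(),
                   _nn.BatchNorm(width), _nn.Dropout(spec.dropout_rate)]
        n_in = width
    layers += [_nn.Dense(n_in, 1, rng), _nn.ReLU()]
    return _nn.Sequential(layers)


def build_model(spec: ModelSpec, seed: int = 0) -> _nn.Sequential:
    if spec.family.startswith("cnn"):
        return build_cnn(spec, seed=seed)
    return build_fnn(spec, seed=seed)


# ---------------------------------------------------------------------------
# loss, schedule, metrics
# ---------------------------------------------------------------------------

def rmsle(pred: np.ndarray, true: np.ndarray) -> float:
    """Root mean squared logarithmic error on log1p-transformed values."""
    pred = np.asarray(pred, dtype=float).ravel()
    true = np.asarray(true, dtype=float).ravel()
    if pred.shape != true.shape:
        raise ValueError("pred and true must have equal length")
    if np.any(pred < 0) or np.any(true < 0):
        raise ValueError("rmsle requires nonnegative inputs")
    d = np.log1p(pred) - np.log1p(true)
    return float(np.sqrt(np.mean(d * d)))


def _rmsle_grad(pred: np.ndarray, true: np.ndarray
                ) -> tuple[float, np.ndarray]:
    """(loss, dloss/dpred); gradient is 0 at the loss minimum."""
    pred = pred.ravel()
    d = np.log1p(pred) - np.log1p(true.ravel())
    loss = float(np.sqrt(np.mean(d * d)))
    if loss == 0.0:
        return 0.0, np.zeros_like(pred)
    grad = d / (len(pred) * loss * (1.0 + pred))
    return loss, grad


def lr_schedule(lr0: float, k: float, j: int) -> float:
    """Exponential decay lr_j = lr0·exp(−k·j) at epoch index j."""
    if lr0 < 0:
        raise ValueError("initial learning rate must be nonnegative")
    if j < 0:
        raise ValueError("epoch index must be >= 0")
    return lr0 * math.exp(-k * j)


def mae(pred: np.ndarray, true: np.ndarray) -> float:
    """Mean absolute error (°Brix)."""
    pred = np.asarray(pred, dtype=float).ravel()
    true = np.asarray(true, dtype=float).ravel()
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("pred and true must have equal nonzero length")
    return float(np.mean(np.abs(pred - true)))


def r_squared(pred: np.ndarray, true: np.ndarray,
              literal_ybar: bool = False) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot.

    By default ȳ is the mean of the reference (true) values, the
    convention under which R² = 1 iff the fit is perfect.  With
    ``literal_ybar=True`` ȳ is the mean of the predictions instead.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    true = np.asarray(true, dtype=float).ravel()
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("pred and true must have equal nonzero length")
    ybar = pred.mean() if literal_ybar else true.mean()
    ss_tot = np.sum((true - ybar) ** 2)
    if ss_tot == 0:
        raise ValueError("R² undefined: reference values have zero variance")
    return float(1.0 - np.sum((true - pred) ** 2) / ss_tot)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(model: _nn.Sequential,
          train_data: tuple[np.ndarray, np.ndarray],
          valid_data: tuple[np.ndarray, np.ndarray],
          config: TrainConfig,
          test_data: tuple[np.ndarray, np.ndarray] | None = None,
          ) -> tuple[_nn.Sequential, Metrics]:
    """Adam + RMSLE training with best-validation checkpointing.

    The output head's bias is initialized to the training-label mean so
    the ReLU head starts in its active regime.  Batches of size 1 are
    skipped (batch statistics are undefined there).  Returns the model
    with the checkpointed weights restored, plus loss histories and —
    when test data is given — test MAE and R².
    """
    x_tr, y_tr = (np.asarray(a, dtype=float) for a in train_data)
    x_va, y_va = (np.asarray(a, dtype=float) for a in valid_data)
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("train and validation sets must be nonempty")
    rng = np.random.default_rng(config.seed)

    # warm-start the scalar head at the label mean
    head = [l for l in model.layers if isinstance(l, _nn.Dense)][-1]
    if np.all(head.b == 0):
        head.b[...] = float(np.mean(y_tr))

    opt = _nn.Adam(model.params, lr=config.initial_lr)
    best_state = model.get_state()
    best_val = math.inf
    metrics = Metrics(mae=math.nan, r2=math.nan)

    no_improve = 0
    for epoch in range(config.max_epochs):
        opt.lr = lr_schedule(config.initial_lr, config.decay_k, epoch)
        order = rng.permutation(len(x_tr))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            if len(idx) < 2:
                continue
            xb, yb = x_tr[idx], y_tr[idx]
            pred = model.forward(xb, training=True, rng=rng)
            loss, dpred = _rmsle_grad(pred, yb)
            if not math.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"lr={opt.lr:g}, batch of {len(idx)}"
                )
            model.backward(dpred.reshape(pred.shape))
            opt.step(model.grads)
            losses.append(loss)
        val_loss = rmsle(model.predict(x_va), y_va)
        metrics.train_loss.append(float(np.mean(losses)) if losses
                                  else math.nan)
        metrics.valid_loss.append(val_loss)
        metrics.epochs_run = epoch + 1
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.get_state()
            metrics.best_epoch = epoch
            no_improve = 0
        else:
            no_improve += 1
            if no_improve >= config.patience:
                break

    model.set_state(best_state)
    if test_data is not None:
        x_te, y_te = (np.asarray(a, dtype=float) for a in test_data)
        pred = model.predict(x_te).ravel()
        metrics.mae = mae(pred, y_te)
        try:
            metrics.r2 = r_squared(pred, y_te)
        except ValueError:
            metrics.r2 = math.nan
    return model, metrics


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: _nn.Sequential, spec: ModelSpec, path: str,
                    config: TrainConfig | None = None,
                    metrics: Metrics | None = None) -> None:
    """Write weights (+BN statistics) as .npz with a JSON sidecar."""
    state = model.get_state()
    arrays = {f"w{i}": w for i, w in enumerate(state["weights"])}
    for i, (rm, rv) in enumerate(state["bn"]):
        arrays[f"bn_mean{i}"] = rm
        arrays[f"bn_var{i}"] = rv
    np.savez(path, n_weights=len(state["weights"]),
             n_bn=len(state["bn"]), **arrays)
    sidecar = {"spec": asdict(spec)}
    if config is not None:
        sidecar["config"] = asdict(config)
    if metrics is not None:
        sidecar["metrics"] = {"mae": metrics.mae, "r2": metrics.r2,
                              "best_epoch": metrics.best_epoch,
                              "epochs_run": metrics.epochs_run}
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_checkpoint(path: str) -> tuple[_nn.Sequential, ModelSpec]:
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as fh:
        sidecar = json.load(fh)
    sd = sidecar["spec"]
    for key in ("input_shape", "fc_units", "conv_kernel"):
        sd[key] = tuple(sd[key])
    sd["pool_sizes"] = tuple(tuple(p) for p in sd["pool_sizes"])
    spec = ModelSpec(**sd)
    model = build_model(spec)
    npz_path = path if path.endswith(".npz") else path + ".npz"
    with np.load(npz_path) as data:
        state = {
            "weights": [data[f"w{i}"] for i in range(int(data["n_weights"]))],
            "bn": [(data[f"bn_mean{i}"], data[f"bn_var{i}"])
                   for i in range(int(data["n_bn"]))],
        }
    model.set_state(state)
    return model, spec
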