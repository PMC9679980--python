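"""The residual convolutional thermal-trait regressor.

Architecture (fixed topology, parameterized widths):

    one-hot input (L_max x 20)
      -> entry convolution (f filters, kernel s_conv, same padding) -> BN -> ReLU
      -> n_blocks residual blocks (Conv-BN-ReLU-Conv-BN + identity skip, ReLU)
      -> max-pool (pool p, stride w, valid padding)
      -> flatten                       <- the learned sequence representation
      -> dropout -> dense(d0) -> BN -> ReLU -> dropout
      -> dense(1, linear)              <- predicted temperature in deg C

Everything before the flatten layer acts as a feature extractor; the dense
head is a regressor on top of it. The flatten width is
``f * (floor((L_max - p) / w) + 1)``; with the default configuration
(L_max=2000, one block of 512 filters, pool 50 / stride 50) this is 20,480.

Transfer-learning modes control which weight groups train during
fine-tuning: ``from_scratch`` (re-initialize everything), ``frozen_all``
(nothing trains), ``frozen_cnn`` (only the dense head trains; the frozen
extractor — including batch-norm statistics — stays bitwise identical), and
``tune_all`` (everything trains from the pretrained weights).
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass
from enum import Enum
from pathlib import Path

import numpy as np

from . import nn
from .datasets import LabeledSet
from .records import ProteinRecord
from .seqio import encode_batch

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TransferMode",
    "ModelState",
    "build",
    "flatten_dim",
    "train",
    "set_transfer_mode",
    "predict",
    "extract_representation",
    "save_model",
    "load_model",
]


@dataclass
class ModelConfig:
    """Architecture parameterization.

    ``dense_sizes`` lists the hidden fully-connected widths; the final
    linear output of width 1 is implied.
    """

    input_length: int = 2000
    n_blocks: int = 1
    filters: int = 512
    kernel_size: int = 5
    pool_size: int = 50
    pool_stride: int = 50
    dense_sizes: tuple[int, ...] = (128,)
    dropout: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if not 1 <= self.n_blocks <= 3:
            raise ValueError(f"n_blocks must be in [1, 3], got {self.n_blocks}")
        if self.pool_size > self.input_length:
            raise ValueError(
                f"pool size {self.pool_size} exceeds input length {self.input_length}"
            )
        if self.pool_stride < 1 or self.kernel_size < 1 or self.filters < 1:
            raise ValueError("pool_stride, kernel_size and filters must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if not self.dense_sizes:
            raise ValueError("dense_sizes must list at least one hidden width")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 50
    validation_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("learning_rate, batch_size, epochs must be positive")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")


class TransferMode(str, Enum):
    FROM_SCRATCH = "from_scratch"
    FROZEN_ALL = "frozen_all"
    FROZEN_CNN = "frozen_cnn"
    TUNE_ALL = "tune_all"


def flatten_dim(config: ModelConfig) -> int:
    """Closed-form width of the flatten-layer representation."""
    config.validate()
    pooled = (config.input_length - config.pool_size) // config.pool_stride + 1
    return config.filters * pooled


class ModelState:
    """A built network: ordered, tagged weight groups plus the layer stack."""

    PRE, POST = "pre_flatten", "post_flatten"

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        f, k = config.filters, config.kernel_size
        groups: list[tuple[str, str, nn.Layer]] = []

        groups.append(("entry_conv", self.PRE, nn.Conv1DSame(20, f, k, rng)))
        groups.append(("entry_bn", self.PRE, nn.BatchNorm(f)))
        groups.append(("entry_relu", self.PRE, nn.ReLU()))
        for i in range(config.n_blocks):
            groups.append((f"block{i + 1}", self.PRE, nn.ResidualBlock(f, k, rng)))
        groups.append(("pool", self.PRE, nn.MaxPool1D(config.pool_size, config.pool_stride)))
        groups.append(("flatten", self.PRE, nn.Flatten()))

        width = flatten_dim(config)
        groups.append(("drop0", self.POST, nn.Dropout(config.dropout)))
        prev = width
        for j, d in enumerate(config.dense_sizes, start=1):
            groups.append((f"dense{j}", self.POST, nn.Dense(prev, d, rng)))
            groups.append((f"dense{j}_bn", self.POST, nn.BatchNorm(d)))
            groups.append((f"dense{j}_relu", self.POST, nn.ReLU()))
            groups.append((f"drop{j}", self.POST, nn.Dropout(config.dropout)))
            prev = d
        groups.append(("output", self.POST, nn.Dense(prev, 1, rng)))

        self._groups = groups
        self._flatten_index = next(
            i for i, (name, _, _) in enumerate(groups) if name == "flatten"
        )

    # -- introspection -----------------------------------------------------
    def weight_groups(self) -> dict[str, dict]:
        """Name -> {tag, trainable, arrays} for every parameterized group."""
        out = {}
        for name, tag, layer in self._groups:
            params = layer.params()
            if params:
                out[name] = {
                    "tag": tag,
                    "trainable": layer.trainable,
                    "arrays": [p.value for p in params],
                    "buffers": layer.buffers(),
                }
        return out

    def trainable_params(self) -> list[nn.Param]:
        out = []
        for _, _, layer in self._groups:
            if layer.trainable:
                out.extend(layer.params())
        return out

    def set_trainable(self, tag_flags: dict[str, bool]) -> None:
        for _, tag, layer in self._groups:
            layer.trainable = tag_flags[tag]

    # -- forward passes ----------------------------------------------------
    def _forward(self, x: np.ndarray, training: bool,
                 rng: np.random.Generator | None = None,
                 stop_after_flatten: bool = False) -> np.ndarray:
        h = x
        for i, (_, _, layer) in enumerate(self._groups):
            h = layer.forward(h, training, rng)
            if stop_after_flatten and i == self._flatten_index:
                return h
        return h

    def _backward(self, dy: np.ndarray) -> None:
        d = dy
        for _, _, layer in reversed(self._groups):
            d = layer.backward(d)

    def predict(self, records: list[ProteinRecord], batch_size: int = 256) -> np.ndarray:
        """Inference-mode predictions (°C), one per record.

        A pure function of (weights, input): batch statistics are never used,
        so predictions are independent of batch composition and order.
        """
        out = np.empty(len(records), dtype=np.float64)
        for lo in range(0, len(records), batch_size):
            chunk = records[lo : lo + batch_size]
            x = encode_batch(chunk, self.config.input_length)
            out[lo : lo + len(chunk)] = self._forward(x, training=False)[:, 0]
        return out

    def representations(self, records: list[ProteinRecord], batch_size: int = 256) -> np.ndarray:
        """Flatten-layer activations, ``n x flatten_dim``."""
        width = flatten_dim(self.config)
        out = np.empty((len(records), width), dtype=np.float32)
        for lo in range(0, len(records), batch_size):
            chunk = records[lo : lo + batch_size]
            x = encode_batch(chunk, self.config.input_length)
            out[lo : lo + len(chunk)] = self._forward(
                x, training=False, stop_after_flatten=True
            )
        return out

    def clone(self) -> "ModelState":
        return copy.deepcopy(self)


def build(config: ModelConfig) -> ModelState:
    """Construct the network with seeded scaled-uniform initialization."""
    return ModelState(config)


def train(
    model: ModelState, data: LabeledSet, tc: TrainConfig
) -> tuple[ModelState, list[dict[str, float]]]:
    """Adam / mean-squared-error training of all trainable weight groups.

    Returns a new :class:`ModelState` (the input model is left untouched)
    and a per-epoch history ``[{"epoch", "train_loss", "val_loss"}, ...]``
    (``val_loss`` is NaN when ``validation_fraction`` is 0).
    """
    tc.validate()
    if len(data) == 0:
        raise ValueError("cannot train on an empty set")
    state = model.clone()
    L_max = state.config.input_length
    for r in data.records:
        if len(r.sequence) > L_max:
            raise ValueError(
                f"record {r.id!r}: length {len(r.sequence)} exceeds input length {L_max}"
            )
    X = encode_batch(data.records, L_max)
    y = data.labels.astype(np.float32)

    rng = np.random.default_rng(tc.seed)
    n = len(data)
    n_val = int(np.floor(tc.validation_fraction * n))
    order = rng.permutation(n)
    val_idx, tr_idx = order[:n_val], order[n_val:]
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    # Warm-start the output bias at the training-label mean so optimization
    # spends its budget on sequence-dependent structure rather than on
    # climbing a large constant offset. Skipped when the head is frozen.
    out_layer = state._groups[-1][2]
    if out_layer.trainable and len(ytr):
        out_layer.b.value[...] = np.float32(ytr.mean())

    opt = nn.Adam(state.trainable_params(), lr=tc.learning_rate)
    history: list[dict[str, float]] = []
    for epoch in range(1, tc.epochs + 1):
        perm = rng.permutation(len(Xtr))
        losses = []
        for lo in range(0, len(Xtr), tc.batch_size):
            idx = perm[lo : lo + tc.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            opt.zero_grad()
            pred = state._forward(xb, training=True, rng=rng)[:, 0]
            err = pred - yb
            losses.append(float(np.mean(err**2)))
            dy = (2.0 / len(yb)) * err.astype(np.float32)
            state._backward(dy[:, None])
            opt.step()
        val_loss = float("nan")
        if n_val:
            vpred = state._forward(Xval, training=False)[:, 0]
            val_loss = float(np.mean((vpred - yval) ** 2))
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_loss": val_loss}
        )
    return state, history


def set_transfer_mode(model: ModelState, mode: TransferMode | str) -> ModelState:
    """Return a copy of the model prepared for the given transfer mode."""
    mode = TransferMode(mode)
    if mode is TransferMode.FROM_SCRATCH:
        return build(model.config)  # fresh seeded initialization, all trainable
    state = model.clone()
    if mode is TransferMode.FROZEN_ALL:
        state.set_trainable({ModelState.PRE: False, ModelState.POST: False})
    elif mode is TransferMode.FROZEN_CNN:
        state.set_trainable({ModelState.PRE: False, ModelState.POST: True})
    else:  # TUNE_ALL
        state.set_trainable({ModelState.PRE: True, ModelState.POST: True})
    return state


def predict(model: ModelState, records: list[ProteinRecord]) -> np.ndarray:
    return model.predict(records)


def extract_representation(model: ModelState, records: list[ProteinRecord]) -> np.ndarray:
    return model.representations(records)


# -- serialization ---------------------------------------------------------

def save_model(model: ModelState, path: str | Path) -> None:
    """Save weights as an .npz plus a sidecar JSON of the configuration."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for name, info in model.weight_groups().items():
        for i, arr in enumerate(info["arrays"]):
            arrays[f"{name}/param{i}"] = arr
        for i, buf in enumerate(info["buffers"]):
            arrays[f"{name}/buffer{i}"] = buf
    np.savez(path, **arrays)
    cfg_path = path.with_suffix(path.suffix + ".json")
    cfg = asdict(model.config)
    cfg["dense_sizes"] = list(model.config.dense_sizes)
    cfg_path.write_text(json.dumps(cfg, indent=2))


def load_model(path: str | Path) -> ModelState:
    path = Path(path)
    cfg = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    cfg["dense_sizes"] = tuple(cfg["dense_sizes"])
    model = build(ModelConfig(**cfg))
    with np.load(path) as data:
        for name, info in model.weight_groups().items():
            for i, arr in enumerate(info["arrays"]):
                arr[...] = data[f"{name}/param{i}"]
            for i, buf in enumerate(info["buffers"]):
                buf[...] = data[f"{name}/buffer{i}"]
    return model
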