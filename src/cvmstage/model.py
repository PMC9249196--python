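"""The CNNDF: a small residual CNN whose first convolution is a tunable
directional-filter layer.

The network ingests a single-channel 77x35 region of interest.  Its first
convolution holds the eight directional edge kernels as initial weights
(updated by backpropagation like any other layer), followed by a depthwise
"match" convolution initialised as a centred identity so the initial forward
pass is pure directional filtering, and a leaky ReLU.  A parallel 1x1
convolution + batch norm taken straight from the input is added to that
path.  Four [max-pool -> skip-connection block] stages with 32/64/128/256
filters follow, then Flatten -> Dense(64) -> BN -> ReLU -> Dense(softmax).

Each skip-connection block is:  3x3 conv -> BN -> ReLU -> dropout on the
main path, 1x1 conv -> BN on the shortcut, then an elementwise add.

Pooling is 2x2 stride 2 in ceil mode, giving the spatial ladder
77x35 -> 39x18 -> 20x9 -> 10x5 -> 5x3, so the flattened feature length is
5*3*256 = 3840.  The default model has well under 715k parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import nn
from .filters import DirectionalFilterBank, build_bank

__all__ = [
    "ModelConfig", "TrainConfig", "NetworkSpec", "CNNDF",
    "build_cnndf", "count_parameters", "predict", "train_cnndf",
    "save_model", "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    num_classes: int = 5
    input_shape: tuple[int, int, int] = (77, 35, 1)
    directional_support: int = 9
    dropout_rate: float = 0.2
    leaky_slope: float = 0.1
    seed: int = 0
    random_init: bool = False   # ablation: random instead of directional init

    def __post_init__(self) -> None:
        if self.num_classes not in (5, 6):
            raise ValueError("num_classes must be 5 or 6")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.directional_support not in (9, 7):
            raise ValueError("directional_support must be 9 or 7")


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")


@dataclass(frozen=True)
class LayerSpec:
    name: str
    type: str
    kernel: Optional[tuple[int, int]]
    filters: Optional[int]
    output_shape: tuple[int, ...]
    connected_to: tuple[str, ...]
    params: int


@dataclass(frozen=True)
class NetworkSpec:
    layers: tuple[LayerSpec, ...]
    total_params: int
    trainable_params: int
    non_trainable_params: int

    def shape_of(self, name: str) -> tuple[int, ...]:
        for layer in self.layers:
            if layer.name == name:
                return layer.output_shape
        raise KeyError(name)

    def to_json(self) -> str:
        return json.dumps(
            {"layers": [asdict(l) for l in self.layers],
             "total_params": self.total_params,
             "trainable_params": self.trainable_params,
             "non_trainable_params": self.non_trainable_params},
            indent=1)


_BLOCK_FILTERS = (32, 64, 128, 256)


class _SkipBlock:
    """3x3 conv -> BN -> ReLU -> dropout, added to 1x1 conv -> BN."""

    def __init__(self, in_ch: int, out_ch: int, dropout: float,
                 rng: np.random.Generator, name: str) -> None:
        self.conv = nn.Conv2D(in_ch, out_ch, 3, rng, name=f"{name}.conv")
        self.bn = nn.BatchNorm(out_ch, ndim=4, name=f"{name}.bn")
        self.relu = nn.ReLU()
        self.drop = nn.Dropout(dropout)
        self.conv_skip = nn.Conv2D(in_ch, out_ch, 1, rng, name=f"{name}.conv_skip")
        self.bn_skip = nn.BatchNorm(out_ch, ndim=4, name=f"{name}.bn_skip")

    def params(self) -> list[nn.Param]:
        return (self.conv.params() + self.bn.params()
                + self.conv_skip.params() + self.bn_skip.params())

    def bns(self) -> list[nn.BatchNorm]:
        return [self.bn, self.bn_skip]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        t = self.drop.forward(
            self.relu.forward(
                self.bn.forward(self.conv.forward(x), training)), training)
        s = self.bn_skip.forward(self.conv_skip.forward(x), training)
        return t + s

    def backward(self, dy: np.ndarray) -> np.ndarray:
        ds = self.conv_skip.backward(self.bn_skip.backward(dy))
        dt = self.conv.backward(
            self.bn.backward(self.relu.backward(self.drop.backward(dy))))
        return dt + ds


class CNNDF:
    """Residual staging CNN with a tunable directional-filter first layer."""

    def __init__(self, cfg: ModelConfig,
                 bank: Optional[DirectionalFilterBank] = None) -> None:
        if bank is None:
            bank = build_bank(support=cfg.directional_support)
        if len(bank) != 8:
            raise ValueError("the directional bank must contain 8 kernels")
        self.cfg = cfg
        self.bank = bank
        rng = np.random.default_rng(cfg.seed)

        s = bank.support[0]
        self.directional = nn.Conv2D(1, 8, s, rng, pad_mode="symmetric",
                                     name="directional")
        if cfg.random_init:
            pass  # keep the He initialisation drawn above
        else:
            stack = bank.as_stack(np.float32)          # (8, S, S)
            self.directional.W.val = np.ascontiguousarray(
                stack.transpose(1, 2, 0)[:, :, None, :])
        self.match = nn.DepthwiseConv2D(8, 7, rng, pad_mode="symmetric",
                                        name="match")
        delta = np.zeros((7, 7, 8), dtype=np.float32)
        delta[3, 3, :] = 1.0
        self.match.W.val = delta
        self.dir_act = nn.LeakyReLU(cfg.leaky_slope)
        self.conv0 = nn.Conv2D(1, 8, 1, rng, name="conv_0")
        self.bn0 = nn.BatchNorm(8, ndim=4, name="batch_0")

        self.pools = [nn.MaxPool2x2Ceil() for _ in _BLOCK_FILTERS]
        self.blocks = []
        in_ch = 8
        for i, f in enumerate(_BLOCK_FILTERS, start=1):
            self.blocks.append(
                _SkipBlock(in_ch, f, cfg.dropout_rate, rng, f"skip_con_{i}"))
            in_ch = f

        self.flatten = nn.Flatten()
        h, w = self.cfg.input_shape[:2]
        for _ in _BLOCK_FILTERS:
            h, w = -(-h // 2), -(-w // 2)
        self._flat_len = h * w * _BLOCK_FILTERS[-1]
        self.dense1 = nn.Dense(self._flat_len, 64, rng, name="dense_1")
        self.bn11 = nn.BatchNorm(64, ndim=2, name="batch_11")
        self.relu11 = nn.ReLU()
        self.dense_out = nn.Dense(64, cfg.num_classes, rng, name="output_dense")

    # -- parameter access ---------------------------------------------------

    def params(self) -> list[nn.Param]:
        out = (self.directional.params() + self.match.params()
               + self.conv0.params() + self.bn0.params())
        for b in self.blocks:
            out += b.params()
        out += self.dense1.params() + self.bn11.params() + self.dense_out.params()
        return out

    def batchnorms(self) -> list[nn.BatchNorm]:
        out = [self.bn0]
        for b in self.blocks:
            out += b.bns()
        out.append(self.bn11)
        return out

    def dropouts(self) -> list[nn.Dropout]:
        return [b.drop for b in self.blocks]

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """``x``: (N, 77, 35, 1) float32 -> logits (N, num_classes)."""
        d = self.dir_act.forward(
            self.match.forward(self.directional.forward(x)), training)
        s = self.bn0.forward(self.conv0.forward(x), training)
        a = d + s
        for pool, block in zip(self.pools, self.blocks):
            a = block.forward(pool.forward(a), training)
        z = self.relu11.forward(
            self.bn11.forward(self.dense1.forward(self.flatten.forward(a)),
                              training))
        return self.dense_out.forward(z)

    def backward(self, dlogits: np.ndarray) -> None:
        dz = self.dense_out.backward(dlogits)
        da = self.flatten.backward(
            self.dense1.backward(
                self.bn11.backward(self.relu11.backward(dz))))
        for pool, block in zip(reversed(self.pools), reversed(self.blocks)):
            da = pool.backward(block.backward(da))
        ds = self.conv0.backward(self.bn0.backward(da))
        dd = self.directional.backward(
            self.match.backward(self.dir_act.backward(da)))
        # input gradient (ds + dd) is discarded: x is data, not a parameter

    # -- inference ----------------------------------------------------------

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """``images``: (N, 77, 35) or (N, 77, 35, 1) in [0, 1] -> (N, C)."""
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[..., None]
        h, w = self.cfg.input_shape[:2]
        if x.shape[1:3] != (h, w):
            raise ValueError(f"expected {h}x{w} input, got {x.shape[1:3]}")
        out = np.empty((x.shape[0], self.cfg.num_classes))
        step = 64
        for i in range(0, x.shape[0], step):
            out[i:i + step] = nn.softmax(
                self.forward(x[i:i + step], training=False).astype(np.float64))
        return out

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Predicted stage labels (1-based); argmax ties go to the lower class."""
        return self.predict_proba(images).argmax(axis=1) + 1

    # -- introspection ------------------------------------------------------

    def spec(self) -> NetworkSpec:
        h, w = self.cfg.input_shape[:2]
        s = self.bank.support[0]
        layers: list[LayerSpec] = []

        def add(name, type_, kernel, filters, shape, connected, params):
            layers.append(LayerSpec(name, type_, kernel, filters, tuple(shape),
                                    tuple(connected), params))

        def n_params(layer_objs):
            return sum(p.size for obj in layer_objs for p in obj.params())

        add("Input", "input", None, None, (h, w, 1), (), 0)
        add("Directional", "conv", (s, s), 8, (h, w, 8), ("Input",),
            n_params([self.directional]))
        add("Match", "depthwise_conv", (7, 7), 8, (h, w, 8), ("Directional",),
            n_params([self.match]))
        add("Dir_Leaky_Relu", "leaky_relu", None, None, (h, w, 8), ("Match",), 0)
        add("Conv_0", "conv", (1, 1), 8, (h, w, 8), ("Input",),
            n_params([self.conv0]))
        add("Batch_0", "batch_norm", None, None, (h, w, 8), ("Conv_0",),
            n_params([self.bn0]) + 16)
        add("ADD_1", "add", None, None, (h, w, 8),
            ("Dir_Leaky_Relu", "Batch_0"), 0)
        prev = "ADD_1"
        ph, pw, ch = h, w, 8
        for i, (f, block) in enumerate(zip(_BLOCK_FILTERS, self.blocks), start=1):
            ph, pw = -(-ph // 2), -(-pw // 2)
            add(f"Max_{i}", "max_pooling2d", (2, 2), None, (ph, pw, ch), (prev,), 0)
            add(f"Skip_Con_{i}", "skip_connection", None, f, (ph, pw, f),
                (f"Max_{i}",), n_params([block]) + 4 * f)
            prev, ch = f"Skip_Con_{i}", f
        add("Flatten", "flatten", None, None, (ph * pw * ch,), (prev,), 0)
        add("Dense_1", "dense", None, 64, (64,), ("Flatten",),
            n_params([self.dense1]))
        add("Batch_11", "batch_norm", None, None, (64,), ("Dense_1",),
            n_params([self.bn11]) + 128)
        add("Relu_11", "relu", None, None, (64,), ("Batch_11",), 0)
        add("Output_Dense", "dense_softmax", None, self.cfg.num_classes,
            (self.cfg.num_classes,), ("Relu_11",), n_params([self.dense_out]))

        counts = count_parameters(self)
        return NetworkSpec(layers=tuple(layers),
                           total_params=counts["total"],
                           trainable_params=counts["trainable"],
                           non_trainable_params=counts["non_trainable"])


def build_cnndf(
    cfg: ModelConfig | None = None,
    bank: Optional[DirectionalFilterBank] = None,
) -> tuple[CNNDF, NetworkSpec]:
    """Construct the model and its auditable layer specification."""
    model = CNNDF(cfg or ModelConfig(), bank)
    return model, model.spec()


def count_parameters(model: CNNDF) -> dict[str, int]:
    """Trainable weights plus batch-norm running statistics, counted apart."""
    trainable = sum(p.size for p in model.params())
    non_trainable = sum(b.size for bn in model.batchnorms() for b in bn.buffers())
    return {"trainable": trainable, "non_trainable": non_trainable,
            "total": trainable + non_trainable}


def predict(model: CNNDF, pixels: np.ndarray) -> np.ndarray:
    """Class-probability vector(s) for 77x35 grayscale input(s)."""
    single = np.asarray(pixels).ndim == 2
    probs = model.predict_proba(pixels)
    return probs[0] if single else probs


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train_cnndf(
    model: CNNDF,
    images: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig | None = None,
    val_images: Optional[np.ndarray] = None,
    val_labels: Optional[np.ndarray] = None,
    verbose: bool = False,
) -> dict[str, list[float]]:
    """Train with Adam on categorical cross-entropy; returns per-epoch history.

    ``labels`` are 1-based stage labels.  The directional layer trains along
    with everything else, so its weights drift from the bank initialisation
    after the first step.  Runs with the same ``cfg.seed`` are bit-identical.
    """
    cfg = cfg or TrainConfig()
    if cfg.optimizer.lower() != "adam":
        raise ValueError("only the adam optimizer is implemented")
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[..., None]
    y = np.asarray(labels, dtype=np.int64) - 1
    if x.shape[0] == 0:
        raise ValueError("empty training set")
    if y.min() < 0 or y.max() >= model.cfg.num_classes:
        raise ValueError("label out of range for num_classes")

    rng = np.random.default_rng(cfg.seed)
    for i, drop in enumerate(model.dropouts()):
        drop.rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, i + 1]))

    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    history: dict[str, list[float]] = {
        "epoch": [], "train_loss": [], "train_acc": [],
        "val_loss": [], "val_acc": [],
    }
    n = x.shape[0]
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            logits = model.forward(x[idx], training=True)
            loss, dlogits, probs = nn.softmax_cross_entropy(logits, y[idx])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
            correct += int((probs.argmax(axis=1) == y[idx]).sum())
        history["epoch"].append(epoch + 1)
        history["train_loss"].append(sum(losses) / n)
        history["train_acc"].append(correct / n)
        if val_images is not None:
            vprobs = model.predict_proba(val_images)
            vy = np.asarray(val_labels, dtype=np.int64) - 1
            vloss = -np.log(vprobs[np.arange(len(vy)), vy] + 1e-12).mean()
            history["val_loss"].append(float(vloss))
            history["val_acc"].append(float((vprobs.argmax(1) == vy).mean()))
        else:
            history["val_loss"].append(float("nan"))
            history["val_acc"].append(float("nan"))
        if verbose:
            print(f"epoch {epoch + 1:3d}  loss {history['train_loss'][-1]:.4f}"
                  f"  acc {history['train_acc'][-1]:.3f}"
                  f"  val_acc {history['val_acc'][-1]:.3f}")
    return history


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_model(model: CNNDF, path: Union[str, Path]) -> None:
    """Save weights, batch-norm statistics, config and the NetworkSpec."""
    arrays = {f"param_{i}": p.val for i, p in enumerate(model.params())}
    for i, bn in enumerate(model.batchnorms()):
        arrays[f"bn_{i}_mean"] = bn.running_mean
        arrays[f"bn_{i}_var"] = bn.running_var
    cfg_json = json.dumps(asdict(model.cfg))
    spec_json = model.spec().to_json()
    np.savez(path, __config__=cfg_json, __spec__=spec_json, **arrays)


def load_model(path: Union[str, Path]) -> CNNDF:
    data = np.load(path, allow_pickle=False)
    cfg_d = json.loads(str(data["__config__"]))
    cfg_d["input_shape"] = tuple(cfg_d["input_shape"])
    model = CNNDF(ModelConfig(**cfg_d))
    for i, p in enumerate(model.params()):
        p.val[...] = data[f"param_{i}"]
    for i, bn in enumerate(model.batchnorms()):
        bn.running_mean[...] = data[f"bn_{i}_mean"]
        bn.running_var[...] = data[f"bn_{i}_var"]
    return model
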