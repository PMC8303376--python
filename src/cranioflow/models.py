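"""CranioNet, transfer-learning heads, and the training recipe.

CranioNet is a compact multilabel CNN: blocks of two 3x3 stride-1
convolutions (batch-normalised, ReLU) followed by a 3x3 stride-2 max
pool and 0.25 dropout; only the first block's convolutions are padded
(P=1).  The classifier is a hidden dense layer (ReLU, batch norm, 0.5
dropout) and a sigmoid output — one independent probability per label,
never normalised across labels.

Training minimises binary cross-entropy plus a weighted L1 norm of the
kernels, with Adam (first-moment decay 0.9, eps 1e-8), Xavier weight
initialisation and zero biases.  The from-scratch recipe uses learning
rate 1e-4, batch size 64, 20 epochs; transfer heads use 1e-5 and 10
epochs with the backbone frozen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _nn
from .dataset import AugmentConfig, augment, preprocess
from .labelspace import LabelVector, N_LABELS

__all__ = [
    "ConfigurationError",
    "CranioNetSpec",
    "TrainConfig",
    "BackboneAdapter",
    "RandomFrozenBackbone",
    "ToolDetector",
    "build_cranionet",
    "build_transfer_model",
    "spatial_trace",
    "train",
    "evaluate_exact_match",
    "save_model",
    "load_model",
]


class ConfigurationError(ValueError):
    """Raised when an architecture specification is internally inconsistent."""


@dataclass(frozen=True)
class CranioNetSpec:
    """Architecture of the from-scratch network.

    The block count, filter counts and hidden width are free choices: the
    defaults (three blocks of 32/64/128 filters, hidden width 512) are the
    shallowest standard doubling that keeps every valid-padded spatial
    size positive starting from 64x64.
    """

    input_size: int = 64
    filters: tuple[int, ...] = (32, 64, 128)
    hidden: int = 512
    conv_dropout: float = 0.25
    dense_dropout: float = 0.5
    n_labels: int = N_LABELS

    def __post_init__(self) -> None:
        if self.n_labels < 1 or not self.filters:
            raise ConfigurationError("need at least one block and one label")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation recipe for :func:`train`."""

    learning_rate: float = 1e-4
    lr_decay: float = 1.0  # per-epoch multiplicative decay (1.0 = constant)
    lr_decay_start: int = 0  # first epoch (0-based) at which decay applies
    l1_weight: float = 1e-5
    batch_size: int = 64
    epochs: int = 20
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0
    augment: AugmentConfig | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("invalid training configuration")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("lr_decay must lie in (0, 1]")
        if self.lr_decay_start < 0:
            raise ValueError("lr_decay_start must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        aug = d.pop("augment", None)
        if isinstance(aug, dict):
            aug = AugmentConfig.from_dict(aug)
        return cls(augment=aug, **d)

    @classmethod
    def from_yaml(cls, text: str) -> "TrainConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(text) or {})

    @classmethod
    def scratch(cls, **kw) -> "TrainConfig":
        return cls(**kw)

    @classmethod
    def transfer(cls, **kw) -> "TrainConfig":
        kw.setdefault("learning_rate", 1e-5)
        kw.setdefault("epochs", 10)
        return cls(**kw)


def spatial_trace(spec: CranioNetSpec) -> list[tuple[str, int]]:
    """Spatial size after every convolution/pool stage.

    Raises :class:`ConfigurationError` naming the first stage at which the
    feature map would collapse below 1x1.
    """
    trace: list[tuple[str, int]] = []
    size = spec.input_size
    for b, _ in enumerate(spec.filters):
        pad = 1 if b == 0 else 0
        for c in range(2):
            size = _nn.conv_out_size(size, 3, 1, pad)
            stage = f"block{b + 1}/conv{c + 1}"
            if size < 1:
                raise ConfigurationError(f"spatial collapse at {stage}")
            trace.append((stage, size))
        size = _nn.pool_out_size(size, 3, 2)
        stage = f"block{b + 1}/pool"
        if size < 1:
            raise ConfigurationError(f"spatial collapse at {stage}")
        trace.append((stage, size))
    return trace


class ToolDetector:
    """A trained (or trainable) multilabel frame classifier.

    Accepts NHWC float batches in [0, 1] (as produced by
    :func:`cranioflow.dataset.preprocess`) and returns per-label sigmoid
    probabilities.  ``descriptor`` is a JSON-serialisable architecture
    summary used when checkpointing.
    """

    def __init__(self, net: _nn.Sequential, descriptor: dict) -> None:
        self.net = net
        self.descriptor = descriptor
        self.input_size = int(descriptor.get("input_size", 64))

    def _to_nchw(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[-1] != 3:
            raise ValueError(f"expected an NHWC batch with 3 channels, got {x.shape}")
        return x.transpose(0, 3, 1, 2)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(self._to_nchw(x), train=train)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.predict(x)

    def num_params(self) -> int:
        return self.net.num_params()

    def parameter_report(self) -> str:
        lines = []
        for i, layer in enumerate(self.net.layers):
            n = layer.num_params() if layer.trainable else 0
            lines.append(f"{i:2d}  {type(layer).__name__:<14s} {n:>10,d}")
        lines.append(f"trainable parameters: {self.num_params():,d}")
        return "\n".join(lines)


def build_cranionet(spec: CranioNetSpec | None = None, seed: int = 0) -> ToolDetector:
    """Build CranioNet per ``spec`` with seeded Xavier initialisation."""
    spec = spec or CranioNetSpec()
    spatial_trace(spec)  # validates before any allocation
    ss = np.random.SeedSequence(seed)
    init_rng = np.random.default_rng(ss.spawn(1)[0])
    drop_seeds = np.random.SeedSequence(seed + 1).spawn(len(spec.filters) + 1)

    layers: list[_nn.Layer] = []
    cin = 3
    size = spec.input_size
    for b, cout in enumerate(spec.filters):
        pad = 1 if b == 0 else 0
        for _ in range(2):
            layers += [
                _nn.Conv2d(cin, cout, 3, 1, pad, rng=init_rng),
                _nn.BatchNorm2d(cout),
                _nn.ReLU(),
            ]
            cin = cout
            size = _nn.conv_out_size(size, 3, 1, pad)
        layers.append(_nn.MaxPool2d(3, 2))
        size = _nn.pool_out_size(size, 3, 2)
        layers.append(_nn.Dropout(spec.conv_dropout, rng=np.random.default_rng(drop_seeds[b])))
    layers += [
        _nn.Flatten(),
        _nn.Dense(cin * size * size, spec.hidden, rng=init_rng),
        _nn.ReLU(),
        _nn.BatchNorm1d(spec.hidden),
        _nn.Dropout(spec.dense_dropout, rng=np.random.default_rng(drop_seeds[-1])),
        _nn.Dense(spec.hidden, spec.n_labels, rng=init_rng),
        _nn.Sigmoid(),
    ]
    descriptor = {
        "kind": "cranionet",
        "input_size": spec.input_size,
        "filters": list(spec.filters),
        "hidden": spec.hidden,
        "conv_dropout": spec.conv_dropout,
        "dense_dropout": spec.dense_dropout,
        "n_labels": spec.n_labels,
        "seed": seed,
    }
    return ToolDetector(_nn.Sequential(layers), descriptor)


class BackboneAdapter:
    """A frozen feature extractor mapping an NCHW batch to a feature map.

    Subclasses implement :meth:`features`; parameters never update during
    training (``frozen`` is always True).
    """

    frozen = True
    out_channels: int

    def features(self, x_nchw: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class RandomFrozenBackbone(BackboneAdapter):
    """A seeded random convolutional feature extractor.

    Serves as a stand-in backbone for exercising the transfer-learning
    path without downloading pretrained weights: random convolutional
    features are fixed, so only the head learns.
    """

    def __init__(self, channels: tuple[int, ...] = (16, 32), seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self._convs: list[_nn.Conv2d] = []
        cin = 3
        for cout in channels:
            conv = _nn.Conv2d(cin, cout, 3, stride=1, pad=1, rng=rng)
            conv.trainable = False
            self._convs.append(conv)
            cin = cout
        self.out_channels = cin
        self._pool = _nn.MaxPool2d(2, 2)

    def features(self, x_nchw: np.ndarray) -> np.ndarray:
        out = np.asarray(x_nchw, dtype=np.float32)
        for conv in self._convs:
            out = np.maximum(conv.forward(out, train=False), 0.0)
            out = self._pool.forward(out, train=False)
        return out

    def state(self) -> list[np.ndarray]:
        return [c.params["W"].copy() for c in self._convs]


class _BackboneLayer(_nn.Layer):
    """Wraps a frozen backbone as a non-trainable first layer."""

    trainable = False

    def __init__(self, backbone: BackboneAdapter) -> None:
        super().__init__()
        self.backbone = backbone

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = self.backbone.features(x)
        if out.ndim != 4:
            raise ConfigurationError(
                f"backbone must emit a spatial (N,C,H,W) feature map, got ndim={out.ndim}"
            )
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout  # gradients stop at the frozen backbone


def build_transfer_model(
    backbone: BackboneAdapter, n_labels: int = N_LABELS, seed: int = 0
) -> ToolDetector:
    """Frozen backbone + global average pooling + 0.5 dropout + sigmoid head.

    Only the head's dense layer is trainable: C backbone channels and L
    labels add exactly C*L + L parameters.
    """
    rng = np.random.default_rng(seed)
    layers: list[_nn.Layer] = [
        _BackboneLayer(backbone),
        _nn.GlobalAvgPool(),
        _nn.Dropout(0.5, rng=np.random.default_rng(seed + 1)),
        _nn.Dense(backbone.out_channels, n_labels, rng=rng),
        _nn.Sigmoid(),
    ]
    descriptor = {
        "kind": "transfer",
        "out_channels": backbone.out_channels,
        "n_labels": n_labels,
        "seed": seed,
    }
    return ToolDetector(_nn.Sequential(layers), descriptor)


def _as_xy(items, augment_cfg: AugmentConfig | None, rng: np.random.Generator | None,
           size: int = 64):
    xs, ys = [], []
    for image, label in items:
        img = preprocess(image, size=size)
        if augment_cfg is not None and rng is not None:
            img = augment(img, augment_cfg, rng)
        xs.append(img)
        ys.append(label.to_array() if isinstance(label, LabelVector) else np.asarray(label))
    return np.stack(xs), np.stack(ys).astype(np.float32)


def _eval_loss(model: ToolDetector, items, batch_size: int) -> float:
    total, count = 0.0, 0
    for i in range(0, len(items), batch_size):
        x, y = _as_xy(items[i : i + batch_size], None, None, size=model.input_size)
        probs = model.forward(x, train=False)
        loss, _ = _nn.bce_loss(probs, y)
        total += loss * len(x)
        count += len(x)
    return total / max(count, 1)


def train(
    model: ToolDetector,
    train_set,
    validation_set=None,
    cfg: TrainConfig | None = None,
) -> tuple[ToolDetector, dict[str, list[float]]]:
    """Train ``model`` and return it with per-epoch loss history.

    ``train_set``/``validation_set`` are sequences of ``(image, label)``
    pairs; images are preprocessed (and, if configured, augmented on the
    fly) every epoch.  Validation loss is computed without augmentation.
    The run is fully reproducible given ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    if not train_set:
        raise ValueError("train_set must be non-empty")
    opt = _nn.Adam(model.net.layers, lr=cfg.learning_rate, beta1=cfg.beta1,
                   beta2=cfg.beta2, eps=cfg.eps)
    shuffle_rng = np.random.default_rng(cfg.seed)
    aug_rng = np.random.default_rng(cfg.seed + 1)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}

    for epoch in range(cfg.epochs):
        opt.lr = cfg.learning_rate * cfg.lr_decay ** max(0, epoch - cfg.lr_decay_start)
        order = shuffle_rng.permutation(len(train_set))
        total, count = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            batch = [train_set[j] for j in order[i : i + cfg.batch_size]]
            x, y = _as_xy(batch, cfg.augment, aug_rng, size=model.input_size)
            probs = model.forward(x, train=True)
            loss, dprobs = _nn.bce_loss(probs, y)
            loss += _nn.l1_penalty(model.net, cfg.l1_weight)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch + 1}: {loss}"
                )
            model.net.backward(dprobs)
            _nn.apply_l1_grads(model.net, cfg.l1_weight)
            opt.step()
            total += loss * len(batch)
            count += len(batch)
        history["train_loss"].append(total / count)
        if validation_set:
            history["val_loss"].append(_eval_loss(model, validation_set, cfg.batch_size))
    return model, history


def evaluate_exact_match(model: ToolDetector, items, threshold: float = 0.5,
                         batch_size: int = 64) -> float:
    """Fraction of frames whose thresholded label set equals the truth exactly."""
    from .detector import threshold_detections

    correct, total = 0, 0
    for i in range(0, len(items), batch_size):
        batch = items[i : i + batch_size]
        x, y = _as_xy(batch, None, None, size=model.input_size)
        probs = model.predict(x)
        for p, truth in zip(probs, y):
            pred = threshold_detections(np.clip(p, 0, 1), threshold)
            true = LabelVector.from_array(truth).to_labels()
            correct += pred == true
            total += 1
    return correct / total


def save_model(model: ToolDetector, path: str | Path) -> None:
    """Checkpoint parameters (npz) plus a JSON architecture descriptor."""
    path = Path(path)
    flat: dict[str, np.ndarray] = {}
    for i, d in enumerate(model.net.state()):
        for k, v in d.items():
            flat[f"{i}:{k}"] = v
    np.savez(path.with_suffix(".npz"), **flat)
    path.with_suffix(".json").write_text(json.dumps(model.descriptor, indent=2))


def load_model(path: str | Path, backbone: BackboneAdapter | None = None) -> ToolDetector:
    path = Path(path)
    descriptor = json.loads(path.with_suffix(".json").read_text())
    if descriptor["kind"] == "cranionet":
        spec = CranioNetSpec(
            input_size=descriptor["input_size"],
            filters=tuple(descriptor["filters"]),
            hidden=descriptor["hidden"],
            conv_dropout=descriptor["conv_dropout"],
            dense_dropout=descriptor["dense_dropout"],
            n_labels=descriptor["n_labels"],
        )
        model = build_cranionet(spec, seed=descriptor.get("seed", 0))
    elif descriptor["kind"] == "transfer":
        if backbone is None:
            raise ValueError("loading a transfer checkpoint requires its backbone")
        model = build_transfer_model(backbone, descriptor["n_labels"],
                                     seed=descriptor.get("seed", 0))
    else:
        raise ValueError(f"unknown checkpoint kind {descriptor['kind']!r}")
    with np.load(path.with_suffix(".npz")) as data:
        state: list[dict[str, np.ndarray]] = [dict() for _ in model.net.layers]
        for key, value in data.items():
            idx, name = key.split(":", 1)
            state[int(idx)][name] = value
    for layer, d in zip(model.net.layers, state):
        if d:
            for k in layer.params:
                layer.params[k] = np.asarray(d[k], dtype=np.float32)
            if isinstance(layer, _nn._BatchNorm):
                layer.running_mean = np.asarray(d["running_mean"], dtype=np.float32)
                layer.running_var = np.asarray(d["running_var"], dtype=np.float32)
    return model
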