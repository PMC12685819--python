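"""The two architectures and their training entry points.

* :func:`build_cnn` — the 1-D CNN stress classifier: two convolutional blocks
  (64 then 128 filters, kernel 3, ReLU, L2), each followed by batch
  normalisation, max pooling and dropout 0.4, then global average pooling, a
  64-unit dense layer with dropout, and a softmax head.  Feature rows are
  consumed as a length-n, 1-channel sequence.
* :func:`fine_tune` — transfer learning: the backbone is initialised from a
  saved checkpoint, the classification head is rebuilt for the new label set,
  and training continues at a reduced learning rate with class weighting.
* :func:`build_conformer` — the Temporal Conformer valence/arousal/dominance
  regressor: a 32→64-filter convolutional stack with dropout, a position-wise
  dense projection, a stack of transformer encoder blocks (residual
  connections, layer norm, dropout, retrievable attention), a final layer
  norm and dropout, and a 3-output dense head trained with smooth-L1.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .io_formats import CheckpointBundle
from .nn import (
    BatchNorm1D, Conv1D, Dense, Dropout, Flatten, GlobalAvgPool1D, LayerNorm,
    MaxPool1D, Sequential, TrainConfig, TrainHistory, TransformerEncoderLayer,
    focal_loss_from_logits, smooth_l1_loss, softmax, softmax_cross_entropy,
    train_model,
)

__all__ = [
    "Cnn1dSpec", "ConformerSpec", "Model",
    "build_cnn", "build_conformer",
    "compute_class_weights",
    "train_classifier", "fine_tune", "train_vad_regressor",
    "accuracy",
]


@dataclass
class Cnn1dSpec:
    input_len: int
    input_channels: int = 1
    n_classes: int = 3
    filters1: int = 64
    filters2: int = 128
    kernel: int = 3
    pool_size: int = 2
    dropout: float = 0.4
    l2_coeff: float = 1e-4
    dense_units: int = 64

    def __post_init__(self) -> None:
        if self.kernel % 2 == 0:
            raise ValueError("kernel must be odd")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass
class ConformerSpec:
    input_len: int = 33
    input_channels: int = 1
    conv1_filters: int = 32
    conv2_filters: int = 64
    kernel: int = 3
    projection_dim: int = 64
    n_encoder_layers: int = 2
    n_heads: int = 4
    ffn_dim: int = 128
    dropout: float = 0.1
    output_dim: int = 3

    def __post_init__(self) -> None:
        if self.projection_dim % self.n_heads != 0:
            raise ValueError("projection_dim must be divisible by n_heads")
        if self.output_dim != 3:
            raise ValueError("output_dim must be 3 (valence, arousal, dominance)")


class Model:
    """A network plus its build spec; handles input shaping, prediction and
    checkpoint round-trips."""

    def __init__(self, network: Sequential, spec, kind: str):
        self.network = network
        self.spec = spec
        self.kind = kind

    # -- shaping ------------------------------------------------------------
    def _prep(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, :, None]
        elif x.ndim == 2:
            x = x[:, :, None]  # feature rows as a 1-channel sequence
        return x

    # -- inference ----------------------------------------------------------
    def forward(self, x, training: bool = False) -> np.ndarray:
        return self.network.forward(self._prep(x), training)

    def predict_logits(self, x) -> np.ndarray:
        return self.forward(x, training=False)

    def predict_proba(self, x) -> np.ndarray:
        return softmax(self.predict_logits(x))

    def predict(self, x) -> np.ndarray:
        out = self.predict_logits(x)
        if self.kind == "conformer":
            return out
        return out.argmax(axis=-1)

    def predict_batched(self, x, batch_size: int = 256) -> np.ndarray:
        x = self._prep(x)
        return np.concatenate([
            self.network.forward(x[i:i + batch_size], training=False)
            for i in range(0, x.shape[0], batch_size)
        ])

    def embeddings(self, x, layer: str = "gap", batch_size: int = 256) -> np.ndarray:
        """Activations at a named layer (default: the global-average-pooling
        embedding used for t-SNE)."""
        x = self._prep(x)
        outs = []
        for i in range(0, x.shape[0], batch_size):
            self.network.forward(x[i:i + batch_size], training=False)
            outs.append(self.network.outputs[layer])
        return np.concatenate(outs)

    # -- checkpointing -------------------------------------------------------
    def to_bundle(self, metadata: dict | None = None) -> CheckpointBundle:
        layers = []
        for lyr in self.network:
            layers.append({
                "name": lyr.name,
                "kind": type(lyr).__name__,
                "config": lyr.config(),
                "weights": {k: list(v.shape) for k, v in lyr.state_items().items()},
            })
        architecture = {"kind": self.kind, "spec": asdict(self.spec), "layers": layers}
        weights = {k: v.copy() for k, v in self.network.state_items().items()}
        return CheckpointBundle(architecture=architecture, weights=weights,
                                metadata=dict(metadata or {}))

    @classmethod
    def from_bundle(cls, bundle: CheckpointBundle, seed: int = 0) -> "Model":
        kind = bundle.architecture["kind"]
        spec_dict = bundle.architecture["spec"]
        if kind == "cnn1d":
            model = build_cnn(Cnn1dSpec(**spec_dict), seed=seed)
        elif kind == "conformer":
            model = build_conformer(ConformerSpec(**spec_dict), seed=seed)
        else:
            raise ValueError(f"unknown architecture kind {kind!r}")
        model.network.load_state(bundle.weights)
        return model


def build_cnn(spec: Cnn1dSpec, seed: int = 0) -> Model:
    """Assemble the 1-D CNN classifier; weight init is seeded."""
    if spec.input_len // spec.pool_size // spec.pool_size < 1:
        raise ValueError(
            f"input_len {spec.input_len} too short for two pools of {spec.pool_size}"
        )
    rng = np.random.default_rng(seed)
    layers = [
        Conv1D(spec.input_channels, spec.filters1, spec.kernel, activation="relu",
               l2=spec.l2_coeff, name="conv1", rng=rng),
        BatchNorm1D(spec.filters1, name="bn1"),
        MaxPool1D(spec.pool_size, name="pool1"),
        Dropout(spec.dropout, name="drop1"),
        Conv1D(spec.filters1, spec.filters2, spec.kernel, activation="relu",
               l2=spec.l2_coeff, name="conv2", rng=rng),
        BatchNorm1D(spec.filters2, name="bn2"),
        MaxPool1D(spec.pool_size, name="pool2"),
        Dropout(spec.dropout, name="drop2"),
        GlobalAvgPool1D(name="gap"),
        Dense(spec.filters2, spec.dense_units, activation="relu", name="dense",
              rng=rng),
        Dropout(spec.dropout, name="drop3"),
        Dense(spec.dense_units, spec.n_classes, name="head", rng=rng),
    ]
    return Model(Sequential(layers), spec, "cnn1d")


def build_conformer(spec: ConformerSpec, seed: int = 0) -> Model:
    """Assemble the Temporal Conformer regressor; weight init is seeded."""
    rng = np.random.default_rng(seed)
    layers = [
        Conv1D(spec.input_channels, spec.conv1_filters, spec.kernel,
               activation="relu", name="conv1", rng=rng),
        Dropout(spec.dropout, name="drop1"),
        Conv1D(spec.conv1_filters, spec.conv2_filters, spec.kernel,
               activation="relu", name="conv2", rng=rng),
        Dropout(spec.dropout, name="drop2"),
        Dense(spec.conv2_filters, spec.projection_dim, name="proj", rng=rng),
    ]
    for i in range(spec.n_encoder_layers):
        layers.append(TransformerEncoderLayer(
            spec.projection_dim, spec.n_heads, spec.ffn_dim,
            dropout=spec.dropout, name=f"enc{i}", rng=rng))
    layers += [
        LayerNorm(spec.projection_dim, name="ln_f"),
        Dropout(spec.dropout, name="drop_f"),
        Flatten(name="flatten"),
        Dense(spec.input_len * spec.projection_dim, spec.output_dim, name="out",
              rng=rng),
    ]
    return Model(Sequential(layers), spec, "conformer")


def compute_class_weights(labels) -> np.ndarray:
    """Balanced class weights w_c = n / (k · n_c), so Σ n_c·w_c = n."""
    labels = np.asarray(labels, dtype=int)
    k = int(labels.max()) + 1
    counts = np.bincount(labels, minlength=k)
    if np.any(counts == 0):
        empty = np.flatnonzero(counts == 0)
        raise ValueError(f"class(es) {empty.tolist()} have no samples")
    return labels.size / (k * counts.astype(float))


def accuracy(logits: np.ndarray, labels: np.ndarray) -> float:
    return float((logits.argmax(axis=-1) == np.asarray(labels)).mean())


def _classification_loss(config: TrainConfig):
    if config.loss == "focal":
        def loss_grad(logits, y):
            return focal_loss_from_logits(
                logits, y, gamma=config.focal_gamma, alpha=config.class_weights)
    elif config.loss == "sparse_ce":
        def loss_grad(logits, y):
            return softmax_cross_entropy(logits, y, class_weights=config.class_weights)
    else:
        raise ValueError(f"unknown classification loss {config.loss!r}")
    return loss_grad


def train_classifier(
    model: Model,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
) -> tuple[Model, TrainHistory]:
    """Train a classifier with early stopping, plateau scheduling and class
    weighting; returns the model at its best validation epoch."""
    x_tr = model._prep(train[0])
    x_va = model._prep(val[0])
    history = train_model(
        model, _classification_loss(config),
        (x_tr, np.asarray(train[1], dtype=int)),
        (x_va, np.asarray(val[1], dtype=int)),
        config, metric_fn=accuracy,
    )
    return model, history


def fine_tune(
    pretrained: CheckpointBundle,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    config: TrainConfig | None = None,
    *,
    n_classes: int,
    input_len: int | None = None,
    input_channels: int | None = None,
    seed: int = 0,
    freeze_backbone: bool = False,
) -> tuple[Model, TrainHistory]:
    """Transfer learning: load backbone weights from a checkpoint, rebuild the
    softmax head for ``n_classes``, then train at a reduced learning rate.

    The backbone (both convolutional blocks and the dense embedding layer) is
    loaded bitwise before any training step; the head is freshly initialised
    from ``seed``.  With ``freeze_backbone`` the convolutional blocks are
    excluded from optimisation.
    """
    if pretrained.architecture.get("kind") != "cnn1d":
        raise ValueError("fine_tune expects a cnn1d checkpoint")
    config = config or TrainConfig(lr=1e-4)
    old_spec = Cnn1dSpec(**pretrained.architecture["spec"])
    new_spec = Cnn1dSpec(**{
        **pretrained.architecture["spec"],
        "n_classes": n_classes,
        "input_len": input_len or old_spec.input_len,
        "input_channels": input_channels or old_spec.input_channels,
    })
    if new_spec.input_channels != old_spec.input_channels:
        raise ValueError(
            f"backbone expects {old_spec.input_channels} input channel(s), "
            f"got {new_spec.input_channels}"
        )
    model = build_cnn(new_spec, seed=seed)
    backbone = {k: v for k, v in pretrained.weights.items()
                if not k.startswith("head/")}
    model.network.load_state(backbone)
    if freeze_backbone:
        for name in ("conv1", "bn1", "conv2", "bn2"):
            model.network.get(name).trainable = False
    if config.class_weights is None:
        config.class_weights = compute_class_weights(train[1])
    return train_classifier(model, train, val, config)


def train_vad_regressor(
    model: Model,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    config: TrainConfig | None = None,
    *,
    beta: float = 1.0,
    normalized_targets: bool = True,
) -> tuple[Model, TrainHistory]:
    """Train the conformer with smooth-L1 (β = 1) and plateau scheduling."""
    config = config or TrainConfig(loss="smooth_l1")
    for name, (_, y) in (("train", train), ("val", val)):
        y = np.asarray(y, dtype=float)
        if normalized_targets and (y.min() < 0.0 or y.max() > 1.0):
            raise ValueError(f"{name} targets outside [0, 1] in normalized mode")

    def loss_grad(out, y):
        return smooth_l1_loss(out, y, beta=beta)

    def neg_mae(pred, y):
        return -float(np.abs(pred - y).mean())

    x_tr = model._prep(train[0])
    x_va = model._prep(val[0])
    history = train_model(
        model, loss_grad,
        (x_tr, np.asarray(train[1], dtype=float)),
        (x_va, np.asarray(val[1], dtype=float)),
        config, metric_fn=neg_mae,
    )
    return model, history
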