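"""The two whistle detectors: a compact CNN and a VGG16-style transfer model.

Both consume 224 x 224 x 3 grayscale tensors and emit a 2-way softmax
(noise vs whistle).  The compact ("vanilla") CNN uses two convolutional
blocks — 16 kernels of 7x7 then 32 kernels of 5x5, both stride 2, each
followed by max pooling (pool 2) and dropout (0.2) — then dense layers
of 32 and 16 units, trained with Adam at 1e-4.  The transfer model
replaces the top of a VGG16 backbone with dense layers of 50 and 20
units and fine-tunes every layer with Adam at 1e-5.  Pretrained
ImageNet weights require a download; offline builds start from random
initialization or a small test-double backbone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from whistlekit.nn import (
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    MaxPool2D,
    ReLU,
    Sequential,
    Softmax,
)
from whistlekit.nn.network import TrainingConfig

__all__ = [
    "VanillaCNNSpec",
    "TransferModelSpec",
    "TrainingConfig",
    "build_vanilla_cnn",
    "build_transfer_model",
    "predict",
    "HYPERPARAMETER_SEARCH_RANGES",
]

# Documented hyperparameter bounds (no search engine is shipped; these
# are the admissible ranges for external tuning tools).
HYPERPARAMETER_SEARCH_RANGES = {
    "n_conv_layers": (2, 4),
    "n_dense_layers": (1, 3),
    "learning_rate": (1e-5, 1e-2),
    "dense_units": (5, 100),
    "conv_filters": (8, 256),
    "conv_kernel": (3, 7),
    "early_stopping_patience": (5, 20),
    "dropout_rate": (0.1, 0.3),
}


@dataclass
class VanillaCNNSpec:
    """Architecture of the compact CNN detector."""

    conv_blocks: tuple = ((16, 7, 2), (32, 5, 2))  # (n_kernels, kernel, stride)
    pool_size: int = 2
    dropout_rate: float = 0.2
    dense_sizes: tuple = (32, 16)
    n_classes: int = 2
    learning_rate: float = 1e-4

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        for nk, k, s in self.conv_blocks:
            if nk <= 0 or k <= 0 or s <= 0:
                raise ValueError("conv block sizes must be positive")
        if any(d <= 0 for d in self.dense_sizes):
            raise ValueError("dense sizes must be positive")


@dataclass
class TransferModelSpec:
    """Architecture of the transfer-learning detector."""

    backbone: str = "vgg16"
    head_dense_sizes: tuple = (50, 20)
    n_classes: int = 2
    fine_tune_all: bool = True
    learning_rate: float = 1e-5

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.head_dense_sizes):
            raise ValueError("head dense sizes must be positive")


def build_vanilla_cnn(
    spec: VanillaCNNSpec = VanillaCNNSpec(),
    input_shape: tuple = (224, 224, 3),
    seed: int = 0,
) -> Sequential:
    """Assemble and initialize the compact CNN.

    Layer order per block is conv -> ReLU -> max-pool -> dropout; the
    stack ends flatten -> dense(32) -> ReLU -> dense(16) -> ReLU ->
    dense(2) -> softmax.  Convolutions are unpadded ("valid").
    Initialization is deterministic per seed.
    """
    layers = []
    for n_kernels, kernel, stride in spec.conv_blocks:
        layers += [
            Conv2D(n_kernels, kernel, stride),
            ReLU(),
            MaxPool2D(spec.pool_size),
            Dropout(spec.dropout_rate),
        ]
    layers.append(Flatten())
    for units in spec.dense_sizes:
        layers += [Dense(units), ReLU()]
    layers += [Dense(spec.n_classes), Softmax()]
    try:
        return Sequential(layers).build(input_shape, seed=seed)
    except ValueError as exc:
        raise ValueError(f"input shape {input_shape} incompatible with spec: {exc}") from exc


# VGG16 feature extractor: (conv counts, channels) per block, 3x3 same-
# padded convs, 2x2 max pool after each block.
_VGG16_BLOCKS = [(2, 64), (2, 128), (3, 256), (3, 512), (3, 512)]


def _vgg16_feature_layers() -> list:
    layers = []
    for n_convs, channels in _VGG16_BLOCKS:
        for _ in range(n_convs):
            layers += [Conv2D(channels, 3, 1, padding="same"), ReLU()]
        layers.append(MaxPool2D(2))
    return layers


def _tiny_backbone_layers() -> list:
    """Small random conv stack standing in for VGG16 in offline tests."""
    return [
        Conv2D(8, 3, 2, padding="same"),
        ReLU(),
        MaxPool2D(2),
        Conv2D(16, 3, 2, padding="same"),
        ReLU(),
        MaxPool2D(2),
    ]


def build_transfer_model(
    spec: TransferModelSpec = TransferModelSpec(),
    input_shape: tuple = (224, 224, 3),
    seed: int = 0,
) -> Sequential:
    """Assemble the transfer-learning detector.

    The backbone's classification top is omitted; a new head
    flatten -> dense(50) -> ReLU -> dense(20) -> ReLU -> dense(2) ->
    softmax is appended.  With ``fine_tune_all`` every backbone layer is
    trainable; otherwise backbone parameters are frozen.

    Backbones: ``"vgg16"`` (VGG16 topology, random init), ``"tiny"``
    (small test double).  ``"vgg16-imagenet"`` is rejected: pretrained
    weights need a one-time download; use ``"vgg16"`` or ``"tiny"``
    for offline work.
    """
    if spec.backbone == "vgg16":
        backbone = _vgg16_feature_layers()
    elif spec.backbone == "tiny":
        backbone = _tiny_backbone_layers()
    elif spec.backbone == "vgg16-imagenet":
        raise RuntimeError(
            "pretrained ImageNet weights are not bundled and require a network "
            "download; build with backbone='vgg16' (random init) or 'tiny' "
            "(offline test double)"
        )
    else:
        raise RuntimeError(f"unknown backbone {spec.backbone!r}; choose 'vgg16' or 'tiny'")
    if not spec.fine_tune_all:
        for layer in backbone:
            layer.trainable = False
    head: list = [Flatten()]
    for units in spec.head_dense_sizes:
        head += [Dense(units), ReLU()]
    head += [Dense(spec.n_classes), Softmax()]
    return Sequential(backbone + head).build(input_shape, seed=seed)


def predict(model: Sequential, inputs, threshold: float = 0.5):
    """Score inputs and threshold into labels.

    ``inputs`` is an array of tensors or a list of
    :class:`~whistlekit.spectrogram.ModelInput`.  Returns a list of
    ``(score, label)`` where score is the whistle-class probability and
    label is 1 iff score >= threshold; input order is preserved.
    """
    if hasattr(inputs, "__len__") and len(inputs) and hasattr(inputs[0], "tensor"):
        x = np.stack([m.tensor for m in inputs])
    else:
        x = np.asarray(inputs, dtype=np.float32)
    if x.ndim == 3:
        x = x[np.newaxis]
    if x.shape[1:] != model.input_shape:
        raise ValueError(f"input tensors {x.shape[1:]} do not match model input "
                         f"{model.input_shape}")
    proba = model.predict_proba(x)
    scores = proba[:, 1]
    return [(float(s), int(s >= threshold)) for s in scores]
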