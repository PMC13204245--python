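"""The compact pooling-pluggable CNN for benign/malignant classification.

Architecture: B in {3, 4} blocks of [conv 3x3 'same' -> batch norm -> ReLU
-> pooling], channel schedule 32 -> 64 -> 128 (-> 256), followed by global
average pooling, a dense 128-unit ReLU head with dropout 0.5, and a final
dense layer with 2 outputs and softmax.  He-normal initialization.  The
pooling operator (average, max or wavelet-LL) is a plug-in and carries no
trainable parameters, so parameter counts are identical across pooling
variants of the same depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from . import nn
from .pooling import PoolingConfig
from .wavelets import make_symlet

CHANNEL_SCHEDULE = (32, 64, 128, 256)


@dataclass(frozen=True)
class ModelConfig:
    blocks: int = 3
    pooling: PoolingConfig = field(default_factory=lambda: PoolingConfig("max"))
    in_channels: int = 1
    head_width: int = 128
    dropout: float = 0.5
    num_classes: int = 2
    input_size: int = 224
    dtype: str = "float32"  # compute precision; parameters stay float64

    def __post_init__(self) -> None:
        if self.blocks not in (3, 4):
            raise ValueError(f"blocks must be 3 or 4, got {self.blocks}")
        if self.dtype not in ("float32", "float64"):
            raise ValueError(f"dtype must be float32 or float64, got {self.dtype}")
        if self.input_size % (2 ** self.blocks) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2^blocks")

    @property
    def channels(self) -> Tuple[int, ...]:
        return CHANNEL_SCHEDULE[: self.blocks]


class WaveletCNN:
    """The compact CNN with a pluggable pooling operator."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        layers: List[nn.Layer] = []
        in_ch = config.in_channels
        self._last_relu_index = None
        for ch in config.channels:
            layers.append(nn.Conv2D(in_ch, ch, rng))
            layers.append(nn.BatchNorm2D(ch))
            layers.append(nn.ReLU())
            self._last_relu_index = len(layers) - 1
            layers.append(self._make_pool(config.pooling))
            in_ch = ch
        layers.append(nn.GlobalAvgPool())
        layers.append(nn.Dense(in_ch, config.head_width, rng))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(config.dropout))
        layers.append(nn.Dense(config.head_width, config.num_classes, rng))
        self.net = nn.Sequential(layers)

    @staticmethod
    def _make_pool(cfg: PoolingConfig) -> nn.Layer:
        if cfg.kind == "avg":
            return nn.AvgPool2()
        if cfg.kind == "max":
            return nn.MaxPool2()
        return nn.WaveletPool2(make_symlet(cfg.order))

    # -- inference ---------------------------------------------------------
    def logits(self, x: np.ndarray, train: bool = False,
               rng: np.random.Generator | None = None) -> np.ndarray:
        """Forward pass to pre-softmax scores; x is (B, C, H, W)."""
        x = np.asarray(x).astype(self.config.dtype, copy=False)
        out = self.net.forward(x, train=train, rng=rng)
        return out.astype(np.float64, copy=False)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities in evaluation mode (deterministic)."""
        return nn.softmax(self.logits(x, train=False))

    # -- Grad-CAM support --------------------------------------------------
    def forward_with_activation(self, x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Evaluation forward returning (logits, last-conv post-ReLU maps)."""
        x = np.asarray(x).astype(self.config.dtype, copy=False)
        a = self.net.forward(x, train=False, stop=self._last_relu_index + 1)
        out = self.net.forward(a, train=False, start=self._last_relu_index + 1)
        self._activation = a
        return out, a

    def grad_wrt_activation(self, dlogits: np.ndarray) -> np.ndarray:
        """Backprop dlogits down to the last-conv post-ReLU activations.

        Must follow a :meth:`forward_with_activation` call; parameter
        gradients accumulated along the way are cleared afterwards so the
        model state is unchanged.
        """
        g = self.net.backward(np.asarray(dlogits).astype(self.config.dtype),
                              start=len(self.net.layers),
                              stop=self._last_relu_index + 1)
        self.net.zero_grad()
        return g


def build_model(config: ModelConfig, seed: int = 0) -> WaveletCNN:
    """Build and He-initialize the network from a configuration."""
    return WaveletCNN(config, np.random.default_rng(seed))


def count_parameters(model: WaveletCNN) -> int:
    """Total trainable parameters (conv/dense weights+biases, BN gamma/beta)."""
    return int(sum(p.value.size for p in model.net.params()))


def summarize(model: WaveletCNN) -> Dict:
    """Per-layer parameter accounting, including BN running statistics."""
    rows = []
    total = 0
    running = 0
    for i, layer in enumerate(model.net.layers):
        n = sum(p.value.size for p in layer.params())
        row = {"index": i, "layer": type(layer).__name__, "trainable_params": int(n)}
        if isinstance(layer, nn.BatchNorm2D):
            r = layer.running_mean.size + layer.running_var.size
            row["running_stats"] = int(r)
            running += r
        rows.append(row)
        total += n
    return {
        "pooling": model.config.pooling.name,
        "blocks": model.config.blocks,
        "layers": rows,
        "total_trainable": int(total),
        "total_running_stats": int(running),
    }
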