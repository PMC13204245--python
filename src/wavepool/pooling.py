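"""Pooling operators under comparison: average, max, and wavelet-LL pooling.

Wavelet pooling downsamples a feature map by keeping the LL (approximation)
subband of a one-level Symlet DWT: P(F) = LL.  Like 2x2 stride-2 average or
max pooling it halves each spatial dimension and carries no trainable
parameters, but the reduction happens after a multiscale filter bank, which
pushes high-frequency speckle into the discarded detail subbands.

The LL gain is deliberately *not* renormalized (a constant map c pools to
2c, the low-pass DC gain sqrt(2) per axis); batch normalization after the
convolution absorbs the scale.

Because LL extraction is linear, its exact backward pass is the adjoint
operator, which for an orthonormal periodized transform is the inverse DWT
of (grad, 0, 0, 0).  Odd spatial dimensions are replicate-padded to even
before pooling, mirroring the transform module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pywt

from .wavelets import FilterBank, dwt2, make_symlet

POOL_KINDS = ("avg", "max", "wavelet")


@dataclass(frozen=True)
class PoolingConfig:
    """One of the pooling configurations under study.

    The six studied configurations are: avg, max, sym2 with and without
    input despeckling, sym4 + despeckling, sym6 + despeckling.
    """

    kind: str
    order: Optional[int] = None
    preprocess: bool = False

    def __post_init__(self) -> None:
        if self.kind not in POOL_KINDS:
            raise ValueError(f"kind must be one of {POOL_KINDS}, got {self.kind!r}")
        if self.kind == "wavelet" and self.order is None:
            raise ValueError("wavelet pooling requires a Symlet order")
        if self.kind != "wavelet" and self.order is not None:
            raise ValueError(f"order is only valid for wavelet pooling, got kind={self.kind!r}")

    @property
    def name(self) -> str:
        base = f"sym{self.order}" if self.kind == "wavelet" else self.kind
        return base + ("+pre" if self.preprocess else "")

    @classmethod
    def from_name(cls, name: str) -> "PoolingConfig":
        base, _, suffix = name.partition("+")
        pre = suffix == "pre"
        if base.startswith("sym"):
            return cls(kind="wavelet", order=int(base[3:]), preprocess=pre)
        return cls(kind=base, preprocess=pre)


STUDY_CONFIGS: Tuple[PoolingConfig, ...] = (
    PoolingConfig("avg"),
    PoolingConfig("max"),
    PoolingConfig("wavelet", order=2),
    PoolingConfig("wavelet", order=2, preprocess=True),
    PoolingConfig("wavelet", order=4, preprocess=True),
    PoolingConfig("wavelet", order=6, preprocess=True),
)


def _as_float(arr: np.ndarray) -> np.ndarray:
    """float64 unless the caller already works in a float dtype (e.g. an
    fp32 network); integer and exotic inputs are promoted."""
    a = np.asarray(arr)
    if a.dtype not in (np.float32, np.float64):
        a = a.astype(np.float64)
    return a


def _pad_even_2d(arr: np.ndarray) -> np.ndarray:
    pad = [(0, 0)] * (arr.ndim - 2) + [(0, arr.shape[-2] % 2), (0, arr.shape[-1] % 2)]
    if any(p[1] for p in pad):
        arr = np.pad(arr, pad, mode="edge")
    return arr


def _blocks(arr: np.ndarray) -> np.ndarray:
    """View the trailing HxW axes as (H/2, 2, W/2, 2) blocks."""
    a = _pad_even_2d(_as_float(arr))
    h, w = a.shape[-2] // 2, a.shape[-1] // 2
    return a.reshape(*a.shape[:-2], h, 2, w, 2)


def avg_pool2(feature_map: np.ndarray) -> np.ndarray:
    """2x2 stride-2 block mean over the trailing two axes."""
    if np.asarray(feature_map).size == 0:
        raise ValueError("empty feature map")
    return _blocks(feature_map).mean(axis=(-3, -1))


def max_pool2(feature_map: np.ndarray) -> np.ndarray:
    """2x2 stride-2 block max over the trailing two axes."""
    if np.asarray(feature_map).size == 0:
        raise ValueError("empty feature map")
    return _blocks(feature_map).max(axis=(-3, -1))


def wavelet_pool2(feature_map: np.ndarray, fb: FilterBank) -> np.ndarray:
    """LL subband of a one-level DWT; works on (..., H, W) stacks."""
    arr = _as_float(feature_map)
    if arr.ndim == 2:
        return dwt2(arr, fb).ll.astype(arr.dtype, copy=False)
    arr = _pad_even_2d(arr)
    ll, _ = pywt.dwt2(arr, fb.as_pywt(), mode="periodization", axes=(-2, -1))
    return ll


def wavelet_pool_adjoint(grad_out: np.ndarray, fb: FilterBank,
                         in_shape: Tuple[int, ...]) -> np.ndarray:
    """Transpose of the LL-extraction operator.

    For the orthonormal periodized transform this is the inverse DWT with
    zero detail subbands, cropped back to ``in_shape`` when the forward
    pass padded an odd axis.
    """
    g = _as_float(grad_out)
    h, w = in_shape[-2], in_shape[-1]
    eh, ew = h + h % 2, w + w % 2
    if g.shape[-2:] != (eh // 2, ew // 2):
        raise ValueError(
            f"gradient shape {g.shape[-2:]} does not match pooled shape "
            f"{(eh // 2, ew // 2)} for input shape {(h, w)}"
        )
    out = pywt.idwt2((g, (None, None, None)), fb.as_pywt(),
                     mode="periodization", axes=(-2, -1))
    # padding by edge replication is not exactly adjoint to cropping, but the
    # forward pad only triggers on odd axes, which the network never produces;
    # cropping keeps shapes consistent in that case.
    return np.ascontiguousarray(out[..., :h, :w])


def pool_forward(feature_map: np.ndarray, config: PoolingConfig,
                 fb: FilterBank | None = None) -> np.ndarray:
    """Dispatch on the pooling kind; channels are handled independently."""
    if config.kind == "avg":
        return avg_pool2(feature_map)
    if config.kind == "max":
        return max_pool2(feature_map)
    if fb is None:
        fb = make_symlet(config.order)
    return wavelet_pool2(feature_map, fb)
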