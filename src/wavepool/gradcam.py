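"""Grad-CAM heatmaps and Pointing-Game localization scoring.

Grad-CAM weights the last convolutional layer's post-ReLU feature maps
A^k by the spatial mean of the class-score gradient,
alpha_k = (1/Z) sum_ij dy^c / dA^k_ij, and takes ReLU(sum_k alpha_k A^k).
The map is bilinearly upsampled to the input size and max-normalized to
[0, 1] (an all-zero map stays zero).

The Pointing Game scores a heatmap as a hit when its maximum (first
row-major index on ties) falls inside the annotated lesion mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.transform import resize

from .model import WaveletCNN


@dataclass
class Heatmap:
    values: np.ndarray              # input-sized, in [0, 1]
    target_class: int
    source_layer: str = "last_conv_relu"


def gradcam_map(model: WaveletCNN, image: np.ndarray, target_class: int) -> Heatmap:
    """Class-discriminative heatmap from the last convolutional block."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a single 2-D grayscale image")
    x = img[None, None]
    logits, acts = model.forward_with_activation(x)
    if logits.ndim != 2 or not (0 <= target_class < logits.shape[1]):
        raise ValueError(f"invalid target class {target_class}")
    if acts.ndim != 4:
        raise ValueError("source layer has no spatial feature maps")
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    grads = model.grad_wrt_activation(dlogits)      # (1, K, h, w)
    alpha = grads[0].mean(axis=(1, 2))              # (K,)
    cam = np.maximum(np.tensordot(alpha, acts[0], axes=1), 0.0)
    cam = resize(cam, img.shape, order=1, mode="edge", anti_aliasing=False)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return Heatmap(values=cam, target_class=target_class)


def pointing_game(heatmap: Heatmap | np.ndarray, lesion_mask: np.ndarray) -> int:
    """1 if the heatmap's (first row-major) argmax lies inside the mask."""
    values = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    mask = np.asarray(lesion_mask).astype(bool)
    if mask.shape != values.shape:
        raise ValueError(f"mask shape {mask.shape} != heatmap shape {values.shape}")
    if not mask.any():
        raise ValueError("empty lesion mask")
    flat_idx = int(values.argmax())                 # first max, row-major
    return int(mask.ravel()[flat_idx])


def pointing_accuracy(heatmaps: Sequence[Heatmap | np.ndarray],
                      masks: Sequence[np.ndarray]) -> float:
    """Mean Pointing-Game hit rate over an evaluation set."""
    if len(heatmaps) != len(masks):
        raise ValueError("need one mask per heatmap")
    hits = [pointing_game(h, m) for h, m in zip(heatmaps, masks)]
    return float(np.mean(hits))
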