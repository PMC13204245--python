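"""Synthetic B-mode-like lesion phantoms with ground-truth masks.

Each phantom is a textured bright background containing one hypoechoic
(darker) lesion.  The lesion boundary is a radial-harmonic curve

    r(theta) = r0 * (1 + sum_m a_m cos(m * theta + phi_m)),

whose harmonic content encodes the class: benign lesions use low orders
with small amplitude (smooth oval margins), malignant lesions use higher
orders with larger amplitude (irregular, spiculated margins) -- the margin
morphology a classifier of breast ultrasound lesions must exploit.
Margins are softened by a Gaussian blur, then multiplicative speckle is
applied last, so the pre-speckle composition is a well-defined clean
reference for despeckling experiments.

Generation is fully deterministic per (label, spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .noise import NoiseSpec

BENIGN, MALIGNANT = 0, 1
LABEL_NAMES = {BENIGN: "benign", MALIGNANT: "malignant"}


@dataclass(frozen=True)
class PhantomSpec:
    size: int = 224
    background_mean: float = 0.55
    texture_amplitude: float = 0.06
    texture_scale: float = 2.0
    lesion_contrast: float = 0.30
    radius_range: Tuple[float, float] = (0.12, 0.20)
    benign_amplitude: float = 0.03
    benign_orders: Tuple[int, ...] = (2, 3)
    malignant_amplitude: float = 0.10
    malignant_orders: Tuple[int, ...] = (4, 5, 6, 7, 8, 9)
    blur_sigma: float = 1.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        if self.lesion_contrast <= self.texture_amplitude:
            raise ValueError("lesion contrast must exceed the texture amplitude")
        lo, hi = self.radius_range
        if not 0 < lo <= hi < 0.5:
            raise ValueError("radius range must lie in (0, 0.5) of the frame")


@dataclass
class PhantomSample:
    image: np.ndarray
    mask: np.ndarray
    label: int
    seed: int
    params: dict


def _boundary_radius(theta: np.ndarray, r0: float, orders: Tuple[int, ...],
                     amps: np.ndarray, phases: np.ndarray) -> np.ndarray:
    pert = np.zeros_like(theta)
    for m, a, phi in zip(orders, amps, phases):
        pert += a * np.cos(m * theta + phi)
    return r0 * (1.0 + pert)


def generate_phantom(label: int, spec: PhantomSpec,
                     rng: np.random.Generator) -> PhantomSample:
    """Draw one phantom image + lesion mask for the given class label."""
    if label not in (BENIGN, MALIGNANT):
        raise ValueError(f"label must be 0 (benign) or 1 (malignant), got {label}")
    s = spec.size
    if label == MALIGNANT:
        orders, amp = spec.malignant_orders, spec.malignant_amplitude
    else:
        orders, amp = spec.benign_orders, spec.benign_amplitude

    r0 = rng.uniform(*spec.radius_range) * s
    amps = amp * rng.uniform(0.5, 1.0, size=len(orders))
    phases = rng.uniform(0, 2 * np.pi, size=len(orders))
    r_max = r0 * (1.0 + np.sum(amps))
    margin = r_max + 3 * spec.blur_sigma + 2
    if 2 * margin >= s:
        raise ValueError("lesion cannot fit inside the frame at this radius/size")
    cx = rng.uniform(margin, s - margin)
    cy = rng.uniform(margin, s - margin)

    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    mask = dist < _boundary_radius(theta, r0, orders, amps, phases)

    texture = ndimage.gaussian_filter(rng.standard_normal((s, s)), spec.texture_scale)
    texture *= spec.texture_amplitude / max(texture.std(), 1e-12)
    soft = ndimage.gaussian_filter(mask.astype(np.float64), spec.blur_sigma)
    image = spec.background_mean + texture - spec.lesion_contrast * soft
    image = np.clip(image, 0.0, 1.0)
    if spec.noise.level > 0:
        image = replace(spec.noise, seed=int(rng.integers(2 ** 31))).apply(image)

    params = {"r0": r0, "center": (cy, cx), "orders": tuple(orders),
              "amps": amps.tolist(), "phases": phases.tolist()}
    return PhantomSample(image=image, mask=mask, label=label, seed=-1, params=params)


def boundary_roughness(mask: np.ndarray) -> float:
    """Perimeter^2 / area -- dimensionless margin irregularity measure."""
    from skimage.measure import perimeter

    area = float(mask.sum())
    if area == 0:
        raise ValueError("empty mask")
    return float(perimeter(mask) ** 2 / area)


def generate_dataset(n: int, class_balance: float, spec: PhantomSpec,
                     seed: int) -> Tuple[List[PhantomSample], pd.DataFrame]:
    """Generate a stratified phantom dataset with a 70/15/15 split column.

    Class counts are exact: floor(n * balance) malignant, the rest benign.
    Each sample gets its own child seed so any sample can be regenerated
    independently.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0.0 < class_balance < 1.0:
        raise ValueError("class_balance must be in (0, 1)")
    n_mal = int(np.floor(n * class_balance))
    n_ben = n - n_mal
    if n_mal == 0 or n_ben == 0:
        raise ValueError("n too small for stratification at this balance")

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]
    labels = [MALIGNANT] * n_mal + [BENIGN] * n_ben
    samples: List[PhantomSample] = []
    for i, (lab, cs) in enumerate(zip(labels, child_seeds)):
        sample = generate_phantom(lab, spec, np.random.default_rng(cs))
        sample.seed = cs
        samples.append(sample)

    rows = []
    for lab in (BENIGN, MALIGNANT):
        idx = [i for i, s in enumerate(samples) if s.label == lab]
        rng = np.random.default_rng(seed + 1)  # fixed split seed
        perm = rng.permutation(len(idx))
        n_train = int(round(0.70 * len(idx)))
        n_val = int(round(0.15 * len(idx)))
        for rank, j in enumerate(perm):
            split = ("train" if rank < n_train
                     else "val" if rank < n_train + n_val else "test")
            rows.append({"index": idx[j], "label": lab,
                         "label_name": LABEL_NAMES[lab],
                         "seed": samples[idx[j]].seed, "split": split})
    manifest = pd.DataFrame(rows).sort_values("index").reset_index(drop=True)
    return samples, manifest


def dataset_arrays(samples: List[PhantomSample],
                   manifest: pd.DataFrame, split: str) -> Tuple[np.ndarray, np.ndarray]:
    """Stack (images, labels) for one split as arrays."""
    idx = manifest.loc[manifest["split"] == split, "index"].to_numpy()
    x = np.stack([samples[i].image for i in idx])
    y = np.array([samples[i].label for i in idx], dtype=int)
    return x, y
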