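"""Controlled speckle-style degradation of [0, 1] grayscale images.

Speckle in coherent (ultrasound) imaging is signal-dependent and
multiplicative: brighter pixels are perturbed proportionally harder.  The
first-order model used throughout this package is

    I_noisy = I * (1 + n),    n ~ Normal(0, sigma^2)  i.i.d. per pixel,

with sigma in {0.1, 0.2} naming the "10%" and "20%" stress levels.  A
Rayleigh-type variant replaces the Gaussian multiplier with a standardized
Rayleigh draw (mean 1, std = level) so that the same percentage
parameterization applies; a raw unit-mean Rayleigh multiplier has a fixed
coefficient of variation (~0.523) and could not express a 10% level.
Outputs are clipped back to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: mean and std of the standard (scale-1) Rayleigh distribution
_RAYLEIGH_MEAN = np.sqrt(np.pi / 2.0)
_RAYLEIGH_STD = np.sqrt(2.0 - np.pi / 2.0)

PSNR_INF = float("inf")


@dataclass(frozen=True)
class NoiseSpec:
    """A reproducible degradation: kind, level and seed."""

    kind: str = "multiplicative_gaussian"  # or "rayleigh"
    level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative_gaussian", "rayleigh"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if not 0.0 <= self.level <= 1.0:
            raise ValueError(f"level must be in [0, 1], got {self.level}")

    def apply(self, image: np.ndarray) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        if self.kind == "rayleigh":
            return add_rayleigh(image, self.level, rng)
        return add_speckle(image, self.level, rng)


def add_speckle(image: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative Gaussian speckle I*(1+n), n ~ N(0, sigma^2), clipped."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    arr = np.asarray(image, dtype=np.float64)
    if sigma == 0:
        return arr.copy()
    n = rng.normal(0.0, sigma, size=arr.shape)
    return np.clip(arr * (1.0 + n), 0.0, 1.0)


def add_rayleigh(image: np.ndarray, level: float, rng: np.random.Generator) -> np.ndarray:
    """Rayleigh-type multiplicative noise with unit-mean, std=level multiplier.

    The multiplier is M = 1 + level * (R - mu_R) / sd_R with R a standard
    Rayleigh draw, so E[M] = 1 and Std[M] = level before clipping.
    """
    if level < 0:
        raise ValueError(f"level must be >= 0, got {level}")
    arr = np.asarray(image, dtype=np.float64)
    if level == 0:
        return arr.copy()
    r = rng.rayleigh(1.0, size=arr.shape)
    mult = 1.0 + level * (r - _RAYLEIGH_MEAN) / _RAYLEIGH_STD
    return np.clip(arr * mult, 0.0, 1.0)


def psnr(reference: np.ndarray, test: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB for peak value 1.

    Returns ``inf`` for identical inputs.
    """
    ref = np.asarray(reference, dtype=np.float64)
    tst = np.asarray(test, dtype=np.float64)
    if ref.shape != tst.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {tst.shape}")
    mse = float(np.mean((ref - tst) ** 2))
    if mse == 0.0:
        return PSNR_INF
    return 10.0 * np.log10(1.0 / mse)
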