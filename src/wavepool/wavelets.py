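"""Symlet filter banks and separable 2-D discrete wavelet transforms.

This module is the shared DWT engine for wavelet pooling and input
despeckling.  It builds least-asymmetric orthonormal (Symlet) filter banks
of order N in {2, 4, 6} and exposes one- and multi-level 2-D transforms
with exact inverses.

Conventions
-----------
* Filter bank: analysis low-pass ``dec_lo`` is the orthonormal Symlet
  scaling filter (2N taps, sum sqrt(2), unit energy); the analysis
  high-pass obeys the quadrature-mirror relation
  ``dec_hi[k] = (-1)**k * dec_lo[2N-1-k]``, and the synthesis filters are
  the time-reversals of the analysis pair.  Note that this fixes the sign
  of the wavelet; either sign spans the same basis.
* Boundary handling: ``periodization`` (circular) by default, which maps
  an even H x W image to four (H/2) x (W/2) subbands and conserves energy
  exactly; ``symmetric`` half-sample extension is available as an
  alternative (redundant sizes, no exact Parseval).
* Odd dimensions are edge-replicated up to the next even size before the
  transform; the original shape is recorded so inversion restores it.

All arithmetic is done in 64-bit floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import List, Sequence, Tuple

import numpy as np
import pywt

SUPPORTED_ORDERS = (2, 4, 6)
BOUNDARY_MODES = ("periodization", "symmetric")


@dataclass(frozen=True)
class FilterBank:
    """Orthonormal Symlet analysis/synthesis filter quadruple.

    Parameters
    ----------
    order : int
        Symlet order N; the filters have 2N taps and the high-pass has N
        vanishing moments.
    dec_lo, dec_hi : tuple of float
        Analysis low-/high-pass filters.
    rec_lo, rec_hi : tuple of float
        Synthesis filters (time-reversed analysis filters).
    """

    order: int
    dec_lo: Tuple[float, ...]
    dec_hi: Tuple[float, ...]
    rec_lo: Tuple[float, ...]
    rec_hi: Tuple[float, ...]

    def as_pywt(self) -> pywt.Wavelet:
        return _pywt_wavelet(self.order)


@dataclass
class SubbandSet:
    """One-level LL/LH/HL/HH decomposition of a 2-D array."""

    ll: np.ndarray
    lh: np.ndarray
    hl: np.ndarray
    hh: np.ndarray
    source_shape: Tuple[int, int]
    boundary_mode: str = "periodization"
    level: int = 1

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.ll, self.lh, self.hl, self.hh)}
        if len(shapes) != 1:
            raise ValueError(f"subband shapes differ: {sorted(shapes)}")

    @property
    def subbands(self) -> Tuple[np.ndarray, ...]:
        return (self.ll, self.lh, self.hl, self.hh)


@dataclass
class MultilevelDecomposition:
    """L-level decomposition: coarsest LL plus per-level detail triples.

    ``details`` is ordered from level 1 (finest) to level L (coarsest).
    """

    ll_final: np.ndarray
    details: List[Tuple[np.ndarray, np.ndarray, np.ndarray]]
    source_shape: Tuple[int, int]
    boundary_mode: str = "periodization"

    @property
    def levels(self) -> int:
        return len(self.details)


def make_symlet(order: int) -> FilterBank:
    """Construct the Symlet-N filter bank for N in {2, 4, 6}.

    The low-pass coefficients come from the standard orthonormal Symlet
    construction; the remaining three filters are derived through the QMF
    and time-reversal relations documented in the module docstring.
    """
    if order not in SUPPORTED_ORDERS:
        raise ValueError(
            f"unsupported Symlet order {order!r}; allowed orders are {SUPPORTED_ORDERS}"
        )
    dec_lo = np.asarray(pywt.Wavelet(f"sym{order}").dec_lo, dtype=np.float64)
    n_taps = 2 * order
    assert len(dec_lo) == n_taps
    signs = np.where(np.arange(n_taps) % 2 == 0, 1.0, -1.0)
    dec_hi = signs * dec_lo[::-1]
    return FilterBank(
        order=order,
        dec_lo=tuple(dec_lo),
        dec_hi=tuple(dec_hi),
        rec_lo=tuple(dec_lo[::-1]),
        rec_hi=tuple(dec_hi[::-1]),
    )


@lru_cache(maxsize=None)
def _pywt_wavelet(order: int) -> pywt.Wavelet:
    """pywt Wavelet object carrying this package's filter convention."""
    fb = make_symlet(order)
    return pywt.Wavelet(
        f"wavepool-sym{order}",
        filter_bank=[list(fb.dec_lo), list(fb.dec_hi), list(fb.rec_lo), list(fb.rec_hi)],
    )


def _check_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D array, got shape {arr.shape}")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError(f"both dimensions must be >= 2, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("input contains NaN or infinite values")
    return arr


def _check_mode(boundary: str) -> str:
    if boundary not in BOUNDARY_MODES:
        raise ValueError(f"boundary must be one of {BOUNDARY_MODES}, got {boundary!r}")
    return boundary


def _pad_to_even(arr: np.ndarray) -> np.ndarray:
    """Edge-replicate odd axes up to the next even length."""
    pads = [(0, arr.shape[0] % 2), (0, arr.shape[1] % 2)]
    if pads[0][1] or pads[1][1]:
        arr = np.pad(arr, pads, mode="edge")
    return arr


def dwt2(image: np.ndarray, fb: FilterBank, boundary: str = "periodization") -> SubbandSet:
    """One-level separable 2-D DWT of a single image or feature map.

    With periodization on even dimensions the transform is orthonormal:
    subbands have shape (H/2, W/2) and conserve energy exactly.
    """
    arr = _check_image(image)
    _check_mode(boundary)
    src_shape = arr.shape
    padded = _pad_to_even(arr)
    ll, (lh, hl, hh) = pywt.dwt2(padded, fb.as_pywt(), mode=boundary)
    return SubbandSet(ll=ll, lh=lh, hl=hl, hh=hh,
                      source_shape=src_shape, boundary_mode=boundary)


def idwt2(sub: SubbandSet, fb: FilterBank) -> np.ndarray:
    """Inverse of :func:`dwt2`; restores the recorded source shape."""
    rec = pywt.idwt2((sub.ll, (sub.lh, sub.hl, sub.hh)), fb.as_pywt(),
                     mode=sub.boundary_mode)
    h, w = sub.source_shape
    return np.ascontiguousarray(rec[:h, :w])


def max_levels(shape: Tuple[int, int]) -> int:
    """Largest L such that every level of the pyramid has both dims >= 2."""
    m = min(shape)
    return int(np.floor(np.log2(m))) if m >= 2 else 0


def wavedec2(image: np.ndarray, fb: FilterBank, levels: int,
             boundary: str = "periodization") -> MultilevelDecomposition:
    """Multi-level 2-D DWT: repeatedly decompose the LL band."""
    arr = _check_image(image)
    _check_mode(boundary)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    lmax = max_levels(arr.shape)
    if levels > lmax:
        raise ValueError(
            f"levels={levels} too deep for image of shape {arr.shape}; maximum is {lmax}"
        )
    details: List[Tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    shapes: List[Tuple[int, int]] = []
    current = arr
    for _ in range(levels):
        shapes.append(current.shape)
        sub = dwt2(current, fb, boundary)
        details.append((sub.lh, sub.hl, sub.hh))
        current = sub.ll
    dec = MultilevelDecomposition(ll_final=current, details=details,
                                  source_shape=arr.shape, boundary_mode=boundary)
    dec._level_shapes = shapes  # type: ignore[attr-defined]
    return dec


def waverec2(dec: MultilevelDecomposition, fb: FilterBank) -> np.ndarray:
    """Inverse of :func:`wavedec2`."""
    if dec.levels < 1:
        raise ValueError("decomposition has no levels")
    shapes = getattr(dec, "_level_shapes", None)
    current = dec.ll_final
    for lvl in range(dec.levels, 0, -1):
        lh, hl, hh = dec.details[lvl - 1]
        if shapes is not None:
            src = shapes[lvl - 1]
        else:
            src = (2 * lh.shape[0], 2 * lh.shape[1]) if lvl > 1 else dec.source_shape
        if current.shape != lh.shape:
            current = current[: lh.shape[0], : lh.shape[1]]
        sub = SubbandSet(ll=current, lh=lh, hl=hl, hh=hh,
                         source_shape=src, boundary_mode=dec.boundary_mode)
        current = idwt2(sub, fb)
    return current
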