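"""Centered 2-D FFT helpers.

Convention used throughout the package: real-space and frequency-space arrays
are indexed ``[row, col]`` = ``[y, x]`` with the origin (r = 0, k = 0) at the
*center* pixel ``floor(n/2)`` on each axis.  ``ft``/``ift`` wrap numpy's FFT
with the fftshift bookkeeping so that callers never see wrapped-order arrays.
``ft`` is unnormalized (numpy forward convention); ``ift`` carries the 1/N²
factor, i.e. ``ift(ft(x)) == x``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ft", "ift", "center_index", "crop_center", "embed_center"]


def ft(x: np.ndarray) -> np.ndarray:
    """Centered forward 2-D DFT (DC lands at the center pixel)."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x)))


def ift(x: np.ndarray) -> np.ndarray:
    """Centered inverse 2-D DFT (input DC at the center pixel)."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(x)))


def center_index(n: int) -> int:
    """Index of the DC / origin pixel on an axis of length *n*."""
    return n // 2


def crop_center(x: np.ndarray, shape: int | tuple[int, int]) -> np.ndarray:
    """Crop the central ``shape`` block (centers aligned) from a 2-D array."""
    if np.isscalar(shape):
        shape = (int(shape), int(shape))
    n0, n1 = x.shape[-2], x.shape[-1]
    m0, m1 = shape
    if m0 > n0 or m1 > n1:
        raise ValueError(f"cannot crop {shape} from {x.shape}")
    r0 = center_index(n0) - center_index(m0)
    c0 = center_index(n1) - center_index(m1)
    return x[..., r0 : r0 + m0, c0 : c0 + m1]


def embed_center(x: np.ndarray, shape: int | tuple[int, int]) -> np.ndarray:
    """Zero-pad a 2-D array into the center of a larger grid (centers aligned)."""
    if np.isscalar(shape):
        shape = (int(shape), int(shape))
    n0, n1 = x.shape
    m0, m1 = shape
    if m0 < n0 or m1 < n1:
        raise ValueError(f"cannot embed {x.shape} into {shape}")
    out = np.zeros(shape, dtype=x.dtype)
    r0 = center_index(m0) - center_index(n0)
    c0 = center_index(m1) - center_index(n1)
    out[r0 : r0 + n0, c0 : c0 + n1] = x
    return out
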