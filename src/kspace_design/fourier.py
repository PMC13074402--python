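"""Centered, unitary Fourier transforms and grid cropping/padding.

All k-space and image arrays in this package use a *centered* grid layout:
the conceptual index m runs over {-N/2, ..., N/2-1} and is stored at array
position m + N/2, so the DC sample of an N-point axis sits at position N/2.
Transforms are unitary (``norm="ortho"``) so that Parseval's identity holds
exactly and energy-based tests are scale-free.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fft2c", "ifft2c", "crop_center", "zero_pad_center"]


def fft2c(x: np.ndarray, axes: tuple[int, int] = (0, 1)) -> np.ndarray:
    """Centered unitary 2D FFT (image -> k-space) over ``axes``."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def ifft2c(x: np.ndarray, axes: tuple[int, int] = (0, 1)) -> np.ndarray:
    """Centered unitary 2D inverse FFT (k-space -> image) over ``axes``."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def _center_slices(n_big: int, n_small: int) -> slice:
    if n_small > n_big:
        raise ValueError(f"cannot crop {n_big} down to {n_small}")
    lo = n_big // 2 - n_small // 2
    return slice(lo, lo + n_small)


def crop_center(x: np.ndarray, shape: tuple[int, int], axes: tuple[int, int] = (0, 1)) -> np.ndarray:
    """Extract the centered ``shape`` block along ``axes`` (DC preserved)."""
    slicer: list[slice] = [slice(None)] * x.ndim
    for ax, n in zip(axes, shape):
        slicer[ax] = _center_slices(x.shape[ax], n)
    return x[tuple(slicer)]


def zero_pad_center(x: np.ndarray, shape: tuple[int, int], axes: tuple[int, int] = (0, 1)) -> np.ndarray:
    """Embed ``x`` in the center of a zero array of size ``shape`` along ``axes``."""
    out_shape = list(x.shape)
    slicer: list[slice] = [slice(None)] * x.ndim
    for ax, n in zip(axes, shape):
        if n < x.shape[ax]:
            raise ValueError(f"pad target {n} smaller than input {x.shape[ax]}")
        out_shape[ax] = n
        slicer[ax] = _center_slices(n, x.shape[ax])
    out = np.zeros(out_shape, dtype=x.dtype)
    out[tuple(slicer)] = x
    return out
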