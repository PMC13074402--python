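"""Linear operators for SENSE-model reconstruction.

``SenseOperator`` is the encoding map E of parallel imaging: sensitivity
modulation by the coil maps, unitary Fourier encoding on the N0 grid, and
centered low-resolution sampling on the N x N subgrid.  ``finite_difference``
is the periodic first-difference operator D whose l1 norm is the
(anisotropic-in-direction) total-variation seminorm used for regularization.
"""

from __future__ import annotations

import numpy as np

from .fourier import crop_center, fft2c, ifft2c, zero_pad_center

__all__ = [
    "SenseOperator",
    "finite_difference_apply",
    "finite_difference_adjoint",
    "tv_seminorm",
    "zero_pad_recon",
    "coil_combine",
]

#: floor for the SENSE combination denominator sum_l |S_l|^2
COMBINE_EPS = 1e-8


class SenseOperator:
    """E: image (N0, N0) -> k-space (N, N, L); adjoint provided.

    Per channel: multiply by the sensitivity map, centered unitary FFT on
    the N0 grid, crop to the central N x N block.
    """

    def __init__(self, maps: np.ndarray, N: int):
        maps = np.asarray(maps, dtype=complex)
        if maps.ndim != 3:
            raise ValueError("maps must be (N0, N0, L)")
        self.maps = maps
        self.N0 = maps.shape[0]
        self.L = maps.shape[2]
        if N > self.N0:
            raise ValueError(f"N={N} exceeds N0={self.N0}")
        self.N = N

    def apply(self, x: np.ndarray) -> np.ndarray:
        if x.shape[:2] != (self.N0, self.N0):
            raise ValueError(f"image shape {x.shape} does not match N0={self.N0}")
        k = fft2c(self.maps * x[:, :, None])
        return crop_center(k, (self.N, self.N))

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        if y.shape != (self.N, self.N, self.L):
            raise ValueError(f"data shape {y.shape} does not match ({self.N},{self.N},{self.L})")
        imgs = ifft2c(zero_pad_center(y, (self.N0, self.N0)))
        return (np.conj(self.maps) * imgs).sum(axis=2)

    def normal(self, x: np.ndarray, line_weights: np.ndarray | None = None) -> np.ndarray:
        """E^H diag(line_weights) E x (weights broadcast per phase-encode line)."""
        y = self.apply(x)
        if line_weights is not None:
            y = y * np.asarray(line_weights)[:, None, None]
        return self.adjoint(y)


def finite_difference_apply(x: np.ndarray) -> np.ndarray:
    """Stacked periodic first differences, shape (2, ...): axis-0 and axis-1."""
    return np.stack([x - np.roll(x, 1, axis=0), x - np.roll(x, 1, axis=1)])


def finite_difference_adjoint(y: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`finite_difference_apply` (negative periodic divergence)."""
    return (y[0] - np.roll(y[0], -1, axis=0)) + (y[1] - np.roll(y[1], -1, axis=1))


def tv_seminorm(x: np.ndarray) -> float:
    """||Dx||_1 with complex-magnitude absolute values."""
    return float(np.abs(finite_difference_apply(x)).sum())


def zero_pad_recon(d_or_s: np.ndarray, N0: int) -> np.ndarray:
    """Per-channel images from N-grid k-space: centered zero-pad to N0, inverse FFT."""
    d = np.asarray(d_or_s, dtype=complex)
    return ifft2c(zero_pad_center(d, (N0, N0)))


def coil_combine(channel_images: np.ndarray, maps: np.ndarray, eps: float = COMBINE_EPS) -> np.ndarray:
    """Unit-gain SENSE combination: sum_l conj(S_l) f_l / sum_l |S_l|^2.

    Voxels where the sensitivity energy falls below ``eps`` are set to zero
    (outside the coil support there is no signal to recover).
    """
    f = np.asarray(channel_images, dtype=complex)
    S = np.asarray(maps, dtype=complex)
    num = (np.conj(S) * f).sum(axis=2)
    den = (np.abs(S) ** 2).sum(axis=2)
    out = np.zeros_like(num)
    good = den > eps
    out[good] = num[good] / den[good]
    return out
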