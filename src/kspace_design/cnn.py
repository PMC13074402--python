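"""Compact convolutional reconstructor plugin.

The network contract mirrors image-domain learned reconstruction: the input
is the 2L real/imaginary planes of the per-channel zero-padded Fourier
images, the output is the 2 real/imaginary planes of the coil-combined
image estimate.  Any object honoring that contract can be registered; this
module ships two:

* :class:`CoilCombineStub` - a fixed, weight-free spatially varying linear
  combination that reproduces SENSE coil combination exactly (useful as an
  oracle for the channel contract).
* :class:`SmallConvNet` - a trainable 3x3-conv / ReLU network (periodic
  padding, He initialization) sized for desk-scale grids, with hand-written
  backpropagation supplying gradients for both its weights and, through the
  input images, the effective averages w.
"""

from __future__ import annotations

import numpy as np

from .fourier import crop_center, fft2c
from .operators import coil_combine, zero_pad_recon
from .recon import Reconstructor, register_reconstructor

__all__ = ["CoilCombineStub", "SmallConvNet", "CnnReconstructor"]


def _shift_stack(x: np.ndarray, offsets: list[tuple[int, int]]) -> np.ndarray:
    """Stack periodic shifts of (C, H, W) input -> (K, C, H, W)."""
    return np.stack([np.roll(x, (-dy, -dx), axis=(-2, -1)) for dy, dx in offsets])


class _Conv:
    """Periodic 2D convolution layer with explicit forward/backward."""

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator):
        self.offsets = [
            (dy, dx)
            for dy in range(-(ksize // 2), ksize // 2 + 1)
            for dx in range(-(ksize // 2), ksize // 2 + 1)
        ]
        k = len(self.offsets)
        scale = np.sqrt(2.0 / (c_in * k))  # He init
        self.W = rng.standard_normal((c_out, c_in, k)) * scale
        self.b = np.zeros(c_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._stack = _shift_stack(x, self.offsets)
        return np.einsum("oik,kihw->ohw", self.W, self._stack) + self.b[:, None, None]

    def backward(self, g_out: np.ndarray) -> np.ndarray:
        self.gW = np.einsum("ohw,kihw->oik", g_out, self._stack)
        self.gb = g_out.sum(axis=(1, 2))
        g_shift = np.einsum("oik,ohw->kihw", self.W, g_out)
        g_in = np.zeros_like(self._stack[0])
        for k, (dy, dx) in enumerate(self.offsets):
            g_in += np.roll(g_shift[k], (dy, dx), axis=(-2, -1))
        return g_in


class SmallConvNet:
    """2L -> width -> width -> 2 channels; two ReLU hidden conv layers."""

    def __init__(self, c_in: int, width: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.layers = [_Conv(c_in, width, 3, rng), _Conv(width, width, 3, rng), _Conv(width, 2, 1, rng)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._masks = []
        h = x
        for layer in self.layers[:-1]:
            h = layer.forward(h)
            mask = h > 0
            self._masks.append(mask)
            h = h * mask
        return self.layers[-1].forward(h)

    def backward(self, g_out: np.ndarray) -> np.ndarray:
        g = self.layers[-1].backward(g_out)
        for layer, mask in zip(self.layers[-2::-1], self._masks[::-1]):
            g = layer.backward(g * mask)
        return g

    def get_weights(self) -> np.ndarray:
        return np.concatenate([np.concatenate([l.W.ravel(), l.b]) for l in self.layers])

    def set_weights(self, vec: np.ndarray) -> None:
        pos = 0
        for l in self.layers:
            n = l.W.size
            l.W = vec[pos : pos + n].reshape(l.W.shape).copy()
            pos += n
            l.b = vec[pos : pos + l.b.size].copy()
            pos += l.b.size

    def weight_grads(self) -> np.ndarray:
        return np.concatenate([np.concatenate([l.gW.ravel(), l.gb]) for l in self.layers])


class CoilCombineStub:
    """Weight-free 2L->2 layer implementing exact SENSE coil combination.

    Synthetic stand-in for a trained network: it honors the channel
    contract while computing sum_l conj(S_l) f_l / sum_l |S_l|^2.
    """

    def __init__(self, maps: np.ndarray):
        self.maps = np.asarray(maps, dtype=complex)

    def forward(self, x: np.ndarray) -> np.ndarray:
        L = self.maps.shape[2]
        f = np.moveaxis(x[:L] + 1j * x[L:], 0, -1)  # (N0, N0, L)
        combined = coil_combine(f, self.maps)
        return np.stack([combined.real, combined.imag])


class CnnReconstructor(Reconstructor):
    """Network-based reconstruction behind the common interface.

    ``p`` is the flat weight vector of the registered network; gradients
    come from manual backpropagation, with the chain to w running through
    the noise scaling of the input images.
    """

    kind = "cnn"

    def __init__(self, maps: np.ndarray, N: int, net=None, width: int = 16, seed: int = 0):
        super().__init__(maps, N)
        self.net = net if net is not None else SmallConvNet(2 * self.L, width=width, seed=seed)

    def _input_planes(self, d: np.ndarray) -> np.ndarray:
        if d.shape[-1] != self.L:
            raise ValueError(f"expected {self.L} channels, got {d.shape[-1]}")
        f = zero_pad_recon(d, self.N0)  # (N0, N0, L)
        f = np.moveaxis(f, -1, 0)
        return np.concatenate([f.real, f.imag])

    def reconstruct(self, d: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
        out = self.net.forward(self._input_planes(d))
        return out[0] + 1j * out[1]

    def get_params(self) -> np.ndarray:
        return self.net.get_weights()

    def set_params(self, p: np.ndarray) -> None:
        self.net.set_weights(np.asarray(p, dtype=float))

    def loss_and_grads(self, s_N, z_N, w, r, need_wgrad=False):
        w = np.asarray(w, dtype=float)
        d = self.data_from(s_N, z_N, w)
        out = self.net.forward(self._input_planes(d))
        x = out[0] + 1j * out[1]
        e = x - r
        loss = float(np.sum(np.abs(e) ** 2))
        g_in = self.net.backward(np.stack([2.0 * e.real, 2.0 * e.imag]))
        grad_p = self.net.weight_grads()
        grad_w = None
        if need_wgrad:
            # complex cotangent per channel image, then adjoint of the
            # (zero-pad, unitary inverse FFT) map back to the N grid
            G = np.moveaxis(g_in[: self.L] + 1j * g_in[self.L :], 0, -1)
            H = crop_center(fft2c(G), (self.N, self.N))
            dd_dw = -0.5 * z_N * (w ** -1.5)[:, None, None]
            grad_w = np.real(H * np.conj(dd_dw)).sum(axis=(1, 2))
        return loss, grad_p, grad_w


register_reconstructor("cnn", CnnReconstructor)
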