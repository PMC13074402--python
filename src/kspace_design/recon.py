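"""Common interface for the reconstruction families.

Every reconstructor is a parameterized map ``g(d) -> x`` from averaged noisy
k-space data on the candidate N grid to a complex image on the full N0 grid,
so images from different candidate grid sizes are directly comparable.  The
trainable parameters p live in a flat real vector (window values for the
apodized method, log-regularization for SENSE-TV, network weights for the
CNN plugin); the per-line effective averages w enter both through the data
synthesis d = s + z/sqrt(w) and, where applicable, through the data-fidelity
weighting of the reconstruction itself.
"""

from __future__ import annotations

import abc
from typing import Callable

import numpy as np

__all__ = ["Reconstructor", "register_reconstructor", "make_reconstructor"]


class Reconstructor(abc.ABC):
    """Map g_{p,N,w}: (N, N, L) k-space -> (N0, N0) complex image."""

    kind: str

    def __init__(self, maps: np.ndarray, N: int):
        self.maps = np.asarray(maps, dtype=complex)
        self.N0 = self.maps.shape[0]
        self.L = self.maps.shape[2]
        self.N = int(N)

    @abc.abstractmethod
    def reconstruct(self, d: np.ndarray, w: np.ndarray) -> np.ndarray:
        """Reconstruct an N0 x N0 complex image from N-grid data."""

    def set_maps(self, maps: np.ndarray) -> None:
        """Rebind the coil sensitivity maps (p is shared across datasets)."""
        self.maps = np.asarray(maps, dtype=complex)

    @abc.abstractmethod
    def get_params(self) -> np.ndarray:
        """Flat real parameter vector p (optimizer space)."""

    @abc.abstractmethod
    def set_params(self, p: np.ndarray) -> None: ...

    def project_params(self) -> None:
        """Project p back onto its constraint set (default: unconstrained)."""

    @abc.abstractmethod
    def loss_and_grads(
        self,
        s_N: np.ndarray,
        z_N: np.ndarray,
        w: np.ndarray,
        r: np.ndarray,
        need_wgrad: bool = False,
    ) -> tuple[float, np.ndarray, np.ndarray | None]:
        """MSE loss ||g(s + z/sqrt(w)) - r||_2^2 and its gradients.

        Returns ``(loss, grad_p, grad_w)``; ``grad_w`` is None unless
        requested.  ``z_N`` is the unscaled (variance sigma**2) noise
        realization on the N grid.
        """

    def data_from(self, s_N: np.ndarray, z_N: np.ndarray, w: np.ndarray) -> np.ndarray:
        return s_N + z_N / np.sqrt(np.asarray(w, dtype=float))[:, None, None]


_REGISTRY: dict[str, Callable[..., Reconstructor]] = {}


def register_reconstructor(kind: str, factory: Callable[..., Reconstructor]) -> None:
    """Register a reconstructor factory under ``kind`` (plugin hook)."""
    _REGISTRY[kind] = factory


def make_reconstructor(kind: str, maps: np.ndarray, N: int, **kw) -> Reconstructor:
    """Instantiate a registered reconstructor (``apodized``, ``sense_tv``, ``cnn``...)."""
    # built-ins register lazily so importing this module stays cheap
    if kind not in _REGISTRY:
        from . import apodize, cnn, sense_tv  # noqa: F401

    if kind not in _REGISTRY:
        raise KeyError(f"unknown reconstructor kind {kind!r}; registered: {sorted(_REGISTRY)}")
    return _REGISTRY[kind](maps=maps, N=N, **kw)
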