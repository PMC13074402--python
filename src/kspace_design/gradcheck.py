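"""Central finite-difference gradients on the common reconstructor interface.

The mandatory fallback route for gradient verification: every analytic or
tangent-propagated gradient in the package is cross-checked against these
stencils on small instances.  Default steps: 1e-3 in reconstruction
parameters (log-lambda scale), 1e-2 in effective averages.
"""

from __future__ import annotations

import numpy as np

from .recon import Reconstructor

__all__ = ["fd_loss_grads"]


def _loss(recon: Reconstructor, s_N, z_N, w, r) -> float:
    x = recon.reconstruct(recon.data_from(s_N, z_N, w), w)
    return float(np.sum(np.abs(x - r) ** 2))


def fd_loss_grads(
    recon: Reconstructor,
    s_N: np.ndarray,
    z_N: np.ndarray,
    w: np.ndarray,
    r: np.ndarray,
    need_wgrad: bool = False,
    step_p: float = 1e-3,
    step_w: float = 1e-2,
) -> tuple[float, np.ndarray, np.ndarray | None]:
    """Loss and central-difference gradients w.r.t. p (and optionally w)."""
    w = np.asarray(w, dtype=float)
    p0 = recon.get_params()
    loss = _loss(recon, s_N, z_N, w, r)
    grad_p = np.zeros_like(p0)
    for i in range(p0.size):
        for sgn in (+1, -1):
            p = p0.copy()
            p[i] += sgn * step_p
            recon.set_params(p)
            grad_p[i] += sgn * _loss(recon, s_N, z_N, w, r)
        grad_p[i] /= 2 * step_p
    recon.set_params(p0)
    grad_w = None
    if need_wgrad:
        grad_w = np.zeros_like(w)
        for m in range(w.size):
            for sgn in (+1, -1):
                wp = w.copy()
                wp[m] += sgn * step_w
                grad_w[m] += sgn * _loss(recon, s_N, z_N, wp, r)
            grad_w[m] /= 2 * step_w
    return loss, grad_p, grad_w
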