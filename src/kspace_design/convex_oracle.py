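"""High-accuracy primal-dual reference solver for the SENSE-TV objective.

An independent algorithmic route to the same convex program that the ADMM
reconstruction solves: a Chambolle-Pock (PDHG) iteration on

    min_x  sum_m a_m ||(E x - d)_m||^2  +  lambda ||D x||_1,

run for many iterations with step sizes from a power-iteration estimate of
the operator norm.  It shares only the linear-operator code with the ADMM
path and is used as a convergence oracle in tests, never as the
reconstruction method itself.
"""

from __future__ import annotations

import numpy as np

from .sense_tv import _D, _Dt, _dot, _e_adjoint, _e_apply, _line_weights, sense_tv_objective

__all__ = ["pdhg_reference_solve"]


def _operator_norm(maps: np.ndarray, N: int, sqrt_a: np.ndarray, iters: int = 30, seed: int = 0) -> float:
    """Power iteration on K^H K with K = [diag(sqrt_a) E; D]."""
    N0 = maps.shape[0]
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((N0, N0)) + 1j * rng.standard_normal((N0, N0))
    nrm = 1.0
    for _ in range(iters):
        y1 = sqrt_a[:, None, None] * _e_apply(maps, N, x)
        y = _e_adjoint(maps, N0, sqrt_a[:, None, None] * y1) + _Dt(_D(x))
        nrm = float(np.sqrt(_dot(y, y)))
        x = y / max(nrm, 1e-300)
    return float(np.sqrt(nrm))


def pdhg_reference_solve(
    d: np.ndarray,
    w: np.ndarray,
    lam: float,
    maps: np.ndarray,
    weighting: str = "sqrt",
    iterations: int = 20000,
    tol: float = 1e-12,
    check_every: int = 200,
):
    """Solve the SENSE-TV program to high accuracy; returns ``(x, objective)``.

    Stops early once the relative objective decrease over ``check_every``
    iterations falls below ``tol``.
    """
    d = np.asarray(d, dtype=complex)
    w = np.asarray(w, dtype=float)
    N = d.shape[0]
    N0 = maps.shape[0]
    a = _line_weights(w, weighting)
    sqrt_a = np.sqrt(a)
    c = sqrt_a[:, None, None] * d  # target of the scaled quadratic term

    Lnorm = _operator_norm(maps, N, sqrt_a)
    tau = sigma = 0.95 / max(Lnorm, 1e-300)

    x = np.zeros((N0, N0), dtype=complex)
    xbar = x.copy()
    y1 = np.zeros_like(d)
    y2 = np.zeros((2, N0, N0), dtype=complex)

    best_obj = np.inf
    best_x = x
    last_check = np.inf
    for it in range(1, iterations + 1):
        v1 = y1 + sigma * sqrt_a[:, None, None] * _e_apply(maps, N, xbar)
        y1 = v1 - sigma * (v1 + 2.0 * c) / (sigma + 2.0)
        v2 = y2 + sigma * _D(xbar)
        mag = np.abs(v2)
        y2 = v2 * np.minimum(1.0, lam / np.maximum(mag, 1e-300))
        x_old = x
        grad = _e_adjoint(maps, N0, sqrt_a[:, None, None] * y1) + _Dt(y2)
        x = x - tau * grad
        xbar = 2.0 * x - x_old
        if it % check_every == 0 or it == iterations:
            obj = sense_tv_objective(x, d, w, lam, maps, weighting)
            if obj < best_obj:
                best_obj, best_x = obj, x.copy()
            if abs(last_check - obj) <= tol * max(abs(obj), 1e-300):
                break
            last_check = obj
    return best_x, best_obj
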