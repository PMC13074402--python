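"""Bilevel acquisition-reconstruction design.

Inner problem (per candidate grid size N): jointly fit the reconstruction
parameters p and, in nonuniform mode, the effective averaging pattern w by
(projected) minibatch stochastic gradient descent on the MSE between the
reconstruction of simulated noisy data and the *matched-resolution*
noise-free reference r^N.  The scan-time budget constraint on w is enforced
at every step by Euclidean projection; w gradients are normalized to unit
l2 norm before stepping.  After the joint epochs the pattern is rounded to
integer actual averages, frozen, and p is refined for a few more epochs.

Outer problem: brute-force search over the candidate N values, scoring each
trained design against the *high-resolution* reference r^{N0} with the same
noise realizations, and returning the argmin.  The two-level structure
keeps the inner problem a pure denoising task while the outer selection
still prioritizes high-resolution fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .acquisition import KSpaceDataset, NoiseModel, crop_kspace
from .operators import coil_combine, zero_pad_recon
from .patterns import (
    AveragingPattern,
    IntegerPattern,
    normalize_gradient,
    project_to_budget,
    round_to_integer_averages,
    uniform_pattern,
)
from .recon import Reconstructor, make_reconstructor

__all__ = [
    "TrainingSet",
    "InnerSchedule",
    "InnerResult",
    "DesignResult",
    "training_loss",
    "make_reference",
    "inner_optimize_uniform",
    "inner_optimize_nonuniform",
    "outer_select_N",
    "default_schedule",
]


@dataclass
class TrainingSet:
    """T noise-free datasets, the noise model, and the reference budget."""

    datasets: list[KSpaceDataset]
    noise: NoiseModel
    w0: int
    N0: int
    split: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.datasets) < 1:
            raise ValueError("need at least one dataset")
        idx = [i for part in self.split.values() for i in part]
        if len(idx) != len(set(idx)):
            raise ValueError("train/val/test splits must be disjoint")
        if not self.split:
            self.split = {"train": list(range(len(self.datasets))), "val": [], "test": []}

    @property
    def train_indices(self) -> list[int]:
        return self.split.get("train", [])


@dataclass
class InnerSchedule:
    """Optimization schedule for the inner (p, w) problem."""

    epochs_joint: int = 10
    epochs_refine: int = 0
    lr_p: float = 0.01
    lr_w: float = 0.01
    decay_p: float = 0.9
    decay_w: float = 0.99
    batch_size: int = 8
    optimizer_p: str = "sgd"
    redraw_noise: bool = False

    def __post_init__(self) -> None:
        if self.lr_p <= 0 or self.lr_w <= 0:
            raise ValueError("learning rates must be positive")
        if not (0 < self.decay_p <= 1 and 0 < self.decay_w <= 1):
            raise ValueError("decay factors must lie in (0, 1]")
        if self.optimizer_p not in ("sgd", "adam"):
            raise ValueError("optimizer_p must be 'sgd' or 'adam'")


#: per-reconstructor schedules for uniform / nonuniform averaging
_DEFAULT_SCHEDULES: dict[tuple[str, str], InnerSchedule] = {
    ("sense_tv", "uniform"): InnerSchedule(10, 0, 0.01, 0.01, 0.9, 0.99, 8, "sgd"),
    ("sense_tv", "nonuniform"): InnerSchedule(45, 5, 0.001, 0.01, 0.99, 0.99, 8, "sgd"),
    # the published plain-SGD window schedule (lr 1) is unstable at desk
    # scale: the quadratic window loss has per-coordinate curvature spanning
    # ~4 decades (DC vs edge k-space lines), so the window uses Adam
    ("apodized", "uniform"): InnerSchedule(50, 0, 0.02, 0.1, 0.99, 0.99, 8, "adam"),
    ("apodized", "nonuniform"): InnerSchedule(45, 5, 0.02, 0.1, 0.99, 0.99, 8, "adam"),
    ("cnn", "uniform"): InnerSchedule(100, 0, 3e-4, 0.01, 1.0, 0.99, 8, "adam"),
    ("cnn", "nonuniform"): InnerSchedule(90, 10, 3e-4, 0.01, 1.0, 0.99, 8, "adam"),
}


def default_schedule(kind: str, mode: str) -> InnerSchedule:
    """The published per-reconstructor training schedule (copy; mutate freely)."""
    from dataclasses import replace

    return replace(_DEFAULT_SCHEDULES[(kind, mode)])


def training_loss(x_hat: np.ndarray, r: np.ndarray) -> float:
    """Squared l2 distance sum |x - r|^2 over voxels (complex MSE loss)."""
    if x_hat.shape != r.shape:
        raise ValueError(f"shape mismatch: {x_hat.shape} vs {r.shape}")
    return float(np.sum(np.abs(x_hat - r) ** 2))


def make_reference(ds: KSpaceDataset, N: int) -> np.ndarray:
    """Noise-free reference r^N: crop to N, zero-pad, inverse FFT, coil-combine.

    ``N == ds.N0`` gives the full-resolution reference used by the outer
    selection; references never depend on w or sigma.
    """
    s_N = crop_kspace(ds, N)
    return coil_combine(zero_pad_recon(s_N, ds.N0), ds.maps)


class _Adam:
    def __init__(self, n: int, lr: float, b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.m = np.zeros(n)
        self.v = np.zeros(n)
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.t = 0

    def step(self, p: np.ndarray, g: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * g
        self.v = self.b2 * self.v + (1 - self.b2) * g ** 2
        mhat = self.m / (1 - self.b1 ** self.t)
        vhat = self.v / (1 - self.b2 ** self.t)
        return p - self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class InnerResult:
    """Artifacts of one inner optimization at a fixed candidate N."""

    N: int
    p_hat: np.ndarray
    w_hat: np.ndarray  # continuous effective averages (pre-rounding)
    q_hat: IntegerPattern | None
    w_final: np.ndarray  # pattern used for evaluation (rounded if nonuniform)
    loss_trace: list[float]


def _prepare(train: TrainingSet, N: int):
    """Crop k-space, build matched references and per-dataset noise."""
    items = []
    for t in train.train_indices:
        ds = train.datasets[t]
        items.append(
            {
                "t": t,
                "maps": ds.maps,
                "s_N": crop_kspace(ds, N),
                "r_N": make_reference(ds, N),
            }
        )
    return items


def _noise_for(train: TrainingSet, t: int, N: int, epoch: int, redraw: bool) -> np.ndarray:
    realization = epoch + 1 if redraw else 0
    return train.noise.noise(t, train.N0, train.datasets[t].L, N=N, realization=realization)


def _epoch_batches(rng: np.random.Generator, n_items: int, batch_size: int):
    order = rng.permutation(n_items)
    for i in range(0, n_items, batch_size):
        yield order[i : i + batch_size]


def inner_optimize_uniform(
    recon: Reconstructor,
    N: int,
    train: TrainingSet,
    sched: InnerSchedule,
    seed: int = 0,
) -> InnerResult:
    """Fit p at fixed uniform averaging w = w0*N0^2/N^2 (pattern not optimized)."""
    if not train.train_indices:
        raise ValueError("empty training split")
    w = uniform_pattern(N, train.N0, train.w0).w
    items = _prepare(train, N)
    rng = np.random.default_rng([seed, N])
    opt = _Adam(recon.get_params().size, sched.lr_p) if sched.optimizer_p == "adam" else None
    lr = sched.lr_p
    trace: list[float] = []
    for epoch in range(sched.epochs_joint):
        epoch_loss = 0.0
        for batch in _epoch_batches(rng, len(items), sched.batch_size):
            g = np.zeros_like(recon.get_params())
            for j in batch:
                it = items[j]
                recon.set_maps(it["maps"])
                z = _noise_for(train, it["t"], N, epoch, sched.redraw_noise)
                loss, gp, _ = recon.loss_and_grads(it["s_N"], z, w, it["r_N"])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"inner optimization diverged at epoch {epoch}; reduce lr_p"
                    )
                epoch_loss += loss
                g += gp
            p = recon.get_params()
            p = opt.step(p, g) if opt is not None else p - lr * g
            recon.set_params(p)
            recon.project_params()
        lr *= sched.decay_p
        if opt is not None:
            opt.lr *= sched.decay_p
        trace.append(epoch_loss / len(items))
    return InnerResult(N=N, p_hat=recon.get_params(), w_hat=w.copy(), q_hat=None, w_final=w.copy(), loss_trace=trace)


def inner_optimize_nonuniform(
    recon: Reconstructor,
    N: int,
    train: TrainingSet,
    sched: InnerSchedule,
    seed: int = 0,
) -> InnerResult:
    """Jointly fit p and w; then round w to integer averages, freeze, refine p.

    w starts at the uniform pattern and stays on the budget hyperplane
    (above the positivity floor) after every projected step; w gradients
    are normalized to unit l2 norm.  Rounding keeps every line measured at
    least once, matching the no-undersampling regime of the design space.
    """
    if not train.train_indices:
        raise ValueError("empty training split")
    pat = uniform_pattern(N, train.N0, train.w0)
    w, budget = pat.w.copy(), pat.budget
    items = _prepare(train, N)
    rng = np.random.default_rng([seed, N])
    opt = _Adam(recon.get_params().size, sched.lr_p) if sched.optimizer_p == "adam" else None
    lr_p, lr_w = sched.lr_p, sched.lr_w
    trace: list[float] = []
    for epoch in range(sched.epochs_joint):
        epoch_loss = 0.0
        for batch in _epoch_batches(rng, len(items), sched.batch_size):
            gp_sum = np.zeros_like(recon.get_params())
            gw_sum = np.zeros_like(w)
            for j in batch:
                it = items[j]
                recon.set_maps(it["maps"])
                z = _noise_for(train, it["t"], N, epoch, sched.redraw_noise)
                loss, gp, gw = recon.loss_and_grads(it["s_N"], z, w, it["r_N"], need_wgrad=True)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"inner optimization diverged at epoch {epoch}; reduce learning rates"
                    )
                epoch_loss += loss
                gp_sum += gp
                gw_sum += gw
            p = recon.get_params()
            p = opt.step(p, gp_sum) if opt is not None else p - lr_p * gp_sum
            recon.set_params(p)
            recon.project_params()
            w = project_to_budget(w - lr_w * normalize_gradient(gw_sum), budget)
        lr_p *= sched.decay_p
        lr_w *= sched.decay_w
        if opt is not None:
            opt.lr *= sched.decay_p
        trace.append(epoch_loss / len(items))

    w_hat = w.copy()
    q_hat = round_to_integer_averages(
        AveragingPattern(N=N, w=w_hat, N0=train.N0, w0=train.w0), require_sampled=True
    )
    w_final = q_hat.effective()

    for epoch in range(sched.epochs_refine):
        epoch_loss = 0.0
        for batch in _epoch_batches(rng, len(items), sched.batch_size):
            gp_sum = np.zeros_like(recon.get_params())
            for j in batch:
                it = items[j]
                recon.set_maps(it["maps"])
                z = _noise_for(train, it["t"], N, sched.epochs_joint + epoch, sched.redraw_noise)
                loss, gp, _ = recon.loss_and_grads(it["s_N"], z, w_final, it["r_N"])
                epoch_loss += loss
                gp_sum += gp
            p = recon.get_params()
            p = opt.step(p, gp_sum) if opt is not None else p - lr_p * gp_sum
            recon.set_params(p)
            recon.project_params()
        lr_p *= sched.decay_p
        if opt is not None:
            opt.lr *= sched.decay_p
        trace.append(epoch_loss / len(items))

    return InnerResult(N=N, p_hat=recon.get_params(), w_hat=w_hat, q_hat=q_hat, w_final=w_final, loss_trace=trace)


@dataclass
class DesignResult:
    """Outcome of the outer brute-force search over candidate grid sizes."""

    kind: str
    mode: str
    N_hat: int
    records: list[dict]

    def __post_init__(self) -> None:
        losses = {rec["N"]: rec["outer_loss"] for rec in self.records}
        if self.N_hat != min(losses, key=losses.get):
            raise ValueError("N_hat must attain the minimal outer loss")

    def record_for(self, N: int) -> dict:
        return next(rec for rec in self.records if rec["N"] == N)

    @property
    def best(self) -> dict:
        return self.record_for(self.N_hat)


def outer_loss_for(
    recon: Reconstructor,
    train: TrainingSet,
    N: int,
    w: np.ndarray,
    fresh_noise: bool = False,
) -> float:
    """Sum over training datasets of J(g(d_t), r_t^{N0}).

    Uses the same fixed noise realizations as the inner problem unless
    ``fresh_noise`` is set.
    """
    total = 0.0
    for t in train.train_indices:
        ds = train.datasets[t]
        recon.set_maps(ds.maps)
        s_N = crop_kspace(ds, N)
        z = train.noise.noise(t, train.N0, ds.L, N=N, realization=(-1 if fresh_noise else 0))
        d = recon.data_from(s_N, z, w)
        x = recon.reconstruct(d, w)
        total += training_loss(x, make_reference(ds, train.N0))
    return total


def outer_select_N(
    kind: str,
    candidates: Sequence[int],
    train: TrainingSet,
    mode: str = "uniform",
    sched: InnerSchedule | None = None,
    seed: int = 0,
    fresh_noise_outer: bool = False,
    recon_kwargs: dict | None = None,
) -> DesignResult:
    """Brute-force grid search over candidate N values (the outer problem)."""
    if not candidates:
        raise ValueError("candidate set must be nonempty")
    if mode not in ("uniform", "nonuniform"):
        raise ValueError("mode must be 'uniform' or 'nonuniform'")
    sched = sched or default_schedule(kind, mode)
    recon_kwargs = recon_kwargs or {}
    records = []
    for N in candidates:
        recon = make_reconstructor(kind, train.datasets[0].maps, N, **recon_kwargs)
        fit = inner_optimize_uniform if mode == "uniform" else inner_optimize_nonuniform
        inner = fit(recon, N, train, sched, seed=seed)
        outer = outer_loss_for(recon, train, N, inner.w_final, fresh_noise=fresh_noise_outer)
        records.append(
            {
                "N": N,
                "p_hat": inner.p_hat,
                "w_hat": inner.w_hat,
                "q_hat": inner.q_hat,
                "w_final": inner.w_final,
                "inner_loss_trace": inner.loss_trace,
                "outer_loss": outer,
            }
        )
    N_hat = min(records, key=lambda rec: rec["outer_loss"])["N"]
    return DesignResult(kind=kind, mode=mode, N_hat=N_hat, records=records)
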