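"""Signal-averaging patterns on the phase-encode axis.

A scan that measures an N-line Cartesian grid with ``q[m]`` repeats
("averages", NEX) of line m costs ``sum(q)`` TRs.  All designs here conserve
the scan-time budget of a reference experiment that measures N0 lines with
uniform ``w0``-fold averaging, i.e. ``sum(q) = w0 * N0`` TRs.  Reducing the
grid to N < N0 additionally narrows the readout bandwidth, which boosts SNR
like extra averaging; the *effective* number of averages absorbing both
effects is ``w[m] = q[m] * N0 / N``, so feasible continuous patterns satisfy
``sum(w) = w0 * N0**2 / N``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from pathlib import Path

import numpy as np

__all__ = [
    "AveragingPattern",
    "IntegerPattern",
    "uniform_pattern",
    "project_to_budget",
    "normalize_gradient",
    "round_to_integer_averages",
    "center_distance",
    "budget_effective",
    "save_pattern_txt",
    "load_pattern_txt",
    "plot_pattern",
]

#: positivity floor for effective averages (undersampling disallowed by construction)
POSITIVITY_FLOOR = 1e-3


def budget_effective(N: int, N0: int, w0: float) -> float:
    """Scan-time budget expressed in effective averages: w0 * N0**2 / N."""
    return w0 * N0 ** 2 / N


@dataclass
class AveragingPattern:
    """Grid size N and per-line effective averages w under a fixed TR budget."""

    N: int
    w: np.ndarray  # length N, positive reals (effective averages)
    N0: int
    w0: float  # reference uniform actual averages (w~0)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.N % 2 != 0 or self.N < 2:
            raise ValueError(f"grid size N={self.N} must be a positive even integer")
        if self.N > self.N0:
            raise ValueError(f"N={self.N} exceeds reference grid N0={self.N0}")
        if self.w.shape != (self.N,):
            raise ValueError(f"w has shape {self.w.shape}, expected ({self.N},)")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("effective averages must be finite")
        if np.any(self.w <= 0):
            raise ValueError("effective averages must be strictly positive")

    @property
    def budget(self) -> float:
        return budget_effective(self.N, self.N0, self.w0)

    @property
    def is_feasible(self) -> bool:
        return abs(self.w.sum() - self.budget) <= 1e-9 * max(1.0, self.budget)

    def actual(self) -> np.ndarray:
        """Actual (possibly fractional) averages q = w * N / N0."""
        return self.w * self.N / self.N0


@dataclass
class IntegerPattern:
    """Integer actual averages per line; sums exactly to the TR budget w0*N0."""

    N: int
    q: np.ndarray  # length N, nonnegative integers
    N0: int
    w0: int

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q)
        if not np.issubdtype(self.q.dtype, np.integer):
            qi = np.rint(self.q).astype(np.int64)
            if not np.allclose(qi, self.q):
                raise ValueError("q must be integer-valued")
            self.q = qi
        if np.any(self.q < 0):
            raise ValueError("actual averages must be nonnegative")
        if int(self.q.sum()) != int(round(self.w0 * self.N0)):
            raise ValueError(
                f"scan-time budget violated: sum(q)={int(self.q.sum())} != "
                f"w0*N0={int(round(self.w0 * self.N0))}"
            )

    def effective(self) -> np.ndarray:
        """Effective averages w = q * N0 / N (exact rationals in float)."""
        return self.q * (self.N0 / self.N)

    def to_pattern(self) -> AveragingPattern:
        if np.any(self.q == 0):
            raise ValueError("pattern contains unmeasured lines; cannot express as positive effective averages")
        return AveragingPattern(N=self.N, w=self.effective(), N0=self.N0, w0=self.w0)


def uniform_pattern(N: int, N0: int, w0: float) -> AveragingPattern:
    """Uniform averaging at grid size N: w[m] = w0 * N0**2 / N**2 for all m."""
    w = np.full(N, w0 * N0 ** 2 / N ** 2, dtype=float)
    return AveragingPattern(N=N, w=w, N0=N0, w0=w0)


def project_to_budget(
    w: np.ndarray, budget: float, floor: float = POSITIVITY_FLOOR
) -> np.ndarray:
    """Euclidean projection of w onto {sum(w) = budget, w >= floor}.

    The unconstrained hyperplane projection adds the common offset
    beta/N with beta = budget - sum(w).  Entries pushed below the positivity
    floor are clipped there and the residual deficit is redistributed over
    the free entries, iterating until no new entry is clipped.
    """
    w = np.asarray(w, dtype=float)
    if budget <= 0:
        raise ValueError("budget must be positive")
    n = w.size
    if floor * n > budget:
        raise ValueError("budget too small to keep every line above the positivity floor")
    out = w.copy()
    free = np.ones(n, dtype=bool)
    for _ in range(n):
        beta = budget - floor * (~free).sum() - w[free].sum()
        out[free] = w[free] + beta / free.sum()
        newly_clipped = free & (out < floor)
        if not newly_clipped.any():
            break
        free &= ~newly_clipped
    out[~free] = floor
    return out


def normalize_gradient(g: np.ndarray) -> np.ndarray:
    """g / ||g||_2, or the zero vector when the gradient vanishes."""
    g = np.asarray(g, dtype=float)
    nrm = float(np.linalg.norm(g))
    if nrm == 0.0:
        return np.zeros_like(g)
    return g / nrm


def center_distance(N: int) -> np.ndarray:
    """Distance of each line from the k-space center, |m + 1/2| for m in {-N/2..N/2-1}.

    With an even grid the DC line sits at array position N/2; the half-sample
    offset makes the two central lines equidistant, as there is no single
    central line on an even grid.
    """
    m = np.arange(N) - N // 2
    return np.abs(m + 0.5)


def round_to_integer_averages(
    pattern: AveragingPattern, require_sampled: bool = False
) -> IntegerPattern:
    """Round a continuous design to integer actual averages at fixed scan time.

    Minimizes ``||q - (N/N0) w||_1`` subject to ``sum(q) = w0*N0`` and
    ``q >= 0`` by nearest-integer rounding followed by greedy unit
    adjustments; each step changes the line whose +-1 modification least
    increases the l1 cost.  Ties preserve averages closest to the k-space
    center (removal takes the farthest tied line, addition the nearest).
    The greedy scheme is globally optimal because the cost is separable and
    piecewise linear with integer breakpoints.
    """
    v = pattern.actual()  # target (N/N0) * w, positive reals
    N, N0 = pattern.N, pattern.N0
    w0 = int(round(pattern.w0))
    if abs(w0 - pattern.w0) > 1e-9:
        raise ValueError("reference averages w0 must be integral for rounding")
    target = w0 * N0
    if require_sampled and target < N:
        raise ValueError("budget smaller than the number of lines; cannot sample every line")
    q = np.floor(v + 0.5).astype(np.int64)  # round-half-up, deterministic
    dist = center_distance(N)
    lo = 1 if require_sampled else 0
    q = np.maximum(q, lo)
    while q.sum() != target:
        if q.sum() > target:
            cand = q > lo
            delta = np.abs(q - 1 - v) - np.abs(q - v)
            delta[~cand] = np.inf
            best = delta.min()
            tied = np.flatnonzero(delta == best)
            # preserve center: remove from the farthest tied line
            pick = tied[np.lexsort((tied, -dist[tied]))][0]
            q[pick] -= 1
        else:
            delta = np.abs(q + 1 - v) - np.abs(q - v)
            best = delta.min()
            tied = np.flatnonzero(delta == best)
            # add nearest to center first
            pick = tied[np.lexsort((tied, dist[tied]))][0]
            q[pick] += 1
    return IntegerPattern(N=N, q=q, N0=N0, w0=w0)


def exhaustive_integer_rounding(v: np.ndarray, target: int) -> float:
    """Brute-force optimum of min ||q - v||_1, sum(q)=target, q>=0 (tiny instances).

    Exponential-time reference used in tests and acceptance checks; do not
    call with target + len(v) above ~20.
    """
    v = np.asarray(v, dtype=float)
    n = v.size
    best = np.inf
    for bars in combinations_with_replacement(range(n), target):
        q = np.bincount(np.asarray(bars, dtype=np.int64), minlength=n)
        best = min(best, float(np.abs(q - v).sum()))
    return best


def save_pattern_txt(path: str | Path, ip: IntegerPattern) -> None:
    """Two-column plain-text table: line index m, integer averages."""
    m = np.arange(ip.N) - ip.N // 2
    header = f"N={ip.N} N0={ip.N0} w0={ip.w0}\nm\tq"
    np.savetxt(path, np.column_stack([m, ip.q]), fmt="%d", delimiter="\t", header=header)


def load_pattern_txt(path: str | Path) -> IntegerPattern:
    with open(path) as fh:
        first = fh.readline().lstrip("# ").strip()
    meta = dict(kv.split("=") for kv in first.split())
    arr = np.loadtxt(path, dtype=np.int64, skiprows=2)
    return IntegerPattern(
        N=int(meta["N"]), q=arr[:, 1], N0=int(meta["N0"]), w0=int(meta["w0"])
    )


def plot_pattern(ip: IntegerPattern, ax=None, **bar_kw):
    """Bar plot of integer averages versus phase-encode index."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    m = np.arange(ip.N) - ip.N // 2
    ax.bar(m, ip.q, width=1.0, **bar_kw)
    ax.set_xlabel("phase-encode index m")
    ax.set_ylabel("averages")
    ax.set_xlim(-ip.N0 // 2, ip.N0 // 2)
    return ax
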