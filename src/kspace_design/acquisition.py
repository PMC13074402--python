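"""Multicoil Cartesian k-space data model and noisy-acquisition simulation.

Arrays are laid out as ``(N_pe, N_ro, L)``: phase-encode index m along axis
0, readout index n along axis 1, receiver channel l along axis 2, on the
centered grid described in :mod:`kspace_design.fourier`.

The noise model is i.i.d. circular complex Gaussian with per-sample variance
``sigma**2`` before averaging (channels prewhitened, no interchannel
correlation).  Averaging line m with ``w[m]`` effective averages reduces the
variance to ``sigma**2 / w[m]``; the simulator realizes this by scaling a
fixed master noise realization by ``1/sqrt(w[m])`` per line.  The master
realization lives on the full N0 grid and is cropped for candidate grids N,
so all candidate designs see the same underlying noise vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np

from .fourier import crop_center, ifft2c
from .patterns import AveragingPattern, IntegerPattern

__all__ = [
    "KSpaceDataset",
    "NoiseModel",
    "NoisyAcquisition",
    "crop_kspace",
    "effective_averages",
    "actual_averages",
    "simulate_noisy_acquisition",
    "normalize_dataset",
    "scan_time",
    "save_dataset_h5",
    "load_dataset_h5",
    "save_dataset_npz",
    "load_dataset_npz",
]


@dataclass
class KSpaceDataset:
    """Noiseless multicoil k-space on the reference N0 grid plus coil maps."""

    s: np.ndarray  # complex, (N0, N0, L)
    maps: np.ndarray  # complex sensitivities, (N0, N0, L)
    fov_mm: float = 220.0
    id: str = ""

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=complex)
        self.maps = np.asarray(self.maps, dtype=complex)
        if self.s.ndim != 3 or self.s.shape[0] != self.s.shape[1]:
            raise ValueError(f"k-space must be (N0, N0, L), got {self.s.shape}")
        if self.s.shape != self.maps.shape:
            raise ValueError("k-space and sensitivity maps must share shape")
        if self.s.shape[0] % 2 != 0:
            raise ValueError("N0 must be even")

    @property
    def N0(self) -> int:
        return self.s.shape[0]

    @property
    def L(self) -> int:
        return self.s.shape[2]

    @property
    def delta_k(self) -> float:
        """Grid spacing in 1/mm (Nyquist sampling of the stated FOV)."""
        return 1.0 / self.fov_mm

    def channel_images(self) -> np.ndarray:
        """Per-channel inverse-Fourier images on the N0 grid."""
        return ifft2c(self.s)


@dataclass
class NoiseModel:
    """Seeded generator of the master complex noise realizations.

    ``sigma`` is the standard deviation of one unaveraged complex sample
    (real and imaginary parts each have variance ``sigma**2 / 2``).  One
    master realization exists per dataset index t; candidate grids crop it.
    """

    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    def master_noise(self, t: int, N0: int, L: int, realization: int = 0) -> np.ndarray:
        """Unit-variance master realization for dataset t on the N0 grid.

        ``realization=0`` is the fixed per-dataset draw shared by all
        candidate grids; other values give independent draws (per-epoch
        redraw, or held-out evaluation noise).
        """
        key = [int(self.seed), int(t)]
        if realization != 0:
            key.append(int(realization) & 0x7FFFFFFF)
        rng = np.random.default_rng(key)
        z = rng.standard_normal((N0, N0, L, 2))
        return (z[..., 0] + 1j * z[..., 1]) / np.sqrt(2.0)

    def noise(self, t: int, N0: int, L: int, N: int | None = None, realization: int = 0) -> np.ndarray:
        """Variance-``sigma**2`` noise for dataset t, cropped to grid N."""
        z = self.sigma * self.master_noise(t, N0, L, realization)
        if N is not None and N != N0:
            z = crop_center(z, (N, N))
        return z


@dataclass
class NoisyAcquisition:
    """Averaged noisy samples d with per-line noise variance sigma**2 / w[m]."""

    d: np.ndarray  # complex, (N, N, L)
    pattern: AveragingPattern
    sigma: float

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=complex)
        if self.d.shape[0] != self.pattern.N or self.d.shape[1] != self.pattern.N:
            raise ValueError(
                f"data shape {self.d.shape} does not match pattern grid N={self.pattern.N}"
            )

    @property
    def N(self) -> int:
        return self.pattern.N

    @property
    def L(self) -> int:
        return self.d.shape[2]


def crop_kspace(ds_or_array: KSpaceDataset | np.ndarray, N: int) -> np.ndarray:
    """Centered N x N crop of the k-space grid (samples outside discarded)."""
    s = ds_or_array.s if isinstance(ds_or_array, KSpaceDataset) else np.asarray(ds_or_array)
    N0 = s.shape[0]
    if N % 2 != 0 or N < 2:
        raise ValueError(f"N={N} must be a positive even integer")
    if N > N0:
        raise ValueError(f"N={N} exceeds grid size N0={N0}")
    return crop_center(s, (N, N))


def effective_averages(w_actual: np.ndarray, N: int, N0: int) -> np.ndarray:
    """Effective averages w = w_actual * N0 / N (bandwidth gain folded in)."""
    w_actual = np.asarray(w_actual, dtype=float)
    if np.any(w_actual <= 0):
        raise ValueError("actual averages must be strictly positive")
    return w_actual * (N0 / N)


def actual_averages(w: np.ndarray, N: int, N0: int) -> np.ndarray:
    """Inverse of :func:`effective_averages`: w_actual = w * N / N0."""
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("effective averages must be strictly positive")
    return w * (N / N0)


def simulate_noisy_acquisition(
    s_N: np.ndarray,
    pattern: AveragingPattern,
    noise: NoiseModel,
    t: int = 0,
    N0: int | None = None,
) -> NoisyAcquisition:
    """Simulate averaged noisy data d = s + (1/sqrt(w)) * z on the N grid.

    z is the (seed, t)-deterministic master realization on the N0 grid,
    cropped to N, so different candidate grid sizes share the same
    underlying noise vectors.  The per-line scale 1/sqrt(w[m]) makes
    Var(d - s) = sigma**2 / w[m] exact.
    """
    s_N = np.asarray(s_N, dtype=complex)
    if s_N.shape[0] != pattern.N or s_N.shape[1] != pattern.N:
        raise ValueError(f"s_N shape {s_N.shape} does not match pattern N={pattern.N}")
    N0 = pattern.N0 if N0 is None else N0
    L = s_N.shape[2]
    z = noise.noise(t, N0, L, N=pattern.N)
    d = s_N + z / np.sqrt(pattern.w)[:, None, None]
    return NoisyAcquisition(d=d, pattern=pattern, sigma=noise.sigma)


def normalize_dataset(ds: KSpaceDataset) -> KSpaceDataset:
    """Scale all channels by one scalar so the max voxel magnitude is 1.

    The maximum is taken over all voxels and channels of the per-channel
    inverse-Fourier images, so the multichannel images have magnitudes in
    [0, 1] afterwards.
    """
    peak = float(np.abs(ds.channel_images()).max())
    if peak == 0.0:
        raise ValueError("cannot normalize an all-zero dataset")
    return replace(ds, s=ds.s / peak)


def scan_time(pattern: AveragingPattern | IntegerPattern) -> int:
    """Total TR count sum(q) of the integer actual averages."""
    if isinstance(pattern, IntegerPattern):
        return int(pattern.q.sum())
    q = pattern.actual()
    qi = np.rint(q)
    if not np.allclose(q, qi, atol=1e-6):
        raise ValueError("pattern has non-integer actual averages; round first")
    return int(qi.sum())


# ---------------------------------------------------------------------------
# container I/O: HDF5 (paired float32 real/imag) with an NPZ mirror


def _c2f(x: np.ndarray) -> np.ndarray:
    return np.stack([x.real, x.imag], axis=-1).astype(np.float32)


def _f2c(x: np.ndarray) -> np.ndarray:
    return x[..., 0].astype(np.float64) + 1j * x[..., 1].astype(np.float64)


def save_dataset_h5(path: str | Path, ds: KSpaceDataset) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("kspace", data=_c2f(ds.s))
        fh.create_dataset("maps", data=_c2f(ds.maps))
        fh.attrs["fov_mm"] = ds.fov_mm
        fh.attrs["N0"] = ds.N0
        fh.attrs["L"] = ds.L
        fh.attrs["id"] = ds.id


def load_dataset_h5(path: str | Path) -> KSpaceDataset:
    with h5py.File(path, "r") as fh:
        return KSpaceDataset(
            s=_f2c(fh["kspace"][()]),
            maps=_f2c(fh["maps"][()]),
            fov_mm=float(fh.attrs["fov_mm"]),
            id=str(fh.attrs.get("id", "")),
        )


def save_dataset_npz(path: str | Path, ds: KSpaceDataset) -> None:
    np.savez(path, kspace=_c2f(ds.s), maps=_c2f(ds.maps), fov_mm=ds.fov_mm, id=ds.id)


def load_dataset_npz(path: str | Path) -> KSpaceDataset:
    with np.load(path, allow_pickle=False) as data:
        return KSpaceDataset(
            s=_f2c(data["kspace"]),
            maps=_f2c(data["maps"]),
            fov_mm=float(data["fov_mm"]),
            id=str(data["id"]),
        )
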