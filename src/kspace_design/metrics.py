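"""Image-quality metrics and evaluation reports.

NRMSE follows the convention ``||x - r||_2 / ||x||_2`` on complex images
(the denominator is the *estimate* norm); the conventional
reference-normalized variant is available behind a switch.  SSIM is
computed on magnitude images with an 11x11 Gaussian window (sigma = 1.5),
K1 = 0.01, K2 = 0.03, and dynamic range set by the maximum magnitude of the
reference — note this makes SSIM asymmetric in its arguments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .acquisition import crop_kspace
from .optimize import DesignResult, TrainingSet, make_reference
from .recon import make_reconstructor

__all__ = ["nrmse", "ssim", "EvalReport", "evaluate_design"]


def nrmse(x: np.ndarray, r: np.ndarray, normalize_by: str = "estimate") -> float:
    """Normalized RMSE ||x - r||_2 / ||x||_2 (or / ||r||_2 with ``normalize_by="reference"``)."""
    if x.shape != r.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {r.shape}")
    denom = np.linalg.norm(x if normalize_by == "estimate" else r)
    if denom == 0:
        raise ValueError("zero-norm normalizer in NRMSE")
    return float(np.linalg.norm(x - r) / denom)


def ssim(x: np.ndarray, r: np.ndarray) -> float:
    """Mean structural similarity of the magnitude images (range from r)."""
    xm, rm = np.abs(x), np.abs(r)
    return float(
        structural_similarity(
            xm,
            rm,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
            data_range=float(rm.max()),
        )
    )


@dataclass
class EvalReport:
    """Per-dataset and aggregate metrics for a trained design."""

    kind: str
    mode: str
    N_hat: int
    rows: pd.DataFrame  # columns: dataset, N, nrmse, ssim, is_selected
    curves: pd.DataFrame  # per-candidate means: N, nrmse, one_minus_nrmse, ssim

    def summary(self) -> dict:
        sel = self.rows[self.rows.N == self.N_hat]
        return {
            "kind": self.kind,
            "mode": self.mode,
            "N_hat": int(self.N_hat),
            "mean_nrmse": float(sel.nrmse.mean()),
            "mean_ssim": float(sel.ssim.mean()),
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind,
            "mode": self.mode,
            "N_hat": int(self.N_hat),
            "rows": self.rows.to_dict(orient="list"),
            "curves": self.curves.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "EvalReport":
        payload = json.loads(Path(path).read_text())
        return cls(
            kind=payload["kind"],
            mode=payload["mode"],
            N_hat=int(payload["N_hat"]),
            rows=pd.DataFrame(payload["rows"]),
            curves=pd.DataFrame(payload["curves"]),
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EvalReport)
            and self.kind == other.kind
            and self.mode == other.mode
            and self.N_hat == other.N_hat
            and np.allclose(self.rows[["N", "nrmse", "ssim"]], other.rows[["N", "nrmse", "ssim"]])
            and np.allclose(self.curves, other.curves)
        )


def evaluate_design(
    result: DesignResult,
    train: TrainingSet,
    split: str = "test",
    recon_kwargs: dict | None = None,
) -> EvalReport:
    """Score a trained design on a held-out split against r^{N0}.

    Reconstructs every dataset in the split with each candidate's trained
    parameters and pattern, yielding both the per-dataset metrics at the
    selected N_hat and the metric-versus-resolution curves over all
    candidates.
    """
    indices = train.split.get(split, [])
    if not indices:
        raise ValueError(f"empty split {split!r}")
    recon_kwargs = recon_kwargs or {}
    rows = []
    for rec in result.records:
        N = rec["N"]
        recon = make_reconstructor(result.kind, train.datasets[0].maps, N, **recon_kwargs)
        recon.set_params(rec["p_hat"])
        for t in indices:
            ds = train.datasets[t]
            recon.set_maps(ds.maps)
            s_N = crop_kspace(ds, N)
            z = train.noise.noise(t, train.N0, ds.L, N=N)
            d = recon.data_from(s_N, z, rec["w_final"])
            x = recon.reconstruct(d, rec["w_final"])
            r = make_reference(ds, train.N0)
            rows.append(
                {
                    "dataset": ds.id or str(t),
                    "N": N,
                    "nrmse": nrmse(x, r),
                    "ssim": ssim(x, r),
                    "is_selected": N == result.N_hat,
                }
            )
    rows = pd.DataFrame(rows)
    curves = (
        rows.groupby("N")[["nrmse", "ssim"]]
        .mean()
        .reset_index()
        .assign(one_minus_nrmse=lambda df: 1.0 - df.nrmse)
    )
    return EvalReport(kind=result.kind, mode=result.mode, N_hat=result.N_hat, rows=rows, curves=curves)
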