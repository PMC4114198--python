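"""Clean-EEG recovery: direct subtraction and group-sparse optimisation.

Direct subtraction removes the estimated artifact elementwise.  The
optimisation route additionally projects the subtraction residual onto a
prior signal basis learned from out-of-scanner EEG, with an l2,1 penalty
that zeroes whole coefficient rows (one basis atom across all segments),
suppressing broadband estimation error that the basis does not support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Recording, ValidationError
from .estimators import (
    GroupSparseReconstructor,
    GroupSparseSolution,
    l21_norm,
    prox_l21,
)

__all__ = [
    "EegBasis",
    "learn_basis",
    "subtract_reconstruct",
    "prox_l21",
    "l21_norm",
    "group_sparse_reconstruct",
    "reconstruct_all",
    "default_mu_grid",
    "GroupSparseSolution",
]


@dataclass
class EegBasis:
    """Prior basis: L-sample atoms as unit-norm columns of B (L x m)."""

    B: np.ndarray
    origin: str = "pca"

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=float)
        if self.B.ndim != 2:
            raise ValidationError("basis must be a 2-D matrix")
        L, m = self.B.shape
        if m > L:
            raise ValidationError(f"more atoms ({m}) than samples ({L})")
        norms = np.linalg.norm(self.B, axis=0)
        if np.any(np.abs(norms - 1) > 1e-8):
            raise ValidationError("basis columns must have unit norm")

    @property
    def L(self) -> int:
        return self.B.shape[0]

    @property
    def m(self) -> int:
        return self.B.shape[1]


def learn_basis(clean_eeg: Recording, L: int = 250, m: int = 40,
                method: str = "pca") -> EegBasis:
    """Learn an L-sample, m-atom prior basis from clean EEG.

    ``pca``: top-m left singular vectors of all non-overlapping L-sample
    segments pooled over channels.  ``dct``: first m type-II DCT atoms
    (data-independent fallback).
    """
    if m > L:
        raise ValidationError(f"m={m} exceeds segment length L={L}")
    if method == "dct":
        n = np.arange(L)
        B = np.cos(np.pi * (n[:, None] + 0.5) * np.arange(m)[None, :] / L)
        B /= np.linalg.norm(B, axis=0, keepdims=True)
        return EegBasis(B=B, origin="dct")
    if method != "pca":
        raise ValidationError(f"unknown basis method {method!r}")
    if clean_eeg.n_samples < 5 * L:
        raise ValidationError(
            f"need T >= 5 L = {5 * L} samples of clean EEG for PCA basis")
    n_seg = clean_eeg.n_samples // L
    segs = clean_eeg.data[:, : n_seg * L].reshape(
        clean_eeg.n_channels, n_seg, L)
    pooled = segs.reshape(-1, L).T              # L x (C * n_seg)
    U, _, _ = np.linalg.svd(pooled, full_matrices=False)
    B = U[:, :m]
    B /= np.linalg.norm(B, axis=0, keepdims=True)
    return EegBasis(B=B, origin="pca")


def subtract_reconstruct(Y: Recording, bcg_hat: Recording) -> Recording:
    """Direct subtraction: clean = contaminated - estimated artifact."""
    if Y.data.shape != bcg_hat.data.shape:
        raise ValidationError(
            f"shape mismatch {Y.data.shape} vs {bcg_hat.data.shape}")
    return Y.copy_with(Y.data - bcg_hat.data)


def group_sparse_reconstruct(y_signal, basis: EegBasis, mu: float,
                             tol: float = 1e-6, max_iter: int = 1000):
    """Denoise one channel; returns (GroupSparseSolution, reconstructed)."""
    solver = GroupSparseReconstructor(basis=basis, mu=mu, tol=tol,
                                      max_iter=max_iter)
    recon, sol = solver.transform(y_signal)
    return sol, recon


def default_mu_grid(Y: np.ndarray, m: int, L: int) -> np.ndarray:
    """Grid {1e-3 .. 1e3} x (mean segment energy / (2 m))."""
    n = max(Y.size // L, 1)
    scale = float((Y ** 2).sum()) / (2 * m * n)
    return scale * np.logspace(-3, 3, 13)


def reconstruct_all(Y: Recording, bcg_hat: Recording,
                    basis: EegBasis | None = None,
                    method: str = "subtract", mu: float = 1.0,
                    tol: float = 1e-6, max_iter: int = 1000) -> Recording:
    """Full-recording reconstruction by either route.

    ``subtract``: elementwise difference.  ``optimize``: subtraction
    followed by per-channel group-sparse denoising of the residual
    signal against ``basis``.
    """
    diff = subtract_reconstruct(Y, bcg_hat)
    if method == "subtract":
        return diff
    if method != "optimize":
        raise ValidationError(f"unknown reconstruction method {method!r}")
    if basis is None:
        raise ValidationError("method='optimize' requires a basis")
    solver = GroupSparseReconstructor(basis=basis, mu=mu, tol=tol,
                                      max_iter=max_iter)
    out = np.empty_like(diff.data)
    for c in range(diff.n_channels):
        out[c], _ = solver.transform(diff.data[c])
    return diff.copy_with(out)
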