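"""Estimator classes for the two-stage artifact-removal framework.

These follow scikit-learn conventions: hyperparameters are constructor
arguments, fitted state lives in trailing-underscore attributes, and the
data orientation is samples x features (time x channels).  The wrapper
functions in :mod:`bcgomp.selection`, :mod:`bcgomp.inference`,
:mod:`bcgomp.reconstruction` and :mod:`bcgomp.obs` work on
channels x time :class:`~bcgomp.core.Recording` objects and delegate here.

Method summary
--------------
``OmpBcgInference`` solves the joint subset-selection / inference problem

    min_{S, W} || X - W_tilde X[S, :] ||_F^2,   |S| = budget,

greedily: each step adds the channel whose (normalised) signal best
correlates with the current residual across all channels, then refits the
expanded inference matrix W_tilde by least squares.  At acquisition time
``predict`` maps artifact-only signals on the selected subset to a
full-scalp artifact estimate.

``GroupSparseReconstructor`` denoises a single-channel signal by solving

    min_C ||C||_{2,1} + 1/(2 mu) || Y - B C ||_F^2

over non-overlapping segments stacked as columns of Y, with a monotone
accelerated proximal-gradient scheme; rows of C (one basis atom across all
segments) form the sparsity groups.

``ObsCleaner`` is the optimal-basis-set baseline: per channel, regress the
heartbeat-epoch mean template and the top principal components of the
demeaned epoch matrix out of every epoch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from .core import BeatAnnotations, ChannelSubset, InferenceModel, ValidationError

__all__ = [
    "OmpBcgInference",
    "GroupSparseReconstructor",
    "ObsCleaner",
    "OmpTrace",
    "GroupSparseSolution",
    "prox_l21",
    "l21_norm",
]


# ---------------------------------------------------------------------------
# least squares + OMP internals (channels x time orientation)
# ---------------------------------------------------------------------------

def lstsq_expanded(X: np.ndarray, rows: list[int]) -> np.ndarray:
    """Min-norm W_tilde (C x k) minimising ||X - W_tilde X[rows, :]||_F."""
    Xs = X[rows]
    # min-norm least squares via gelsd
    Wt, *_ = scipy.linalg.lstsq(Xs.T, X.T, lapack_driver="gelsd")
    return Wt.T


@dataclass
class OmpTrace:
    """Greedy-selection diagnostics: order, residuals, per-step scores."""

    selected: ChannelSubset
    residual_norms: list[float]
    per_channel_scores: list[np.ndarray] | None = None

    def __post_init__(self):
        r = np.asarray(self.residual_norms)
        if len(r) != len(self.selected):
            raise ValidationError(
                "one residual norm per completed iteration required"
            )
        if len(r) > 1 and np.any(np.diff(r) > 1e-9 * max(r[0], 1.0)):
            raise ValidationError("residual norms must be non-increasing")


def _omp_iterate(X: np.ndarray, budget: int, early_stop_tol: float,
                 keep_scores: bool):
    """Greedy residual-correlation selection with per-step LS refit.

    Score of candidate i at step k:
        sum_j <R_j^(k-1), X_i / ||X_i||_F>^2
    with X_i the ORIGINAL row of channel i.  Ties break to the smallest
    channel index; already-selected channels are excluded.
    """
    C, _ = X.shape
    norms = np.linalg.norm(X, axis=1)
    x_norm = np.linalg.norm(X)
    R = X.copy()
    selected: list[int] = []
    residual_norms: list[float] = []
    scores_log: list[np.ndarray] = []
    W_exp = np.zeros((C, 0))
    for _ in range(budget):
        M = R @ X.T                      # M[j, i] = <R_j, X_i>
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = (M ** 2).sum(axis=0) / norms ** 2
        scores[norms == 0] = 0.0
        scores[selected] = -np.inf
        i = int(np.argmax(scores))       # first max -> smallest index
        selected.append(i)
        if keep_scores:
            scores_log.append(np.where(np.isfinite(scores), scores, np.nan))
        W_exp = lstsq_expanded(X, selected)
        R = X - W_exp @ X[selected]
        rnorm = float(np.linalg.norm(R))
        residual_norms.append(rnorm)
        if rnorm < early_stop_tol * x_norm and len(selected) < budget:
            warnings.warn(
                f"residual vanished after {len(selected)} channels; "
                "stopping before budget", RuntimeWarning)
            break
    return selected, W_exp, residual_norms, scores_log if keep_scores else None


class OmpBcgInference(BaseEstimator, RegressorMixin):
    """Greedy channel-subset selection + linear full-scalp artifact inference.

    Parameters
    ----------
    budget : int, default 20
        Number of channels to select (the insulation-set cardinality).
    subset : sequence of int, optional
        Explicit 1-based channel subset; skips the greedy search.
    demean : bool, default False
        Subtract per-channel means before selection/fitting.
    early_stop_tol : float, default 1e-10
        Stop early when the residual falls below this fraction of the
        training norm (degenerate low-rank inputs).
    keep_scores : bool, default False
        Record the per-iteration per-channel score vectors in the trace.

    Attributes
    ----------
    subset_ : ChannelSubset           selected channels, selection order
    W_ : ndarray (C-k, k)             map to the non-selected channels
    W_expanded_ : ndarray (C, k)      map to all channels
    trace_ : OmpTrace                 greedy diagnostics (None if subset given)
    n_channels_ : int
    """

    def __init__(self, budget: int = 20, subset=None, demean: bool = False,
                 early_stop_tol: float = 1e-10, keep_scores: bool = False):
        self.budget = budget
        self.subset = subset
        self.demean = demean
        self.early_stop_tol = early_stop_tol
        self.keep_scores = keep_scores

    def fit(self, X, y=None):
        """Fit on artifact-only training data, shape (T, C)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("X must be 2-D (n_samples, n_channels)")
        Xc = X.T.copy()                  # channels x time internally
        C, T = Xc.shape
        if self.demean:
            Xc -= Xc.mean(axis=1, keepdims=True)
        if self.subset is not None:
            rows = [int(i) - 1 for i in self.subset]
            if not rows:
                raise ValidationError("subset must not be empty")
            if any(not (0 <= r < C) for r in rows):
                raise ValidationError("subset channel index out of range")
            sel_norms = np.linalg.norm(Xc[rows], axis=1)
            if np.any(sel_norms == 0):
                warnings.warn("all-zero selected rows: returning the "
                              "minimum-norm solution", RuntimeWarning)
            self.W_expanded_ = lstsq_expanded(Xc, rows)
            self.trace_ = None
            selected = rows
        else:
            if not (1 <= self.budget <= C):
                raise ValidationError(
                    f"budget must be in [1..{C}], got {self.budget}")
            if T < 1:
                raise ValidationError("empty training data")
            selected, self.W_expanded_, rnorms, scores = _omp_iterate(
                Xc, self.budget, self.early_stop_tol, self.keep_scores)
            self.trace_ = OmpTrace(
                selected=ChannelSubset([i + 1 for i in selected], C),
                residual_norms=rnorms,
                per_channel_scores=scores,
            )
        self.subset_ = ChannelSubset([i + 1 for i in selected], C)
        nins = self.subset_.complement().row_indices
        self.W_ = self.W_expanded_[nins]
        self.n_channels_ = C
        return self

    def to_model(self, **meta) -> InferenceModel:
        """Package the fitted maps as an :class:`InferenceModel`."""
        return InferenceModel(subset=self.subset_, W=self.W_,
                              W_expanded=self.W_expanded_,
                              training_meta=dict(meta))

    def predict(self, X_ins) -> np.ndarray:
        """Full-scalp artifact estimate (T, C) from insulated signals (T, k)."""
        X_ins = np.asarray(X_ins, dtype=float)
        if X_ins.ndim != 2 or X_ins.shape[1] != len(self.subset_):
            raise ValidationError(
                f"expected (T, {len(self.subset_)}) insulated signals, "
                f"got {X_ins.shape}")
        return X_ins @ self.W_expanded_.T

    def predict_nins(self, X_ins) -> np.ndarray:
        """Artifact estimate restricted to the non-selected channels."""
        X_ins = np.asarray(X_ins, dtype=float)
        return X_ins @ self.W_.T


# ---------------------------------------------------------------------------
# group-sparse reconstruction
# ---------------------------------------------------------------------------

def l21_norm(V: np.ndarray) -> float:
    """Sum of row-wise euclidean norms."""
    return float(np.linalg.norm(V, axis=1).sum())


def prox_l21(V: np.ndarray, tau: float) -> np.ndarray:
    """Row-wise shrinkage: row <- max(0, 1 - tau/||row||) * row."""
    if tau < 0:
        raise ValidationError("tau must be >= 0")
    norms = np.linalg.norm(V, axis=1, keepdims=True)
    scale = np.zeros_like(norms)
    nz = norms > 0
    scale[nz] = np.maximum(0.0, 1.0 - tau / norms[nz])
    return V * scale


@dataclass
class GroupSparseSolution:
    """Solver output for one channel."""

    C_eeg: np.ndarray
    objective_trace: list[float]
    mu: float
    converged: bool = False


class GroupSparseReconstructor(BaseEstimator, TransformerMixin):
    """Segment-wise group-sparse denoiser with a prior signal basis.

    Parameters
    ----------
    basis : object with attribute ``B`` (L x m, unit-norm columns)
    mu : float
        Fidelity/sparsity trade-off; small mu trusts the data, large mu
        drives all coefficient rows to zero.
    tol : float, default 1e-6
        Relative objective-change stopping criterion.
    max_iter : int, default 1000
    """

    def __init__(self, basis=None, mu: float = 1.0, tol: float = 1e-6,
                 max_iter: int = 1000):
        self.basis = basis
        self.mu = mu
        self.tol = tol
        self.max_iter = max_iter

    def _check(self):
        if self.basis is None:
            raise ValidationError("a basis is required")
        if self.mu <= 0:
            raise ValidationError(f"mu must be > 0, got {self.mu}")
        return np.asarray(self.basis.B, dtype=float)

    def solve_segments(self, Y_seg: np.ndarray) -> GroupSparseSolution:
        """Minimise ||C||_2,1 + 1/(2 mu) ||Y - B C||_F^2 for Y (L x n).

        Monotone FISTA: plain accelerated proximal gradient, but the
        iterate only moves when the objective decreases, so the recorded
        objective trace is non-increasing by construction.
        """
        B = self._check()
        mu = float(self.mu)
        smax2 = np.linalg.norm(B, 2) ** 2
        step = mu / smax2 if smax2 > 0 else 1.0
        m = B.shape[1]
        n = Y_seg.shape[1]
        BtY = B.T @ Y_seg
        BtB = B.T @ B

        def objective(C):
            resid = Y_seg - B @ C
            return l21_norm(C) + (resid ** 2).sum() / (2 * mu)

        x = np.zeros((m, n))
        x_prev = x
        yk = x
        t = 1.0
        F_prev = objective(x)
        trace = [F_prev]
        converged = False
        for _ in range(self.max_iter):
            grad = (BtB @ yk - BtY) / mu
            z = prox_l21(yk - step * grad, step)
            Fz = objective(z)
            if Fz <= F_prev:
                x_new, F_new = z, Fz
                t_new = 0.5 * (1 + np.sqrt(1 + 4 * t * t))
                yk = x_new + (t / t_new) * (z - x_new) \
                    + ((t - 1) / t_new) * (x_new - x_prev)
            else:
                # momentum overshoot: keep the iterate, restart momentum
                x_new, F_new = x, F_prev
                t_new = 1.0
                yk = x_new
            x_prev, x = x, x_new
            scale = max(abs(trace[0]), 1e-30)
            accepted_change = F_prev - F_new
            candidate_change = abs(Fz - F_prev)
            F_prev = F_new
            trace.append(F_new)
            t = t_new
            if max(accepted_change, candidate_change) < self.tol * scale:
                converged = True
                break
        return GroupSparseSolution(C_eeg=x, objective_trace=trace,
                                   mu=mu, converged=converged)

    def transform(self, y: np.ndarray):
        """Denoise a single-channel signal of length T.

        The signal is cut into floor(T/L) non-overlapping L-sample
        segments (columns of Y); a trailing remainder shorter than L is
        passed through unmodified.  Returns (reconstructed, solution).
        """
        B = self._check()
        y = np.asarray(y, dtype=float).ravel()
        L = B.shape[0]
        n = len(y) // L
        if n == 0:
            raise ValidationError(
                f"signal of length {len(y)} shorter than one segment ({L})")
        Y_seg = y[: n * L].reshape(n, L).T
        sol = self.solve_segments(Y_seg)
        recon = (B @ sol.C_eeg).T.ravel()
        if n * L < len(y):
            recon = np.concatenate([recon, y[n * L:]])
        return recon, sol


# ---------------------------------------------------------------------------
# optimal-basis-set baseline
# ---------------------------------------------------------------------------

class ObsCleaner(BaseEstimator):
    """Heartbeat-epoch mean + principal-component regression, per channel.

    Parameters
    ----------
    n_pcs : int, default 3
        Principal components of the demeaned epoch matrix to regress out
        alongside the mean template.
    window : (float, float), default (0.25, 0.75)
        Epoch extent as fractions of the median RR interval before/after
        each R-peak; the fractions must sum to 1 (epoch length = median RR).
    """

    def __init__(self, n_pcs: int = 3, window: tuple = (0.25, 0.75)):
        self.n_pcs = n_pcs
        self.window = window

    def clean(self, X: np.ndarray, beats: BeatAnnotations) -> np.ndarray:
        """Clean (C, T) data; samples outside any epoch pass through."""
        pre_frac, post_frac = self.window
        if abs(pre_frac + post_frac - 1.0) > 1e-9:
            raise ValidationError("window fractions must sum to 1")
        if self.n_pcs < 0:
            raise ValidationError("n_pcs must be >= 0")
        X = np.asarray(X, dtype=float)
        C, T = X.shape
        rr = beats.rr_intervals()
        if len(rr) == 0:
            raise ValidationError("need at least 2 beats")
        med_rr = float(np.median(rr))
        L = int(round(med_rr))
        L_pre = int(round(pre_frac * med_rr))
        starts = []
        for p in beats.row_indices:
            s = p - L_pre
            if s >= 0 and s + L <= T:
                starts.append(s)
        if len(starts) < self.n_pcs + 2:
            raise ValidationError(
                f"need at least {self.n_pcs + 2} complete epochs, "
                f"got {len(starts)}")
        out = X.copy()
        idx = np.asarray(starts)[:, None] + np.arange(L)[None, :]
        for c in range(C):
            E = X[c][idx]                       # n_epochs x L
            mean_t = E.mean(axis=0)
            design = [mean_t]
            if self.n_pcs > 0:
                D = E - mean_t
                _, _, Vt = np.linalg.svd(D, full_matrices=False)
                design.extend(Vt[: self.n_pcs])
            A = np.column_stack(design)         # L x (1 + n_pcs)
            coef, *_ = np.linalg.lstsq(A, E.T, rcond=None)
            cleaned = E - (A @ coef).T
            for row, s in enumerate(starts):
                out[c, s: s + L] = cleaned[row]
        return out
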